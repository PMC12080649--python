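"""Gene-set over-representation analysis (hypergeometric test with BH-FDR).

Replaces an external enrichment web service with an exact, auditable local
computation: for a query gene list and a background universe, each annotation
term is scored with the hypergeometric upper-tail probability of its observed
overlap, and Benjamini-Hochberg correction is applied across all tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORIES = ("biological_process", "molecular_function", "cellular_component", "other")


@dataclass(frozen=True)
class GeneSet:
    """One annotation term: id, display name, ontology category, member genes."""

    term_id: str
    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has an empty gene set")
        if self.category not in CATEGORIES:
            object.__setattr__(self, "category", "other")


class GeneSetCollection:
    """Mapping term_id -> GeneSet with GMT round-tripping."""

    def __init__(self, terms: dict[str, GeneSet] | None = None):
        self.terms: dict[str, GeneSet] = dict(terms or {})

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.terms[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term in self:
                genes = "\t".join(sorted(term.genes))
                fh.write(f"{term.term_id}\t{term.category}\t{genes}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one term per line, ``term_id<TAB>description<TAB>genes...``.

    Duplicate genes within a term are deduplicated; a duplicate term_id or a
    line with fewer than three fields is an error (reported with its line
    number).  The description field doubles as the ontology category when it
    matches one of the GO namespaces, otherwise the category is "other".
    """
    terms: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            term_id, desc = fields[0], fields[1]
            if term_id in terms:
                raise ValueError(f"{path}: line {lineno}: duplicate term id {term_id!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}: line {lineno}: term {term_id!r} has no genes")
            category = desc if desc in CATEGORIES else "other"
            terms[term_id] = GeneSet(term_id, desc, category, genes)
    return GeneSetCollection(terms)


def hypergeom_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    With background size N, term size K (after intersecting the term with the
    background), query size n and overlap k, the one-sided p-value is
    P(X >= k) for X ~ Hypergeometric(N, K, n).  BH-FDR is applied across all
    tested terms; terms with no background overlap are skipped (and logged).

    Returns a DataFrame sorted by (q, p) with columns
    term_id, term_name, category, k, K, n, N, p, q, significant.
    """
    background = set(background)
    query = set(query)
    stray = sorted(query - background)
    if stray:
        raise ValueError(f"query genes absent from background: {stray[:10]}"
                         + ("..." if len(stray) > 10 else ""))
    N, n = len(background), len(query)

    rows = []
    for term in collection:
        term_bg = term.genes & background
        if not term_bg:
            logger.warning("term %s has no overlap with background; skipped", term.term_id)
            continue
        K = len(term_bg)
        k = len(term_bg & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term.term_id, term.name, term.category, k, K, n, N, min(p, 1.0)))

    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "category", "k", "K", "n", "N", "p"]
    )
    if len(out):
        from .groupmaps import bh_fdr

        q, reject = bh_fdr(out["p"].to_numpy(), q_threshold)
        out["q"] = q
        out["significant"] = reject
        out = out.sort_values(["q", "p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
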