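"""Synthetic multi-site morphometry cohorts, receptor maps and expression data.

The generators emulate the statistical structure of a two-group (HC vs MDD),
multi-site structural-MRI study:

* a cohort with uniform ages, balanced site assignment and exact group counts;
* region-wise cortical thickness with linear age-related thinning on a subset
  of regions, additive and multiplicative site effects, Gaussian measurement
  noise, and a spatially contiguous group-specific thinning cluster (the
  ground truth recovered by the difference-map stage);
* receptor/transporter density maps with controllable spatial smoothness and a
  controllable correlation to the true effect map;
* a regional gene-expression matrix in which a designated subset of "signal"
  genes loads on the true effect map, together with a risk-gene list and an
  annotation collection containing one term enriched for the signal genes.

Every generator takes an explicit integer seed and uses no global state, so
regenerating with the same arguments is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .enrich import GeneSet, GeneSetCollection
from .geometry import ParcellationGeometry, make_geometry  # noqa: F401  (re-export)

__all__ = [
    "TruthMap",
    "ThicknessParams",
    "DEFAULT_RECEPTOR_SPEC",
    "make_geometry",
    "make_cohort",
    "simulate_thickness",
    "simulate_receptor_maps",
    "simulate_expression",
]


@dataclass(frozen=True)
class TruthMap:
    """Ground-truth injected group effect per region.

    ``effect`` holds the additive group effect in mm (negative = thinning in
    the patient group); ``affected_mask`` is True exactly where the effect is
    nonzero, and the affected regions form one spatially contiguous cluster.
    """

    region_ids: list[str]
    effect: np.ndarray
    affected_mask: np.ndarray

    def __post_init__(self) -> None:
        effect = np.asarray(self.effect, dtype=float)
        mask = np.asarray(self.affected_mask, dtype=bool)
        if effect.shape != (len(self.region_ids),) or mask.shape != effect.shape:
            raise ValueError("effect/affected_mask must be region-length vectors")
        if not np.array_equal(mask, effect != 0):
            raise ValueError("effect must be nonzero exactly where affected_mask is True")
        object.__setattr__(self, "effect", effect)
        object.__setattr__(self, "affected_mask", mask)


def make_cohort(
    n_hc: int,
    n_mdd: int,
    n_sites: int = 5,
    age_range: tuple[float, float] = (18.0, 80.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate subject metadata: subject_id, age, sex, site, group.

    Ages are uniform on ``age_range``, drawn group-stratified (each group's
    ages are a jittered equal-probability stratification of the range) so the
    two groups are age-matched by construction, as in a case-control sample
    screened for group age differences; sites are assigned round-robin to a
    shuffled subject order (so every site gets a near-equal share of each
    group); group counts are exact.
    """
    if n_hc < 0 or n_mdd < 0:
        raise ValueError("group counts must be non-negative")
    n = n_hc + n_mdd
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n < 2 * n_sites:
        raise ValueError(
            f"need at least 2 subjects per site: {n} subjects for {n_sites} sites"
        )
    lo, hi = float(age_range[0]), float(age_range[1])
    if not lo < hi:
        raise ValueError(f"age_range must satisfy lo < hi, got {age_range}")

    rng = np.random.default_rng(seed)

    def stratified_uniform(m: int) -> np.ndarray:
        if m == 0:
            return np.empty(0)
        strata = rng.permutation(m) + rng.uniform(0.0, 1.0, size=m)
        return lo + (hi - lo) * strata / m

    ages = np.concatenate([stratified_uniform(n_hc), stratified_uniform(n_mdd)])
    sex = rng.integers(0, 2, size=n)
    group = np.array(["HC"] * n_hc + ["MDD"] * n_mdd)
    order = rng.permutation(n)
    site = np.empty(n, dtype=object)
    site[order] = [f"site{(k % n_sites) + 1}" for k in range(n)]
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{k:05d}" for k in range(n)],
            "age": ages,
            "sex": sex,
            "site": site,
            "group": group,
        }
    )


@dataclass(frozen=True)
class ThicknessParams:
    """Parameters of the thickness generator (units: mm, years).

    ``age_slope_mm_per_year`` is the central age slope applied to
    ``n_age_regions`` randomly chosen regions (each region's slope is jittered
    by a uniform factor in [0.5, 1.5] so informative features are not exact
    copies of each other); ``effect_amplitude_mm`` is the additive group
    effect in the contiguous affected cluster of ``n_affected`` regions;
    ``acceleration_years`` additionally ages the patient group along each
    region's own age slope, i.e. patients appear that many years older.
    """

    baseline_mm: float = 2.5
    baseline_sd: float = 0.25
    age_slope_mm_per_year: float = -0.01
    n_age_regions: int = 200
    effect_amplitude_mm: float = -0.2
    n_affected: int = 30
    site_shift_sd: float = 0.1
    site_scale_sd: float = 0.05
    noise_sd: float = 0.05
    acceleration_years: float = 0.0


def simulate_thickness(
    cohort: pd.DataFrame,
    geometry: ParcellationGeometry,
    params: ThicknessParams | None = None,
    seed: int = 0,
    **overrides,
) -> tuple[pd.DataFrame, TruthMap]:
    """Simulate subject x region thickness values plus the injected truth.

    The generative model per subject ``s`` and region ``r`` is::

        value[s, r] = baseline_r + slope_r * age_s
                      + effect_r * 1[group_s = MDD]
                      + slope_r * acceleration_years * 1[group_s = MDD]
                      + gamma[site_s, r] + delta[site_s, r] * eps[s, r]

    with ``eps ~ N(0, noise_sd^2)``, additive site shifts
    ``gamma ~ N(0, site_shift_sd^2)`` and multiplicative site scalings
    ``delta = exp(N(0, site_scale_sd^2))``.  Affected regions are the
    ``n_affected`` nearest neighbours (by geometry distance, including
    itself) of one randomly chosen seed region.

    Returns
    -------
    features : DataFrame indexed by subject_id, one column per region.
    truth : TruthMap
    """
    params = replace(params or ThicknessParams(), **overrides)
    n_r = geometry.n_regions
    if params.n_affected > n_r:
        raise ValueError(f"n_affected={params.n_affected} exceeds n_regions={n_r}")
    if params.n_age_regions > n_r:
        raise ValueError(f"n_age_regions={params.n_age_regions} exceeds n_regions={n_r}")
    for name in ("site_shift_sd", "site_scale_sd", "noise_sd", "baseline_sd"):
        if getattr(params, name) < 0:
            raise ValueError(f"{name} must be >= 0")
    vals = [getattr(params, f.name) for f in params.__dataclass_fields__.values()]
    if not np.all(np.isfinite(vals)):
        raise ValueError("all thickness parameters must be finite")

    rng = np.random.default_rng(seed)
    baseline = params.baseline_mm + rng.normal(0.0, params.baseline_sd, n_r)

    slope = np.zeros(n_r)
    if params.n_age_regions > 0:
        idx = rng.choice(n_r, size=params.n_age_regions, replace=False)
        slope[idx] = params.age_slope_mm_per_year * rng.uniform(
            0.5, 1.5, params.n_age_regions
        )

    effect = np.zeros(n_r)
    mask = np.zeros(n_r, dtype=bool)
    if params.n_affected > 0 and params.effect_amplitude_mm != 0.0:
        seed_region = int(rng.integers(n_r))
        nearest = np.argsort(geometry.dist[seed_region], kind="stable")[: params.n_affected]
        effect[nearest] = params.effect_amplitude_mm
        mask[nearest] = True

    ages = cohort["age"].to_numpy(dtype=float)
    is_mdd = (cohort["group"].to_numpy() == "MDD").astype(float)
    sites, site_idx = np.unique(cohort["site"].to_numpy(), return_inverse=True)
    gamma = rng.normal(0.0, params.site_shift_sd, size=(len(sites), n_r))
    delta = np.exp(rng.normal(0.0, params.site_scale_sd, size=(len(sites), n_r)))
    eps = rng.normal(0.0, params.noise_sd, size=(len(cohort), n_r))

    values = (
        baseline[None, :]
        + np.outer(ages, slope)
        + np.outer(is_mdd, effect + slope * params.acceleration_years)
        + gamma[site_idx]
        + delta[site_idx] * eps
    )
    features = pd.DataFrame(
        values, index=pd.Index(cohort["subject_id"], name="subject_id"),
        columns=geometry.region_ids,
    )
    return features, TruthMap(list(geometry.region_ids), effect, mask)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def smooth_noise_field(
    dist: np.ndarray, smoothness: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardized spatially autocorrelated field: white noise convolved with
    an exponentially distance-decaying kernel exp(-d / smoothness)."""
    noise = rng.standard_normal(dist.shape[0])
    if smoothness > 0:
        noise = np.exp(-dist / smoothness) @ noise
    return _zscore(noise)


# Default receptor/transporter battery: the nine PET/SPECT-derived maps used in
# MDD cortical-thinning association work, with target correlations to the true
# effect map mirroring the association strengths the analysis is meant to
# detect (five genuinely associated systems, four null).
DEFAULT_RECEPTOR_SPEC: list[tuple[str, float, float]] = [
    ("5-HT1a", 0.0, 0.5),
    ("5-HT1b", -0.50, 0.5),
    ("5-HT2a", -0.30, 0.5),
    ("D1", 0.0, 0.5),
    ("D2", 0.18, 0.5),
    ("DAT", 0.32, 0.5),
    ("F-DOPA", 0.0, 0.5),
    ("GABAa", 0.0, 0.5),
    ("mGluR5", -0.39, 0.5),
]


def simulate_receptor_maps(
    geometry: ParcellationGeometry,
    truth_map: TruthMap,
    spec: list[tuple[str, float, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Receptor/transporter density maps as signal + smooth-noise mixtures.

    Each map is ``rho * z(effect) + sqrt(1 - rho^2) * eta`` where ``eta`` is a
    standardized smooth noise field orthogonalized against the standardized
    effect map, so the empirical Pearson correlation with the effect map
    equals ``target_rho`` by construction.  If the truth map is constant
    (no injected effect), only ``target_rho = 0`` is meaningful and maps are
    pure smooth noise.
    """
    spec = list(DEFAULT_RECEPTOR_SPEC if spec is None else spec)
    rng = np.random.default_rng(seed)
    effect = truth_map.effect
    has_signal = effect.std() > 0
    z = _zscore(effect) if has_signal else None

    cols = {}
    for map_name, target_rho, smoothness in spec:
        if abs(target_rho) > 1:
            raise ValueError(f"|target_rho| must be <= 1, got {target_rho} for {map_name}")
        if smoothness < 0:
            raise ValueError(f"smoothness must be >= 0, got {smoothness} for {map_name}")
        eta = smooth_noise_field(geometry.dist, smoothness, rng)
        if z is None:
            if target_rho != 0:
                raise ValueError(
                    f"truth map is constant; cannot target rho={target_rho} for {map_name}"
                )
            cols[map_name] = eta
            continue
        eta = eta - (eta @ z) / (z @ z) * z  # orthogonalize against the signal
        if abs(target_rho) < 1:
            eta = _zscore(eta)
        cols[map_name] = target_rho * z + np.sqrt(1.0 - target_rho**2) * eta
    return pd.DataFrame(cols, index=pd.Index(geometry.region_ids, name="region_id"))


def simulate_expression(
    geometry: ParcellationGeometry,
    truth_map: TruthMap,
    n_genes: int = 10027,
    n_signal: int = 30,
    loading: float = 1.0,
    noise_sd: float = 0.5,
    n_terms: int = 50,
    seed: int = 0,
    noise_smoothness: float = 0.3,
) -> tuple[pd.DataFrame, list[str], GeneSetCollection]:
    """Regional gene expression with a planted signal-gene subset.

    Signal genes load on the standardized true effect map
    (``loading * z(effect) + N(0, noise_sd^2)``); the remaining genes are pure
    smooth spatial noise.  The risk-gene list contains the signal genes plus
    an equal number of decoys.  The annotation collection holds ``n_terms``
    terms; one ("enriched") term consists of all signal genes padded with 25%
    decoys, so 80% of its members are signal genes.

    Default dimensions (10027 genes on a 176-region parcellation) match an
    AHBA-style regional microarray matrix.  The planted signal-gene ids are
    carried in ``expression.attrs["signal_genes"]`` for recovery tests.
    """
    if n_signal > n_genes:
        raise ValueError(f"n_signal={n_signal} exceeds n_genes={n_genes}")
    if not np.isfinite(loading):
        raise ValueError("loading must be finite")
    rng = np.random.default_rng(seed)
    n_r = geometry.n_regions
    gene_ids = [f"GENE{k:05d}" for k in range(n_genes)]
    signal_idx = rng.choice(n_genes, size=n_signal, replace=False) if n_signal else np.array([], int)
    signal_set = set(signal_idx.tolist())

    has_signal = truth_map.effect.std() > 0
    z = _zscore(truth_map.effect) if has_signal else np.zeros(n_r)
    if n_signal > 0 and not has_signal:
        raise ValueError("cannot plant signal genes on a constant truth map")

    expr = np.empty((n_r, n_genes))
    for g in range(n_genes):
        if g in signal_set:
            expr[:, g] = loading * z + rng.normal(0.0, noise_sd, n_r)
        else:
            expr[:, g] = smooth_noise_field(geometry.dist, noise_smoothness, rng)
    expression = pd.DataFrame(
        expr, index=pd.Index(geometry.region_ids, name="region_id"), columns=gene_ids
    )
    # ground-truth labels for recovery tests, carried as table metadata
    expression.attrs["signal_genes"] = sorted(gene_ids[i] for i in signal_idx)

    non_signal = np.setdiff1d(np.arange(n_genes), signal_idx)
    decoys = rng.choice(non_signal, size=min(n_signal, non_signal.size), replace=False)
    risk_genes = sorted([gene_ids[i] for i in signal_idx] + [gene_ids[i] for i in decoys])

    categories = ["biological_process", "molecular_function", "cellular_component"]
    terms: dict[str, GeneSet] = {}
    if n_terms > 0:
        if n_signal > 0:
            n_pad = max(1, int(np.ceil(0.25 * n_signal)))
            pad = rng.choice(non_signal, size=min(n_pad, non_signal.size), replace=False)
            genes = frozenset(gene_ids[i] for i in np.concatenate([signal_idx, pad]))
        else:
            genes = frozenset(
                gene_ids[i] for i in rng.choice(n_genes, size=min(20, n_genes), replace=False)
            )
        terms["T0000"] = GeneSet("T0000", "biological_process", "biological_process", genes)
        for k in range(1, n_terms):
            size = int(rng.integers(10, 101))
            members = rng.choice(n_genes, size=min(size, n_genes), replace=False)
            terms[f"T{k:04d}"] = GeneSet(
                f"T{k:04d}",
                categories[k % 3],
                categories[k % 3],
                frozenset(gene_ids[i] for i in members),
            )
    return expression, risk_genes, GeneSetCollection(terms)
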