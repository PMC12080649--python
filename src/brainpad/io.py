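"""Tab-separated readers/writers for the pipeline's tables.

All tables are UTF-8 TSV with a header row; row order is significant and
preserved.  Floating-point values are written with 10 significant digits so
that output files (and hence run manifests) are comparable across platforms.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ParcellationGeometry, great_circle_distances

FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    write_table(cohort[["subject_id", "age", "sex", "site", "group"]], path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t")
    required = {"subject_id", "age", "sex", "site", "group"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"{path}: missing cohort column(s): {sorted(missing)}")
    return cohort


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    write_table(features.rename_axis("subject_id"), path)


def read_features(path: str | Path) -> pd.DataFrame:
    return read_table(path)


def write_geometry(geometry: ParcellationGeometry, path: str | Path) -> None:
    df = pd.DataFrame(geometry.coords, columns=["x", "y", "z"])
    df.insert(0, "region_id", geometry.region_ids)
    write_table(df, path, index=False)


def read_geometry(path: str | Path) -> ParcellationGeometry:
    df = pd.read_csv(path, sep="\t")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    coords = coords / np.linalg.norm(coords, axis=1, keepdims=True)
    return ParcellationGeometry(
        [str(r) for r in df["region_id"]], coords, great_circle_distances(coords)
    )


def write_risk_genes(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n", encoding="utf-8")


def read_risk_genes(path: str | Path) -> list[str]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip()]
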