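"""Delimited-text readers and writers for the pipeline's data formats.

Dose-response tables travel in long format (``cell_id, concentration_uM,
growth_percent, replicate``); expression matrices as a genes x samples TSV
(first column gene id, header row of sample ids) joined against a sample
sheet (``sample_id, ic50_uM, label``).  All writers produce files their
paired readers accept unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import DoseResponseTable
from .screen import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_dose_response",
    "write_dose_response",
    "read_expression",
    "write_expression",
]

_NA_TOKENS = {"", "na", "nan", "n/a", "null", "none"}


@dataclass
class PipelineConfig:
    """Thresholds, numeric settings and bookkeeping for one pipeline run."""

    threshold_uM: float = 4.0
    alpha: float = 0.01
    min_fold_change: float = 1.0
    min_r: float = 0.8
    flavor: str = "welch"
    grid_step: float = 0.01
    seed: int = 162
    bootstrap_se: bool = False
    out_prefix: str = "sixmodel"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not -1 <= self.min_r <= 1:
            raise ValueError("min_r must be in [-1, 1]")
        if self.min_fold_change <= 0:
            raise ValueError("min_fold_change must be > 0")
        if self.grid_step <= 0:
            raise ValueError("grid step must be > 0")
        if self.threshold_uM <= 0:
            raise ValueError("IC50 threshold must be > 0")

    def as_dict(self) -> dict:
        return asdict(self)


def _sep_for(path: Path, dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_dose_response(path, dialect: str = "auto") -> list[DoseResponseTable]:
    """Read a long-format dose-response file, grouped by cell_id.

    Rows with missing (NA-like) concentration or growth are dropped with a
    warning; any other non-numeric value is a parse error naming the row.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"cell_id", "concentration_uM", "growth_percent"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: header must contain {sorted(required)}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicated header columns")

    keep = np.ones(len(df), dtype=bool)
    for col in ("concentration_uM", "growth_percent"):
        raw = df[col].str.strip()
        na = raw.str.lower().isin(_NA_TOKENS)
        numeric = pd.to_numeric(raw.where(~na, "0"), errors="coerce")
        bad = numeric.isnull() & ~na
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
            raise ValueError(f"{path}: non-numeric {col} at row {row}: {raw[bad].iloc[0]!r}")
        if na.any():
            logger.warning("%s: dropping %d row(s) with missing %s", path, int(na.sum()), col)
            keep &= ~na.to_numpy()
        # a repeated header line inside the body would land here as non-numeric
    df = df[keep]
    tables = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        tables.append(
            DoseResponseTable(
                cell_id=str(cell_id),
                concentrations=pd.to_numeric(grp["concentration_uM"]).to_numpy(),
                growth=pd.to_numeric(grp["growth_percent"]).to_numpy(),
                replicate=grp["replicate"].to_numpy() if "replicate" in grp else None,
            )
        )
    return tables


def write_dose_response(tables: list[DoseResponseTable], path, dialect: str = "auto") -> None:
    path = Path(path)
    sep = _sep_for(path, dialect)
    frames = []
    for t in tables:
        frames.append(pd.DataFrame({
            "cell_id": t.cell_id,
            "concentration_uM": t.concentrations,
            "growth_percent": t.growth,
            "replicate": t.replicate if t.replicate is not None
            else np.arange(1, t.n_obs + 1),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_expression(path, sheet_path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus its sample sheet (ic50 + label per sample)."""
    path, sheet_path = Path(path), Path(sheet_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated gene ids: {dups}")
    sheet = pd.read_csv(sheet_path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    missing = [s for s in df.columns if s not in sheet.index]
    if missing:
        raise ValueError(f"{sheet_path}: samples missing from sheet: {missing}")
    sheet = sheet.loc[list(df.columns)]
    return ExpressionMatrix(
        values=df,
        ic50=pd.to_numeric(sheet["ic50_uM"]).rename("ic50_uM"),
        labels=sheet["label"].astype(str).rename("label"),
    )


def write_expression(matrix: ExpressionMatrix, path, sheet_path) -> None:
    matrix.values.to_csv(Path(path), sep="\t", index_label="gene")
    pd.DataFrame({
        "sample_id": matrix.values.columns,
        "ic50_uM": matrix.ic50.to_numpy(),
        "label": matrix.labels.to_numpy(),
    }).to_csv(Path(sheet_path), sep="\t", index=False)
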