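"""Synthetic dose-response panels and expression matrices with known truth.

The default scenario emulates a seven-cell-line melanoma panel assayed
against a cytotoxic compound: an 8-point geometric dose ladder spanning
0.02–20 uM with 3 replicate wells, true IC50s straddling the 4 uM
sensitivity threshold (4 sensitive, 3 resistant), and a ~2,000-gene log2
expression matrix with a small planted signature whose expression tracks
the IC50 profile (9 planted genes) over an uncorrelated Gaussian
background.  Every generator is a pure function of (scenario, seed), so
truth records are sufficient to score recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import DoseResponseTable, classify_sensitivity
from .logistic import LogisticParams, predict_growth
from .screen import ExpressionMatrix

__all__ = [
    "PanelScenario",
    "ExpressionScenario",
    "simulate_panel",
    "simulate_expression",
    "default_scenario",
    "DEFAULT_PLANTED_GENES",
]

#: Gene symbols used for the planted signature of the default scenario —
#: the nine validated markers of Si162 response in the melanoma panel.
DEFAULT_PLANTED_GENES = (
    "LRBA", "MGMT", "CAND1", "ADD1", "SETD2", "CNTN6", "FGF18", "C18orf25", "RPL13",
)


@dataclass
class PanelScenario:
    """Ground truth and noise model for one simulated dose-response panel."""

    cell_ids: list[str]
    true_params: list[LogisticParams]
    doses: np.ndarray
    n_replicates: int = 3
    noise_sd: float = 5.0          # percent-growth units, additive Gaussian
    heteroscedastic: bool = False  # if set, SD is noise_sd/100 * predicted growth
    seed: int = 162

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        if len(self.cell_ids) != len(self.true_params):
            raise ValueError("one LogisticParams per cell id required")
        if np.any(self.doses <= 0) or np.any(np.diff(self.doses) <= 0):
            raise ValueError("dose ladder must be strictly increasing and > 0")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate per dose")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")

    def true_ic50s(self) -> np.ndarray:
        from .logistic import invert_level
        return np.array([invert_level(p, 50.0) for p in self.true_params])


@dataclass
class ExpressionScenario:
    """Planted-signature expression matrix scenario.

    Background genes are i.i.d. Gaussian(baseline, background_sd) per
    sample.  Each planted gene is baseline + beta * zscore(IC50) plus
    Gaussian noise whose SD is calibrated so the true (population)
    correlation with the IC50 profile equals ``true_r``:
    sd = beta * sqrt(1/true_r^2 - 1).
    """

    n_genes: int = 2000
    planted_genes: tuple[str, ...] = DEFAULT_PLANTED_GENES
    beta: float = 0.5              # log2 units per SD of IC50
    true_r: float = 0.95
    planted_sd: float | None = None
    background_sd: float = 0.5
    baseline: float = 7.0          # typical log2 microarray intensity
    seed: int = 163

    def __post_init__(self) -> None:
        if len(set(self.planted_genes)) != len(self.planted_genes):
            raise ValueError("planted gene names must be distinct")
        if self.n_genes < len(self.planted_genes):
            raise ValueError("n_genes must be >= number of planted genes")
        if not 0 < self.true_r < 1:
            raise ValueError("true_r must be in (0, 1)")
        if self.planted_sd is None:
            self.planted_sd = abs(self.beta) * math.sqrt(1.0 / self.true_r**2 - 1.0)


def simulate_panel(scenario: PanelScenario) -> list[DoseResponseTable]:
    """Simulate replicated viability tables for every cell line of a scenario."""
    rng = np.random.default_rng(scenario.seed)
    doses = np.repeat(scenario.doses, scenario.n_replicates)
    reps = np.tile(np.arange(1, scenario.n_replicates + 1), scenario.doses.size)
    tables = []
    for cell_id, params in zip(scenario.cell_ids, scenario.true_params):
        clean = predict_growth(params, doses)
        if scenario.heteroscedastic:
            sd = scenario.noise_sd / 100.0 * np.abs(clean)
        else:
            sd = scenario.noise_sd
        growth = clean + rng.normal(0.0, 1.0, size=doses.shape) * sd
        tables.append(DoseResponseTable(cell_id, doses.copy(), growth, replicate=reps.copy()))
    return tables


def simulate_expression(
    ic50s, scenario: ExpressionScenario, sample_ids=None, threshold_uM: float = 4.0
) -> tuple[ExpressionMatrix, dict]:
    """Simulate a genes x samples log2 matrix with a planted IC50-tracking signature.

    Returns the matrix (with labels derived from the IC50s) and a truth
    record listing the planted genes and effect size.
    """
    ic50s = np.asarray(ic50s, dtype=float)
    n_samples = ic50s.size
    if sample_ids is None:
        sample_ids = [f"S{i+1}" for i in range(n_samples)]
    if len(sample_ids) != n_samples:
        raise ValueError("sample_ids length must match ic50s")
    rng = np.random.default_rng(scenario.seed)

    n_planted = len(scenario.planted_genes)
    gene_ids = [f"G{i:05d}" for i in range(scenario.n_genes - n_planted)]
    planted_idx = np.sort(
        rng.choice(scenario.n_genes, size=n_planted, replace=False)
    )
    names = []
    bg_iter = iter(gene_ids)
    planted_set = set(planted_idx.tolist())
    planted_iter = iter(scenario.planted_genes)
    for i in range(scenario.n_genes):
        names.append(next(planted_iter) if i in planted_set else next(bg_iter))

    z = (ic50s - ic50s.mean()) / ic50s.std(ddof=0)
    values = scenario.baseline + rng.normal(
        0.0, 1.0, size=(scenario.n_genes, n_samples)
    ) * scenario.background_sd
    noise = rng.normal(0.0, 1.0, size=(n_planted, n_samples)) * scenario.planted_sd
    values[planted_idx] = scenario.baseline + scenario.beta * z[None, :] + noise

    df = pd.DataFrame(values, index=names, columns=list(sample_ids))
    labels = pd.Series(
        [classify_sensitivity(v, threshold_uM) for v in ic50s],
        index=list(sample_ids), name="label",
    )
    matrix = ExpressionMatrix(
        values=df,
        ic50=pd.Series(ic50s, index=list(sample_ids), name="ic50_uM"),
        labels=labels,
    )
    truth = {
        "planted_genes": list(scenario.planted_genes),
        "planted_indices": planted_idx.tolist(),
        "beta": scenario.beta,
        "true_r": scenario.true_r,
        "planted_sd": scenario.planted_sd,
    }
    return matrix, truth


# Default seven-cell panel: target true IC50s (uM), 4 below / 3 above the
# 4 uM threshold, with mildly varied plateaus and Hill slopes.  The two
# groups are clearly separated (tight within-group spread relative to the
# gap), the regime in which genes tracking the IC50 profile are also
# differentially expressed between the groups.
_DEFAULT_CELLS = [
    # (cell_id, target IC50, a, d, b)
    ("M1", 0.5, 100.0, 0.0, 1.2),
    ("M21", 1.2, 98.0, 4.0, 0.9),
    ("M24", 2.0, 102.0, 2.0, 1.5),
    ("M84", 3.0, 100.0, 6.0, 1.0),
    ("M133", 8.0, 101.0, 0.0, 1.1),
    ("M2025", 9.0, 99.0, 5.0, 1.4),
    ("M307", 10.0, 100.0, 2.0, 0.8),
]


def _params_for_ic50(target: float, a: float, d: float, b: float) -> LogisticParams:
    # choose c so the curve crosses 50% growth exactly at the target dose
    c = target / ((a - d) / (50.0 - d) - 1.0) ** (1.0 / b)
    return LogisticParams(a=a, b=b, c=c, d=d)


def default_scenario(seed: int = 162) -> tuple[PanelScenario, ExpressionScenario]:
    """The seven-cell melanoma-panel study conditions with known ground truth.

    8-dose geometric ladder 0.02–20 uM, 3 replicates, additive Gaussian
    noise SD 5 percent-growth units; 2,000-gene expression matrix with the
    nine-gene planted signature at true correlation 0.95 with the IC50
    profile.
    """
    panel = PanelScenario(
        cell_ids=[c[0] for c in _DEFAULT_CELLS],
        true_params=[_params_for_ic50(*c[1:]) for c in _DEFAULT_CELLS],
        doses=np.geomspace(0.02, 20.0, 8),
        n_replicates=3,
        noise_sd=5.0,
        seed=seed,
    )
    expr = ExpressionScenario(seed=seed + 1)
    return panel, expr
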