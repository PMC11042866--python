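"""Drug-sensitivity biomarker screen on a genes x samples expression matrix.

Samples (cell lines) carry an IC50 for the compound and a sensitive/resistant
label from the 4 uM threshold.  Each gene is scored by

* an unpaired two-sample t-test between the resistant and sensitive groups
  (Welch by default; Student's pooled-variance available),
* the linear-scale fold change FC(R/S) = 2^(mean_R - mean_S) of the log2
  group means (ratio of geometric means on the intensity scale), and
* the Pearson correlation of its expression with the per-sample IC50 vector,
  with a two-sided p from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.

A gene is selected when all three thresholds are met (default p < 0.01,
FC > 1, r > 0.8).  Benjamini-Hochberg adjusted t-test p-values are reported
as an informational column; selection uses the raw p.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .fitting import RESISTANT, SENSITIVE, classify_sensitivity

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "QpcrRecord",
    "BiomarkerScreen",
    "unpaired_t_test",
    "fold_change",
    "pearson_with_p",
    "screen_biomarkers",
    "ddct_ratio",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized log2 intensities with sample metadata."""

    values: pd.DataFrame            # index: gene ids, columns: sample ids
    ic50: pd.Series                 # per-sample IC50, uM
    labels: pd.Series               # per-sample {sensitive, resistant}

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene ids: {dups}")
        if self.values.index.isnull().any() or self.values.columns.isnull().any():
            raise ValueError("gene and sample identifiers must not be missing")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression values must be finite")
        self.ic50 = self.ic50.reindex(self.values.columns)
        self.labels = self.labels.reindex(self.values.columns)
        if self.ic50.isnull().any():
            missing = self.ic50[self.ic50.isnull()].index.tolist()
            raise ValueError(f"samples missing an IC50: {missing}")
        if self.labels.isnull().any():
            missing = self.labels[self.labels.isnull()].index.tolist()
            raise ValueError(f"samples missing a label: {missing}")

    @property
    def n_genes(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class QpcrRecord:
    """Ct values for one gene: target/reference in case and calibrator samples."""

    gene: str
    ct_target_case: float
    ct_ref_case: float
    ct_target_calibrator: float
    ct_ref_calibrator: float

    def __post_init__(self) -> None:
        for f in ("ct_target_case", "ct_ref_case", "ct_target_calibrator", "ct_ref_calibrator"):
            v = getattr(self, f)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{self.gene}: {f} must be finite and > 0, got {v}")


def unpaired_t_test(group_r, group_s, flavor: str = "welch") -> float:
    """Two-sided p of an unpaired two-sample t-test (Welch or Student).

    Degenerate zero-variance inputs: equal means give p = 1; unequal means
    give p = 0 (flagged with a warning).
    """
    r = np.asarray(group_r, dtype=float)
    s = np.asarray(group_s, dtype=float)
    if r.size < 2 or s.size < 2:
        raise ValueError("each group needs at least 2 values")
    if flavor not in ("welch", "student"):
        raise ValueError(f"unknown t-test flavor {flavor!r}")
    if np.var(r) == 0 and np.var(s) == 0:
        if np.mean(r) == np.mean(s):
            return 1.0
        logger.warning("degenerate t-test: zero variance with unequal means")
        return 0.0
    res = stats.ttest_ind(r, s, equal_var=(flavor == "student"))
    return float(res.pvalue)


def fold_change(mean_log2_r: float, mean_log2_s: float) -> float:
    """Linear-scale fold change FC(R/S) from log2 group means: 2^(mR - mS)."""
    return float(2.0 ** (mean_log2_r - mean_log2_s))


def _pearson_p_from_r(r, n) -> np.ndarray:
    """Two-sided p for a sample Pearson r via the t-transform on n-2 df."""
    r = np.asarray(r, dtype=float)
    denom = np.clip(1.0 - r**2, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / denom)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return np.where(np.isfinite(r), p, np.nan)


def pearson_with_p(expr, ic50s) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided p-value.

    Returns (NaN, NaN) when either vector has zero variance.
    """
    x = np.asarray(expr, dtype=float)
    y = np.asarray(ic50s, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("both vectors must have the same length n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, float(_pearson_p_from_r(r, x.size))


def _rowwise_pearson(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson r of every row of X (genes x samples) with the vector v."""
    Xc = X - X.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    num = Xc @ vc
    den = np.sqrt((Xc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


class BiomarkerScreen(SelectorMixin, BaseEstimator):
    """Per-gene screen for markers of drug sensitivity (a feature selector).

    Follows the scikit-learn selector protocol: ``fit(X, y)`` where ``X`` is
    samples x genes and ``y`` the per-sample IC50 vector (uM); ``transform``
    keeps the selected genes.  Sample labels are derived from ``y`` with the
    IC50 threshold.

    Parameters
    ----------
    alpha : float
        Raw t-test p-value threshold (selection uses raw p, not BH-adjusted).
    min_fold_change : float
        FC(R/S) must exceed this (default 1: up-regulated in resistant).
    min_r : float
        Pearson r against the IC50 vector must exceed this.
    flavor : {"welch", "student"}
        t-test flavor.
    correlation : {"ic50", "label"}
        Correlate with the continuous IC50 vector (default) or with the
        binary label (point-biserial).
    threshold_uM : float
        IC50 threshold for labelling samples.

    Attributes
    ----------
    records_ : DataFrame
        One row per gene (t_p, t_p_bh, fc_rs, r, r_p, selected), sorted by
        descending fold change then r.
    support_ : ndarray of bool
        Selection mask in input gene order.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        min_fold_change: float = 1.0,
        min_r: float = 0.8,
        flavor: str = "welch",
        correlation: str = "ic50",
        threshold_uM: float = 4.0,
    ):
        self.alpha = alpha
        self.min_fold_change = min_fold_change
        self.min_r = min_r
        self.flavor = flavor
        self.correlation = correlation
        self.threshold_uM = threshold_uM

    def fit(self, X, y, sample_labels=None):
        if isinstance(X, pd.DataFrame):
            genes = X.columns.to_numpy()
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            M = X.to_numpy(dtype=float)
        else:
            M = np.asarray(X, dtype=float)
            genes = np.array([f"g{i}" for i in range(M.shape[1])])
        ic50 = np.asarray(y, dtype=float)
        if M.shape[0] != ic50.size:
            raise ValueError("X rows and y length must match (samples)")
        if sample_labels is not None:
            labels = np.asarray(sample_labels, dtype=object)
            if labels.size != ic50.size:
                raise ValueError("sample_labels length must match y")
        else:
            labels = np.array([classify_sensitivity(v, self.threshold_uM) for v in ic50])
        res_mask = labels == RESISTANT
        sen_mask = labels == SENSITIVE
        if res_mask.sum() < 2 or sen_mask.sum() < 2:
            raise ValueError(
                f"need >=2 samples per group, got {res_mask.sum()} resistant / "
                f"{sen_mask.sum()} sensitive"
            )

        G = M.T  # genes x samples
        R, S = G[:, res_mask], G[:, sen_mask]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_res = stats.ttest_ind(R, S, axis=1, equal_var=(self.flavor == "student"))
        t_p = np.asarray(t_res.pvalue, dtype=float)
        # degenerate zero-variance genes: equal means -> 1, unequal -> 0
        degen = (R.var(axis=1) == 0) & (S.var(axis=1) == 0)
        if degen.any():
            eq = np.isclose(R.mean(axis=1), S.mean(axis=1))
            t_p[degen & eq] = 1.0
            t_p[degen & ~eq] = 0.0

        fc = 2.0 ** (R.mean(axis=1) - S.mean(axis=1))
        target = ic50 if self.correlation == "ic50" else res_mask.astype(float)
        r = _rowwise_pearson(G, target)
        r_p = _pearson_p_from_r(r, G.shape[1])

        valid = np.isfinite(t_p)
        t_p_bh = np.full_like(t_p, np.nan)
        if valid.any():
            t_p_bh[valid] = multipletests(t_p[valid], method="fdr_bh")[1]

        selected = (
            np.nan_to_num(t_p, nan=1.0) < self.alpha
        ) & (fc > self.min_fold_change) & (np.nan_to_num(r, nan=-2.0) > self.min_r)

        records = pd.DataFrame(
            {
                "gene": genes,
                "t_p": t_p,
                "t_p_bh": t_p_bh,
                "fc_rs": fc,
                "r": r,
                "r_p": r_p,
                "selected": selected,
            }
        ).sort_values(["fc_rs", "r"], ascending=False, kind="mergesort")
        self.records_ = records.reset_index(drop=True)
        self.support_ = selected
        self.n_features_in_ = M.shape[1]
        self.labels_ = labels
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def screen_biomarkers(
    matrix: ExpressionMatrix,
    alpha: float = 0.01,
    min_fold_change: float = 1.0,
    min_r: float = 0.8,
    flavor: str = "welch",
    correlation: str = "ic50",
) -> pd.DataFrame:
    """Screen every gene of an :class:`ExpressionMatrix`; returns the records table."""
    screen = BiomarkerScreen(
        alpha=alpha,
        min_fold_change=min_fold_change,
        min_r=min_r,
        flavor=flavor,
        correlation=correlation,
    )
    screen.fit(
        matrix.values.T,
        matrix.ic50.to_numpy(),
        sample_labels=matrix.labels.to_numpy(),
    )
    logger.info(
        "screened %d genes, selected %d", matrix.n_genes, int(screen.support_.sum())
    )
    return screen.records_


def ddct_ratio(rec: QpcrRecord) -> float:
    """Relative expression by the delta-delta Ct method: 2^-(dCt_case - dCt_cal)."""
    dct_case = rec.ct_target_case - rec.ct_ref_case
    dct_cal = rec.ct_target_calibrator - rec.ct_ref_calibrator
    return float(2.0 ** (-(dct_case - dct_cal)))
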