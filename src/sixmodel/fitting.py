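"""Six-model constrained logistic fitting and IC50 model selection.

The engine fits six constrained variants of the 4PL curve (see
:mod:`sixmodel.logistic`) to one cell line's dose-response table by
unweighted nonlinear least squares on arithmetic concentration, computes six
drug-response metrics per variant (IC50/IC90/IC95, EC50, Amax, activity
area), attaches a delta-method standard error to each IC50, and reports the
IC50 of the variant whose IC50 has the lowest standard error.

Estimators follow scikit-learn conventions: ``fit(X, y)`` with fitted
attributes carrying a trailing underscore, ``get_params``/``set_params``
inherited from :class:`sklearn.base.BaseEstimator`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .logistic import (
    CANONICAL_ORDER,
    VARIANTS,
    LogisticParams,
    ModelVariant,
    activity_area,
    invert_level,
    predict_growth,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseTable",
    "ResponseMetrics",
    "LogisticCurveFit",
    "SixModelIC50",
    "fit_variant",
    "fit_six_models",
    "select_best_model",
    "classify_sensitivity",
    "ic50_gradient",
]

SENSITIVE, RESISTANT, UNCLASSIFIED = "sensitive", "resistant", "unclassified"


@dataclass
class DoseResponseTable:
    """Replicated (concentration, percent growth) observations for one cell line.

    Concentrations are in uM on the arithmetic scale; growth is percent of the
    untreated control (values outside [0, 100] are allowed — luminescence
    noise).  Replicate structure is kept as repeated concentration values.
    """

    cell_id: str
    concentrations: np.ndarray
    growth: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float).ravel()
        self.growth = np.asarray(self.growth, dtype=float).ravel()
        if self.concentrations.shape != self.growth.shape:
            raise ValueError(
                f"{self.cell_id}: concentration and growth lengths differ "
                f"({self.concentrations.size} vs {self.growth.size})"
            )
        if not np.all(np.isfinite(self.concentrations)) or np.any(self.concentrations <= 0):
            raise ValueError(f"{self.cell_id}: concentrations must be finite and > 0")
        if not np.all(np.isfinite(self.growth)):
            raise ValueError(f"{self.cell_id}: growth values must be finite")
        if np.unique(self.concentrations).size < 4:
            raise ValueError(
                f"{self.cell_id}: at least 4 distinct concentrations required, "
                f"got {np.unique(self.concentrations).size}"
            )
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate).ravel()
            if self.replicate.shape != self.growth.shape:
                raise ValueError(f"{self.cell_id}: replicate column length mismatch")

    @property
    def n_obs(self) -> int:
        return int(self.growth.size)


@dataclass(frozen=True)
class ResponseMetrics:
    """The six drug-response metrics of one fitted curve, plus the IC50 SE.

    IC-levels are the doses at which the fitted percent-growth curve crosses
    50/90/95%; they are NaN (undefined) when the level lies outside the open
    interval between the fitted plateaus.  EC50 is the dose at the midpoint
    response (a+d)/2, i.e. the fitted ``c``.  Amax = a - d.  The activity
    area sums fitted growth over the tested concentration range in 0.01 uM
    steps (smaller = more sensitive).
    """

    ic50: float
    ic90: float
    ic95: float
    ec50: float
    amax: float
    activity_area: float
    ic50_se: float
    residual_se: float

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in (
            "ic50", "ic90", "ic95", "ec50", "amax", "activity_area", "ic50_se", "residual_se")}


def ic50_gradient(params: LogisticParams, level: float, free_names: Sequence[str]) -> np.ndarray:
    """Gradient of the IC-level closed form w.r.t. the free parameters.

    With u = (a-d)/(L-d) - 1 and x = c u^(1/b):

        dx/dc = x/c
        dx/db = -x ln(u) / b^2
        dx/da = x / (b u (L-d))
        dx/dd = x (a-L) / (b u (L-d)^2)
    """
    a, b, c, d = params.a, params.b, params.c, params.d
    u = (a - d) / (level - d) - 1.0
    x = c * u ** (1.0 / b)
    partial = {
        "a": x / (b * u * (level - d)),
        "b": -x * math.log(u) / b**2,
        "c": x / c,
        "d": x * (a - level) / (b * u * (level - d) ** 2),
    }
    return np.array([partial[n] for n in free_names])


class LogisticCurveFit(RegressorMixin, BaseEstimator):
    """Least-squares fit of one constrained 4PL variant.

    Parameters
    ----------
    variant : str
        One of the six variant ids (``P3``, ``P3_TOP100``, ``P3_BOTTOM0``,
        ``P4``, ``P4_TOP100``, ``P4_BOTTOM0``).
    n_restarts : int
        Number of jittered restarts added to the deterministic start
        (a0 = max growth, d0 = min growth, c0 = geometric midpoint of the
        tested range, b0 = 1).
    seed : int
        Seed for the restart jitter.
    c_bound_factor : float
        Upper bound on ``c`` as a multiple of the highest tested dose.
    b_bounds : tuple of float
        Bounds on the Hill slope.
    grid_step : float
        Arithmetic step of the activity-area grid, uM.

    Attributes
    ----------
    params_ : LogisticParams
        Estimates with the variant's constraints imposed exactly.
    covariance_ : ndarray
        Free-parameter covariance from the linearization at the optimum,
        scaled by the residual variance RSS/dof.
    rss_, dof_, converged_ : fit diagnostics.
    metrics_ : ResponseMetrics
    """

    def __init__(
        self,
        variant: str = "P4",
        n_restarts: int = 4,
        seed: int = 162,
        c_bound_factor: float = 100.0,
        b_bounds: tuple[float, float] = (0.05, 20.0),
        grid_step: float = 0.01,
        extrapolation_factor: float = 10.0,
    ):
        self.variant = variant
        self.n_restarts = n_restarts
        self.seed = seed
        self.c_bound_factor = c_bound_factor
        self.b_bounds = b_bounds
        self.grid_step = grid_step
        self.extrapolation_factor = extrapolation_factor

    # ---- internal helpers -------------------------------------------------
    def _bounds(self, spec: ModelVariant, x_max: float):
        lo = {"a": -500.0, "b": self.b_bounds[0], "c": 1e-9, "d": -500.0}
        hi = {"a": 500.0, "b": self.b_bounds[1], "c": self.c_bound_factor * x_max, "d": 500.0}
        names = spec.free_names
        return np.array([lo[n] for n in names]), np.array([hi[n] for n in names])

    def _starts(self, spec: ModelVariant, x: np.ndarray, y: np.ndarray, lo, hi):
        base = {
            "a": float(np.max(y)),
            "d": float(np.min(y)),
            "c": float(np.sqrt(np.min(x) * np.max(x))),
            "b": 1.0,
        }
        rng = np.random.default_rng(self.seed)
        starts = [base]
        for _ in range(self.n_restarts):
            starts.append({
                "a": base["a"] + rng.normal(0.0, 10.0),
                "d": base["d"] + rng.normal(0.0, 10.0),
                "c": base["c"] * math.exp(rng.normal(0.0, 1.0)),
                "b": math.exp(rng.normal(0.0, 0.4)),
            })
        out = []
        for s in starts:
            p0 = np.array([s[n] for n in spec.free_names])
            out.append(np.clip(p0, lo + 1e-12, hi - 1e-12))
        return out

    # ---- sklearn API ------------------------------------------------------
    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        x = x.ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("X and y must have the same number of observations")
        if not np.all(np.isfinite(x)) or np.any(x < 0):
            raise ValueError("concentrations must be finite and >= 0")
        if not np.all(np.isfinite(y)):
            raise ValueError("growth values must be finite")
        if np.unique(x).size < 2:
            raise ValueError("degenerate table: at least 2 distinct concentrations needed")

        spec = VARIANTS[self.variant] if isinstance(self.variant, str) else self.variant
        if y.size < spec.n_free + 1:
            raise ValueError(
                f"variant {spec.variant_id} needs at least {spec.n_free + 1} observations"
            )

        lo, hi = self._bounds(spec, float(np.max(x)))

        def resid(theta):
            p = spec.full_params(theta)
            yhat = np.where(
                x == 0, p["a"], p["d"] + (p["a"] - p["d"]) / (1.0 + (x / p["c"]) ** p["b"])
            )
            return yhat - y

        best = None
        for p0 in self._starts(spec, x, y, lo, hi):
            try:
                res = least_squares(resid, p0, bounds=(lo, hi), method="trf")
            except Exception:  # numerical failure on one start is not fatal
                continue
            if best is None or res.cost < best.cost:
                best = res

        self.variant_ = spec
        self.x_ = x
        self.y_ = y
        self.x_min_ = float(np.min(x[x > 0])) if np.any(x > 0) else float(np.min(x))
        self.x_max_ = float(np.max(x))
        self.n_free_ = spec.n_free
        self.dof_ = int(y.size - spec.n_free)

        if best is None or not best.success or not np.all(np.isfinite(best.x)):
            self.converged_ = False
            self.params_ = None
            self.covariance_ = np.full((spec.n_free, spec.n_free), np.nan)
            self.rss_ = float("nan")
            self.metrics_ = ResponseMetrics(*([float("nan")] * 8))
            return self

        full = spec.full_params(best.x)
        self.converged_ = True
        self.params_ = LogisticParams(**full)
        self.rss_ = float(2.0 * best.cost)
        if self.dof_ >= 1:
            s2 = self.rss_ / self.dof_
        else:
            s2 = float("nan")
        # SVD-based covariance; a rank-deficient Jacobian means some free
        # parameters are unidentifiable from the data, so their uncertainty
        # is infinite (not zero, as a blind pseudo-inverse would imply)
        _, s, vt = np.linalg.svd(best.jac, full_matrices=False)
        rank = int(np.sum(s > np.finfo(float).eps * max(best.jac.shape) * s[0]))
        if rank < spec.n_free:
            self.covariance_ = np.full((spec.n_free, spec.n_free), np.inf)
        else:
            self.covariance_ = s2 * (vt.T / s**2) @ vt
        self.metrics_ = self._compute_metrics()
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        if self.params_ is None:
            raise RuntimeError("fit did not converge; no parameters to predict with")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        return predict_growth(self.params_, x.ravel())

    # ---- metrics ----------------------------------------------------------
    def _compute_metrics(self) -> ResponseMetrics:
        p = self.params_
        # an IC level whose implied dose sits far beyond the tested range is
        # an extrapolation artifact (e.g. flat viability fitted with a forced
        # zero bottom), not an estimate; mark it undefined
        limit = self.extrapolation_factor * self.x_max_

        def invert(level: float) -> float:
            v = invert_level(p, level)
            return v if v <= limit else float("nan")

        ic50 = invert(50.0)
        residual_se = math.sqrt(self.rss_ / self.dof_) if self.dof_ >= 1 else float("nan")
        if math.isnan(ic50):
            se = float("nan")
        else:
            g = ic50_gradient(p, 50.0, self.variant_.free_names)
            var = float(g @ self.covariance_ @ g)
            se = math.sqrt(max(var, 0.0)) if math.isfinite(var) else float("inf")
        return ResponseMetrics(
            ic50=ic50,
            ic90=invert(90.0),
            ic95=invert(95.0),
            ec50=p.c,  # dose at the midpoint response (a+d)/2
            amax=p.a - p.d,
            activity_area=activity_area(p, self.x_min_, self.x_max_, self.grid_step),
            ic50_se=se,
            residual_se=residual_se,
        )

    def bootstrap_ic50_se(self, n_boot: int = 1000, seed: int | None = None) -> float:
        """Parametric-bootstrap SE of the IC50 (optional cross-check mode).

        Simulates ``n_boot`` datasets from the fitted curve with Gaussian
        noise at the residual SD, refits this variant (single start at the
        fitted values), and returns the SD of the defined IC50 estimates.
        """
        check_is_fitted(self, "params_")
        if not self.converged_ or math.isnan(self.metrics_.ic50):
            return float("nan")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        spec = self.variant_
        lo, hi = self._bounds(spec, self.x_max_)
        yhat = predict_growth(self.params_, self.x_)
        sd = math.sqrt(self.rss_ / self.dof_)
        theta0 = np.clip(
            np.array([getattr(self.params_, n) for n in spec.free_names]),
            lo + 1e-12, hi - 1e-12,
        )
        x = self.x_
        ic50s = []
        for _ in range(n_boot):
            yb = yhat + rng.normal(0.0, sd, size=yhat.shape)

            def resid(theta):
                p = spec.full_params(theta)
                pred = np.where(
                    x == 0, p["a"],
                    p["d"] + (p["a"] - p["d"]) / (1.0 + (x / p["c"]) ** p["b"]),
                )
                return pred - yb

            try:
                res = least_squares(resid, theta0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if not res.success:
                continue
            est = invert_level(LogisticParams(**spec.full_params(res.x)), 50.0)
            if math.isfinite(est):
                ic50s.append(est)
        if len(ic50s) < 2:
            return float("nan")
        return float(np.std(ic50s, ddof=1))


def select_best_model(entries: Sequence[tuple[str, float, float, bool]]) -> str | None:
    """Pick the variant whose IC50 has the lowest standard error.

    ``entries`` are (variant_id, ic50, ic50_se, converged) in canonical
    order.  Variants that did not converge or whose IC50 or SE is undefined
    (NaN) are ineligible even if their residual error is smallest.  Ties go
    to the earlier canonical variant (the simpler model family first).
    Returns None when no variant is eligible.
    """
    eligible = [
        (se, CANONICAL_ORDER.index(vid), vid)
        for vid, ic50, se, converged in entries
        if converged and math.isfinite(ic50) and math.isfinite(se)
    ]
    if not eligible:
        return None
    return min(eligible)[2]


def classify_sensitivity(ic50: float, threshold: float = 4.0) -> str:
    """Label a cell line by its selected IC50 against a threshold (uM).

    IC50 below the threshold is sensitive; at or above it, resistant (the
    boundary goes to the resistant side).  An undefined IC50 (NaN) yields
    ``unclassified``.
    """
    if ic50 is None or (isinstance(ic50, float) and math.isnan(ic50)):
        return UNCLASSIFIED
    if ic50 <= 0:
        raise ValueError(f"IC50 must be > 0, got {ic50}")
    return SENSITIVE if ic50 < threshold else RESISTANT


class SixModelIC50(BaseEstimator):
    """The six-model (6M) IC50 engine.

    Fits all six constrained logistic variants to one dose-response table,
    computes the response metrics for each, and selects the variant whose
    IC50 carries the lowest standard error.  Non-convergent variants and
    variants whose fitted curve never crosses 50% growth are retained in the
    output but excluded from selection.  Ties are broken by canonical
    variant order (the simpler 3-parameter family first).

    Parameters
    ----------
    threshold_uM : float
        IC50 threshold separating sensitive from resistant cell lines.
    grid_step : float
        Activity-area grid step, uM.
    selection_criterion : {"ic50_se", "residual_se"}
        Standard error used for selection; the delta-method IC50 SE by
        default, with the residual SE of the fit as an alternative.
    se_method : {"delta", "bootstrap"}
        How the reported IC50 SE is computed.  The delta method propagates
        the free-parameter covariance through the IC50 closed form; the
        parametric bootstrap refits simulated datasets.
    """

    def __init__(
        self,
        threshold_uM: float = 4.0,
        grid_step: float = 0.01,
        n_restarts: int = 4,
        seed: int = 162,
        selection_criterion: str = "ic50_se",
        se_method: str = "delta",
        n_boot: int = 1000,
        extrapolation_factor: float = 10.0,
    ):
        self.threshold_uM = threshold_uM
        self.grid_step = grid_step
        self.n_restarts = n_restarts
        self.seed = seed
        self.selection_criterion = selection_criterion
        self.se_method = se_method
        self.n_boot = n_boot
        self.extrapolation_factor = extrapolation_factor

    def fit(self, X, y):
        fits: dict[str, LogisticCurveFit] = {}
        for vid in CANONICAL_ORDER:
            m = LogisticCurveFit(
                variant=vid,
                n_restarts=self.n_restarts,
                seed=self.seed,
                grid_step=self.grid_step,
                extrapolation_factor=self.extrapolation_factor,
            ).fit(X, y)
            fits[vid] = m
        self.fits_ = fits
        self.metrics_ = {vid: m.metrics_ for vid, m in fits.items()}

        if self.se_method == "bootstrap":
            self.bootstrap_se_ = {
                vid: m.bootstrap_ic50_se(self.n_boot, seed=self.seed + i)
                for i, (vid, m) in enumerate(fits.items())
            }

        def criterion(vid: str) -> float:
            if self.selection_criterion == "residual_se":
                return self.metrics_[vid].residual_se
            if self.se_method == "bootstrap":
                return self.bootstrap_se_[vid]
            return self.metrics_[vid].ic50_se

        self.selected_variant_ = select_best_model([
            (vid, self.metrics_[vid].ic50, criterion(vid), fits[vid].converged_)
            for vid in CANONICAL_ORDER
        ])
        if self.selected_variant_ is None:
            logger.warning("no variant yielded a defined IC50; no estimate")
            self.ic50_ = float("nan")
            self.ic50_se_ = float("nan")
        else:
            self.ic50_ = self.metrics_[self.selected_variant_].ic50
            self.ic50_se_ = criterion(self.selected_variant_)
        self.label_ = classify_sensitivity(self.ic50_, self.threshold_uM)
        return self

    def predict(self, X):
        """Predicted growth from the selected variant's curve."""
        check_is_fitted(self, "selected_variant_")
        if self.selected_variant_ is None:
            raise RuntimeError("no variant was selected; cannot predict")
        return self.fits_[self.selected_variant_].predict(X)

    def summary(self) -> dict:
        """Flat per-cell summary of the selected fit (for the TSV report)."""
        check_is_fitted(self, "selected_variant_")
        if self.selected_variant_ is None:
            out = {k: float("nan") for k in (
                "ic50", "ic50_se", "ic90", "ic95", "ec50", "amax", "activity_area")}
            out.update(selected_variant="none", label=self.label_)
            return out
        m = self.metrics_[self.selected_variant_]
        return {
            "selected_variant": self.selected_variant_,
            "ic50": m.ic50,
            "ic50_se": self.ic50_se_,
            "ic90": m.ic90,
            "ic95": m.ic95,
            "ec50": m.ec50,
            "amax": m.amax,
            "activity_area": m.activity_area,
            "label": self.label_,
        }

    def report(self) -> dict:
        """Full six-model report (per-cell JSON)."""
        check_is_fitted(self, "selected_variant_")
        per_variant = {}
        for vid in CANONICAL_ORDER:
            f = self.fits_[vid]
            per_variant[vid] = {
                "converged": bool(f.converged_),
                "params": f.params_.as_dict() if f.params_ is not None else None,
                "rss": f.rss_,
                "dof": f.dof_,
                "metrics": self.metrics_[vid].as_dict(),
            }
        return {
            "models": per_variant,
            "selected_variant": self.selected_variant_,
            "selected_ic50": self.ic50_,
            "selected_ic50_se": self.ic50_se_,
            "label": self.label_,
            "threshold_uM": self.threshold_uM,
        }


def fit_variant(table: DoseResponseTable, variant: str, **kwargs) -> LogisticCurveFit:
    """Fit one constrained variant to a dose-response table."""
    return LogisticCurveFit(variant=variant, **kwargs).fit(table.concentrations, table.growth)


def fit_six_models(table: DoseResponseTable, **kwargs) -> SixModelIC50:
    """Run the full six-model engine on one dose-response table."""
    return SixModelIC50(**kwargs).fit(table.concentrations, table.growth)
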