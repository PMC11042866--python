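"""Four-parameter logistic (4PL) dose-response curves and derived potency metrics.

The curve family is the standard 4PL on arithmetic concentration

    Y(x) = d + (a - d) / (1 + (x / c)^b)

with ``a`` the percent growth of untreated cells (top plateau), ``d`` the
percent growth at infinite dose (bottom plateau), ``c`` the dose at the
half-way response between ``a`` and ``d``, and ``b`` the Hill slope
controlling the steepness of the transition.  For a cytotoxic compound the
curve is decreasing (``a > d``, ``b > 0``).

Six constrained variants of this family are used by the model-selection
engine (:mod:`sixmodel.fitting`): the full four-parameter form, and the
reductions obtained by fixing ``b = 1`` (the "3-parameter" family),
``a = 100`` (top anchored at the untreated control) and/or ``d = 0``
(complete kill at infinite dose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "LogisticParams",
    "ModelVariant",
    "VARIANTS",
    "CANONICAL_ORDER",
    "predict_growth",
    "invert_level",
    "activity_area",
]

#: Order in which parameters are laid out whenever free parameters are vectorized.
PARAM_NAMES = ("a", "b", "c", "d")


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of one 4PL curve.

    Attributes
    ----------
    a : float
        Percent growth at zero dose (top plateau).
    b : float
        Hill slope, dimensionless, > 0 for the decreasing-viability orientation.
    c : float
        Dose at the half-way response, same units as the concentration axis (uM).
    d : float
        Percent growth at infinite dose (bottom plateau).
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"logistic parameter {name!r} must be finite, got {v}")
        if self.c <= 0:
            raise ValueError(f"half-response dose c must be > 0, got {self.c}")
        if self.b <= 0:
            raise ValueError(f"Hill slope b must be > 0, got {self.b}")

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


@dataclass(frozen=True)
class ModelVariant:
    """One constrained variant of the 4PL family.

    ``fixed`` maps parameter names to the values at which they are pinned
    during fitting; the remaining parameters are free.
    """

    variant_id: str
    fixed: Mapping[str, float]

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if n not in self.fixed)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def full_params(self, free_values: np.ndarray) -> dict[str, float]:
        """Combine free-parameter values (in PARAM_NAMES order) with the fixed ones."""
        out = dict(self.fixed)
        for name, value in zip(self.free_names, np.asarray(free_values, dtype=float)):
            out[name] = float(value)
        return out


#: The six variants, in canonical order: the 3-parameter family (Hill slope
#: fixed at 1) first, then the full 4-parameter family, each with its
#: top-anchored and bottom-anchored reductions.
VARIANTS: dict[str, ModelVariant] = {
    "P3": ModelVariant("P3", {"b": 1.0}),
    "P3_TOP100": ModelVariant("P3_TOP100", {"b": 1.0, "a": 100.0}),
    "P3_BOTTOM0": ModelVariant("P3_BOTTOM0", {"b": 1.0, "d": 0.0}),
    "P4": ModelVariant("P4", {}),
    "P4_TOP100": ModelVariant("P4_TOP100", {"a": 100.0}),
    "P4_BOTTOM0": ModelVariant("P4_BOTTOM0", {"d": 0.0}),
}

CANONICAL_ORDER: tuple[str, ...] = tuple(VARIANTS)


def _core(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    zero = x == 0
    # x -> 0 limit is a (b > 0); avoids 0**b edge handling
    out[zero] = a
    nz = ~zero
    out[nz] = d + (a - d) / (1.0 + (x[nz] / c) ** b)
    return out


def predict_growth(params: LogisticParams, x) -> np.ndarray | float:
    """Predicted percent growth at concentration ``x`` (uM, arithmetic scale).

    ``x = 0`` is handled as the zero-dose limit and returns ``a``.  Scalar in,
    scalar out; array in, array out.
    """
    if np.any(np.asarray(x, dtype=float) < 0):
        raise ValueError("concentrations must be >= 0")
    y = _core(np.atleast_1d(x), params.a, params.b, params.c, params.d)
    return float(y[0]) if np.isscalar(x) or np.ndim(x) == 0 else y


def invert_level(params: LogisticParams, level: float) -> float:
    """Concentration at which the fitted curve crosses ``level`` percent growth.

    Closed form ``x = c * ((a - d)/(level - d) - 1)^(1/b)``.  Returns NaN (the
    undefined marker) when ``level`` does not lie strictly between the two
    plateaus, in which case the curve never attains it.
    """
    a, b, c, d = params.a, params.b, params.c, params.d
    lo, hi = min(a, d), max(a, d)
    if not (lo < level < hi):
        return float("nan")
    return c * ((a - d) / (level - d) - 1.0) ** (1.0 / b)


def dose_grid(x_min: float, x_max: float, step: float = 0.01) -> np.ndarray:
    """Arithmetic concentration grid from ``x_min`` to ``x_max``, endpoints included."""
    if step <= 0:
        raise ValueError("grid step must be > 0")
    if x_max < x_min:
        raise ValueError("x_max must be >= x_min")
    n = int(round((x_max - x_min) / step))
    grid = x_min + step * np.arange(n + 1)
    if grid[-1] < x_max - step * 1e-9:  # guard against float truncation
        grid = np.append(grid, x_max)
    return grid


def activity_area(params: LogisticParams, x_min: float, x_max: float, step: float = 0.01) -> float:
    """Sum of predicted percent growth over the arithmetic dose grid.

    The grid runs from the lowest to the highest tested concentration in
    steps of ``step`` (default 0.01 uM), endpoints included.  Summing
    viability means a *smaller* activity area indicates a more sensitive
    cell line.
    """
    return float(np.sum(predict_growth(params, dose_grid(x_min, x_max, step))))
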