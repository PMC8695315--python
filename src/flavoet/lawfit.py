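"""Least-squares fitting of the three empirical electron-transfer laws.

* SEGL — energy gap law: ln Rate vs -SFEG, downward parabola; its vertex
  X_m(ES) locates the crossover from the normal to the energy-inverted region.
* EXDL — extended Dutton law: ln Rate vs donor-acceptor distance Rc;
  parabolic for ultrafast donors (vertex X_m(Rc)), linear (classical Dutton
  decay) for slower ones, sometimes no clear relation.
* ESRC — empirical linear relation between -SFEG and Rc; it maps peaks
  between the distance and energy axes.

All fits are unweighted ordinary least squares. Display rounding to the two
decimals used in reports happens only in presentation code; every value here
is full precision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FitError",
    "LawClass",
    "ParabolicFit",
    "LinearFit",
    "RegionPartition",
    "fit_parabola",
    "fit_line",
    "peak_location",
    "classify_relationship",
    "region_partition",
    "determination_coefficient",
]


class FitError(ValueError):
    """Degenerate or undefined fit (rank deficiency, zero variance, ...)."""


class LawClass(str, enum.Enum):
    """Shape class of an observed ln Rate vs Rc (or vs -SFEG) relation."""

    PARABOLIC = "parabolic"
    LINEAR = "linear"
    NONE = "none"


@dataclass
class ParabolicFit:
    """Quadratic OLS fit y = a x^2 + b x + c with peak location -b/(2a).

    ``x_peak`` is populated only for a downward parabola (a < 0); an upward
    curvature leaves it ``None`` with ``upward=True``.
    """

    a: float
    b: float
    c: float
    r2: float
    law: str = "SEGL"
    x_peak: float | None = field(default=None)
    upward: bool = False

    def __post_init__(self) -> None:
        if self.x_peak is None and self.a != 0:
            if self.a < 0:
                self.x_peak = peak_location(self.a, self.b)
            else:
                self.upward = True

    def __call__(self, x):
        return self.a * np.asarray(x) ** 2 + self.b * np.asarray(x) + self.c

    def to_record(self) -> dict:
        return {
            "law": self.law,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "r2": self.r2,
            "x_peak": self.x_peak,
        }


@dataclass
class LinearFit:
    """Linear OLS fit y = slope x + intercept."""

    slope: float
    intercept: float
    r2: float
    law: str = "ESRC"

    def __call__(self, x):
        return self.slope * np.asarray(x) + self.intercept

    def to_record(self) -> dict:
        return {
            "law": self.law,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
        }


@dataclass
class RegionPartition:
    """Snapshot split into inverted/normal regions about a peak threshold.

    On the energy axis a snapshot is inverted when -SFEG exceeds X_m(ES);
    on the distance axis when Rc falls below X_m(Rc). Values equal to the
    threshold count as normal.
    """

    axis: str
    threshold: float
    labels: np.ndarray  # True = inverted

    @property
    def fraction_inverted(self) -> float:
        return float(np.mean(self.labels))

    @property
    def fraction_normal(self) -> float:
        return 1.0 - self.fraction_inverted


def determination_coefficient(y, y_hat) -> float:
    """R^2 = 1 - SS_res/SS_tot; 1 for a perfect fit, negative for fits worse
    than the mean. Errors on zero variance in ``y``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise FitError("y and y_hat must have equal length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise FitError("R^2 undefined: zero variance in y")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def _ols(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise FitError("rank-deficient design (too few distinct x values)")
    return coef


def fit_parabola(x, y, law: str = "SEGL") -> ParabolicFit:
    """Ordinary least-squares quadratic fit.

    Requires at least three points with three distinct x values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.unique(x).size < 3:
        raise FitError("parabola fit needs >= 3 points with >= 3 distinct x values")
    design = np.column_stack([x**2, x, np.ones_like(x)])
    a, b, c = map(float, _ols(design, y))
    r2 = determination_coefficient(y, design @ [a, b, c]) if np.ptp(y) > 0 else 1.0
    return ParabolicFit(a=a, b=b, c=c, r2=r2, law=law)


def fit_line(x, y, law: str = "ESRC") -> LinearFit:
    """Ordinary least-squares straight-line fit (>= 2 distinct x values)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise FitError("line fit needs >= 2 points with >= 2 distinct x values")
    design = np.column_stack([x, np.ones_like(x)])
    slope, intercept = map(float, _ols(design, y))
    r2 = determination_coefficient(y, design @ [slope, intercept]) if np.ptp(y) > 0 else 1.0
    return LinearFit(slope=slope, intercept=intercept, r2=r2, law=law)


def peak_location(a: float, b: float) -> float:
    """Vertex abscissa -b/(2a) of y = a x^2 + b x + c.

    Errors when a = 0 (no peak). For a > 0 the parabola opens upward; the
    stationary point is still returned, callers should treat it as a minimum.
    """
    if a == 0:
        raise FitError("peak undefined for a = 0")
    return -b / (2.0 * a)


@dataclass
class Classification:
    """Outcome of the parabola-vs-line shape test with both candidate fits."""

    law_class: LawClass
    parabola: ParabolicFit | None
    line: LinearFit | None
    p_quadratic: float | None = None


def classify_relationship(
    x,
    y,
    alpha: float = 0.05,
    linear_r2_min: float = 0.2,
    law: str = "EXDL",
) -> Classification:
    """Classify a relation as parabolic, linear, or no clear relation.

    Fits both a line and a parabola. The relation is *parabolic* when the
    quadratic term is significant (partial F-test at ``alpha``), curvature is
    downward, and the vertex lies within the observed x range extended by
    half its width on both sides (a peak the data can actually see).
    Otherwise *linear* when the line's R^2 >= ``linear_r2_min``, else *none*.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise FitError("classification needs >= 4 points")
    line = fit_line(x, y, law=f"{law}-linear")
    par = fit_parabola(x, y, law=law)
    n = x.size
    sse_lin = float(np.sum((y - line(x)) ** 2))
    sse_par = float(np.sum((y - par(x)) ** 2))
    df_res = n - 3
    if sse_par <= 0:
        p = 0.0 if sse_lin > sse_par else 1.0
    else:
        f_stat = (sse_lin - sse_par) / (sse_par / df_res)
        p = float(stats.f.sf(max(f_stat, 0.0), 1, df_res))
    lo, hi = float(x.min()), float(x.max())
    half_width = (hi - lo) / 2.0
    vertex_visible = (
        par.x_peak is not None
        and (lo - half_width) <= par.x_peak <= (hi + half_width)
    )
    if p < alpha and par.a < 0 and vertex_visible:
        cls = LawClass.PARABOLIC
    elif line.r2 >= linear_r2_min:
        cls = LawClass.LINEAR
    else:
        cls = LawClass.NONE
    return Classification(law_class=cls, parabola=par, line=line, p_quadratic=p)


def region_partition(values, threshold: float, axis: str) -> RegionPartition:
    """Split snapshot values into inverted/normal regions about ``threshold``.

    axis="energy": values are -SFEG, inverted when value > X_m(ES).
    axis="distance": values are Rc, inverted when value < X_m(Rc).
    Ties at the threshold count as normal.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise FitError("region partition of an empty value list")
    if not np.isfinite(threshold):
        raise FitError("threshold must be finite")
    if axis == "energy":
        labels = values > threshold
    elif axis == "distance":
        labels = values < threshold
    else:
        raise ValueError(f"axis must be 'energy' or 'distance', got {axis!r}")
    return RegionPartition(axis=axis, threshold=float(threshold), labels=labels)
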