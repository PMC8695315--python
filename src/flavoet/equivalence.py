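"""Peak equivalence between the energy-gap and donor-acceptor-distance axes.

The energy gap law locates a rate maximum at -SFEG = X_m(ES); the extended
Dutton law locates one at Rc = X_m(Rc). Because -SFEG is, empirically, close
to linear in Rc (the ESRC relation -SFEG = B Rc + C), a distance peak maps
onto the energy axis as X_m(ESRc) = B X_m(Rc) + C. Agreement between
X_m(ES) and X_m(ESRc) demonstrates that the energy-inverted region and the
distance-inverted region are the same phenomenon seen along two axes.

For donors whose ln Rate falls *linearly* with Rc (classical Dutton
behaviour), no distance peak is observed; the implied X_m(Rc) is instead
back-evaluated by inverting the ESRC line at the energy-axis peak,
X_m(Rc) = (X_m(ES) - C)/B, and flagged as an extrapolation when it falls
below the observed Rc range.

No intermediate value is ever rounded: display rounding to the two decimals
of the report tables happens only at serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import DonorSeries
from .lawfit import (
    Classification,
    FitError,
    LawClass,
    LinearFit,
    classify_relationship,
    fit_line,
    fit_parabola,
)

__all__ = [
    "EquivalenceRecord",
    "xm_esrc",
    "xm_rc_from_es",
    "compare_peaks",
    "donor_equivalence_report",
]

#: Default agreement tolerance |X_m(ES) - X_m(ESRc)|, eV.
DEFAULT_TOL_EV = 0.10


@dataclass
class EquivalenceRecord:
    """Per-donor comparison of energy-axis and distance-axis rate peaks."""

    protein: str
    donor: str
    subunit: str
    wavelength: float | None
    exdl_class: str
    xm_es: float | None = None
    xm_rc: float | None = None
    xm_esrc: float | None = None
    abs_diff: float | None = None
    agrees: bool | None = None
    extrapolated: bool = False
    tol: float = DEFAULT_TOL_EV

    def to_record(self) -> dict:
        return asdict(self)


def xm_esrc(esrc: LinearFit, xm_rc: float) -> float:
    """Map a distance-axis peak onto the energy axis through the ESRC line:
    X_m(ESRc) = slope * X_m(Rc) + intercept."""
    return esrc.slope * xm_rc + esrc.intercept


def xm_rc_from_es(esrc: LinearFit, xm_es: float) -> float:
    """Invert the ESRC line at an energy-axis peak: (X_m(ES) - C)/B.

    The *unrounded* X_m(ES) must be supplied; rounding first displaces the
    result by far more than the display precision because |B| is small.
    """
    if esrc.slope == 0:
        raise FitError("cannot invert ESRC line with zero slope")
    return (xm_es - esrc.intercept) / esrc.slope


def compare_peaks(xm_es: float, xm_esrc_val: float, tol: float = DEFAULT_TOL_EV):
    """Absolute discrepancy between the two energy-axis peak estimates and
    whether they agree within ``tol`` (eV)."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    abs_diff = abs(xm_es - xm_esrc_val)
    return abs_diff, abs_diff <= tol


def donor_equivalence_report(
    series: DonorSeries,
    tol: float = DEFAULT_TOL_EV,
    alpha: float = 0.05,
    linear_r2_min: float = 0.2,
    rc_cutoff: float | None = None,
) -> EquivalenceRecord:
    """Run the full three-law analysis on one donor series.

    The series must have ``dg0`` and ``ln_rate`` populated on every snapshot
    (see :func:`flavoet.core.trajectory_rates`). ``rc_cutoff`` optionally
    restricts the ESRC fit to snapshots with Rc below the cutoff, for donors
    sampling two conformations.

    Workflow: fit the energy gap law (parabola of ln Rate vs -SFEG) for
    X_m(ES); classify the distance law; if parabolic take X_m(Rc) from its
    vertex and map it through the ESRC line to X_m(ESRc); if linear
    back-evaluate X_m(Rc) from X_m(ES) instead and flag it as extrapolated
    when it falls below the observed Rc range.
    """
    rc = series.column("rc")
    neg_sfeg = series.neg_sfeg
    lnk = series.column("ln_rate")
    if np.any(~np.isfinite(neg_sfeg)) or np.any(~np.isfinite(lnk)):
        raise FitError(
            f"{series.protein}/{series.donor}{series.subunit}: series has "
            "missing dg0 or ln_rate; run trajectory_rates first"
        )

    try:
        segl = fit_parabola(neg_sfeg, lnk, law="SEGL")
        exdl: Classification = classify_relationship(
            rc, lnk, alpha=alpha, linear_r2_min=linear_r2_min, law="EXDL"
        )
        if rc_cutoff is not None:
            keep = rc < rc_cutoff
            esrc = fit_line(rc[keep], neg_sfeg[keep], law="ESRC")
        else:
            esrc = fit_line(rc, neg_sfeg, law="ESRC")
    except FitError as exc:
        raise FitError(
            f"{series.protein}/{series.donor}{series.subunit}: {exc}"
        ) from exc

    rec = EquivalenceRecord(
        protein=series.protein,
        donor=series.donor,
        subunit=series.subunit,
        wavelength=series.wavelength,
        exdl_class=exdl.law_class.value,
        xm_es=segl.x_peak,
        tol=tol,
    )
    if segl.x_peak is None:
        return rec

    if exdl.law_class is LawClass.PARABOLIC and exdl.parabola.x_peak is not None:
        rec.xm_rc = exdl.parabola.x_peak
        rec.xm_esrc = xm_esrc(esrc, rec.xm_rc)
        rec.abs_diff, rec.agrees = compare_peaks(rec.xm_es, rec.xm_esrc, tol)
    elif exdl.law_class is LawClass.LINEAR:
        rec.xm_rc = xm_rc_from_es(esrc, rec.xm_es)
        rec.extrapolated = rec.xm_rc < float(rc.min())
    return rec
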