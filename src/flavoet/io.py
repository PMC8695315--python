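"""Snapshot-table CSV format, run configuration and report serialization.

The interchange format is a flat CSV, one row per MD snapshot::

    protein,donor,subunit,wavelength_nm,time_ps,rc_nm,neg_sfeg_ev,lambda_ev,ln_rate

``wavelength_nm``, ``lambda_ev`` and ``ln_rate`` are optional; missing
energies are computed downstream once ET parameters are supplied. Rows are
grouped into one :class:`~flavoet.core.DonorSeries` per distinct
(protein, donor, subunit, wavelength) and ordered by ``time_ps``.

All numeric I/O preserves full precision; the two-decimal columns in report
files are display-only extras alongside the full-precision fields.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DonorSeries, ETParameters, Snapshot
from .synthetic import TrajectorySpec

__all__ = [
    "read_snapshot_csv",
    "write_snapshot_csv",
    "write_report",
    "read_report",
    "RunConfig",
    "load_run_config",
]

logger = logging.getLogger("flavoet")

REQUIRED_COLUMNS = ("protein", "donor", "subunit", "time_ps", "rc_nm", "neg_sfeg_ev")
OPTIONAL_COLUMNS = ("wavelength_nm", "lambda_ev", "ln_rate")

#: Donor-acceptor distances outside this window trigger a unit-sanity warning.
RC_PLAUSIBLE_NM = (0.1, 5.0)


def read_snapshot_csv(path: str | Path) -> list[DonorSeries]:
    """Read a snapshot CSV into donor series grouped by identity columns.

    Raises on an empty or header-less file and on malformed rows (with the
    file line number); implausible distances only warn.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty snapshot file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no snapshot rows")
    for col in ("time_ps", "rc_nm", "neg_sfeg_ev", "lambda_ev", "ln_rate"):
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}:{line}: malformed value in column {col!r}")
        df[col] = coerced
    if (df["rc_nm"] <= 0).any():
        line = int((df["rc_nm"] <= 0).idxmax()) + 2
        raise ValueError(f"{path}:{line}: rc_nm must be > 0")
    if not df["neg_sfeg_ev"].apply(math.isfinite).all():
        raise ValueError(f"{path}: non-finite neg_sfeg_ev value")
    outside = (df["rc_nm"] < RC_PLAUSIBLE_NM[0]) | (df["rc_nm"] > RC_PLAUSIBLE_NM[1])
    if outside.any():
        logger.warning(
            "%s: %d snapshot(s) with rc_nm outside the plausible %s nm window — "
            "check units", path, int(outside.sum()), RC_PLAUSIBLE_NM
        )
    if "wavelength_nm" not in df.columns:
        df["wavelength_nm"] = np.nan

    series_list: list[DonorSeries] = []
    for (protein, donor, subunit, wl), grp in df.groupby(
        ["protein", "donor", "subunit", "wavelength_nm"], dropna=False, sort=True
    ):
        grp = grp.sort_values("time_ps")
        snaps = [
            Snapshot(
                t=float(r.time_ps),
                rc=float(r.rc_nm),
                dg0=-float(r.neg_sfeg_ev),
                lam=None if "lambda_ev" not in grp.columns or pd.isna(r.lambda_ev) else float(r.lambda_ev),
                ln_rate=None if "ln_rate" not in grp.columns or pd.isna(r.ln_rate) else float(r.ln_rate),
            )
            for r in grp.itertuples()
        ]
        series_list.append(
            DonorSeries(
                protein=str(protein),
                donor=str(donor),
                subunit=str(subunit),
                wavelength=None if pd.isna(wl) else float(wl),
                snapshots=snaps,
            )
        )
    return series_list


def write_snapshot_csv(series_list: list[DonorSeries], path: str | Path) -> None:
    """Write donor series to the snapshot CSV format at full precision."""
    rows = []
    for s in series_list:
        for snap in s.snapshots:
            rows.append(
                {
                    "protein": s.protein,
                    "donor": s.donor,
                    "subunit": s.subunit,
                    "wavelength_nm": s.wavelength,
                    "time_ps": repr(snap.t),
                    "rc_nm": repr(snap.rc),
                    "neg_sfeg_ev": "" if snap.dg0 is None else repr(-snap.dg0),
                    "lambda_ev": "" if snap.lam is None else repr(snap.lam),
                    "ln_rate": "" if snap.ln_rate is None else repr(snap.ln_rate),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


_DISPLAY_FIELDS = ("xm_es", "xm_rc", "xm_esrc", "abs_diff")


def _as_dict(record) -> dict:
    return record.to_record() if hasattr(record, "to_record") else dict(record)


def write_report(records: list, path: str | Path, format: str = "csv") -> None:
    """Serialize analysis records to CSV or JSON.

    Full-precision numbers are written as-is (``repr`` round-trippable in
    CSV); for the peak fields a two-decimal ``*_display`` column mirrors the
    precision of the published tables. An empty record list yields a
    header-only CSV / empty JSON array.
    """
    recs = [_as_dict(r) for r in records]
    for r in recs:
        for f in _DISPLAY_FIELDS:
            if f in r:
                r[f"{f}_display"] = None if r[f] is None else f"{r[f]:.2f}"
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(recs, indent=2) + "\n")
    elif format == "csv":
        if recs:
            df = pd.DataFrame(recs)
            for col in df.columns:
                if df[col].dtype == float:
                    df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(v))
            df.to_csv(path, index=False)
        else:
            cols = ["protein", "donor", "subunit", "wavelength", "exdl_class",
                    "xm_es", "xm_rc", "xm_esrc", "abs_diff", "agrees",
                    "extrapolated", "tol"]
            path.write_text(",".join(cols) + "\n")
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")


def read_report(path: str | Path) -> list[dict]:
    """Read a report back (JSON or CSV) as a list of dicts."""
    path = Path(path)
    if path.suffix == ".json":
        return json.loads(path.read_text())
    df = pd.read_csv(path)
    return df.where(pd.notna(df), None).to_dict(orient="records")


@dataclass
class FitOptions:
    """Classification thresholds and the peak-agreement tolerance."""

    alpha: float = 0.05
    linear_r2_min: float = 0.2
    tol_ev: float = 0.10
    rc_cutoff_nm: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.tol_ev <= 0:
            raise ValueError(f"tol_ev must be > 0, got {self.tol_ev}")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run.

    Sections: ``parameters`` (ET parameters with unit-suffixed keys),
    ``trajectory`` (synthetic-generator spec), ``fit`` (thresholds), and a
    top-level ``seed``. Unknown sections or keys are rejected.
    """

    parameters: ETParameters = field(default_factory=ETParameters)
    trajectory: TrajectorySpec | None = None
    fit: FitOptions = field(default_factory=FitOptions)
    seed: int | None = None


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or TOML run configuration."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    else:
        raw = json.loads(path.read_text())
    known = {"parameters", "trajectory", "fit", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections/keys: {sorted(unknown)}")
    params = ETParameters.from_unit_keys(raw.get("parameters", {}))
    traj = None
    if "trajectory" in raw:
        traj_kwargs = dict(raw["trajectory"])
        if "seed" not in traj_kwargs and raw.get("seed") is not None:
            traj_kwargs["seed"] = raw["seed"]
        traj = TrajectorySpec(**traj_kwargs)
    fit = FitOptions(**raw.get("fit", {}))
    return RunConfig(parameters=params, trajectory=traj, fit=fit, seed=raw.get("seed"))
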