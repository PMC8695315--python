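"""Marcus-Kakitani-Mataga (MKM) photoinduced electron-transfer rate model.

The reaction modelled is photoinduced electron transfer from an aromatic
donor (typically a tryptophan side chain) to the photoexcited isoalloxazine
ring of a flavin cofactor::

    Iso* + Trp  ->  Iso- + Trp+        (standard free-energy gap dG0)

The rate for a single molecular-dynamics snapshot is

    k = nu0 / (1 + exp[beta (Rc - R0)]) * exp[ -(dG0 + lambda)^2 / (4 lambda kB T) ]

in ps^-1, where Rc is the donor-acceptor distance (nm), the sigmoidal factor
gates the adiabatic (Rc < R0) to nonadiabatic (Rc > R0) crossover, and the
Gaussian factor is the classical Marcus Franck-Condon term with solvent
reorganization energy lambda (eV).

All quantities use eV / nm / ps / K throughout; unit conversion belongs at
I/O boundaries only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import BOLTZMANN_EV_PER_K, COULOMB_EV_NM, DEFAULT_TEMPERATURE_K

__all__ = [
    "ETParameters",
    "ChargeSite",
    "SnapshotGeometry",
    "Snapshot",
    "DonorSeries",
    "reorganization_energy",
    "coulomb_pair_energy",
    "net_electrostatic_energy",
    "free_energy_gap",
    "et_rate",
    "ln_rate",
    "trajectory_rates",
]


class DomainError(ValueError):
    """A physical-domain precondition was violated (non-positive distance, ...)."""


@dataclass(frozen=True)
class ETParameters:
    """All parameters of the MKM rate expression for one donor-acceptor system.

    The default numbers are illustrative placeholders for exercising the
    model, not values determined for any particular flavoprotein.

    Parameters
    ----------
    nu0 : float
        Frequency prefactor, ps^-1.
    beta : float
        Distance decay coefficient of the adiabatic/nonadiabatic gate, nm^-1.
    r0 : float
        Critical adiabatic <-> nonadiabatic crossover distance, nm.
    eps_da : float
        Static dielectric constant between donor and acceptor (>= 1).
    eps_static : float
        Bulk static dielectric constant entering the reorganization energy.
    eps_optical : float
        Optical dielectric constant (< eps_static).
    a_donor, a_acceptor : float
        Effective spherical radii of donor and acceptor, nm.
    temperature : float
        Absolute temperature, K.
    e_ip : float
        Donor ionization potential, eV.
    e_ea : float
        Acceptor (Iso*) electron affinity, eV; may be shifted to model the
        emission-wavelength dependence of the accepting state.
    """

    nu0: float = 1000.0
    beta: float = 14.0
    r0: float = 0.6
    eps_da: float = 2.0
    eps_static: float = 5.0
    eps_optical: float = 2.0
    a_donor: float = 0.25
    a_acceptor: float = 0.25
    temperature: float = DEFAULT_TEMPERATURE_K
    e_ip: float = 7.2
    e_ea: float = 6.5

    def __post_init__(self) -> None:
        if self.nu0 <= 0:
            raise DomainError(f"nu0 must be > 0, got {self.nu0}")
        if self.beta <= 0:
            raise DomainError(f"beta must be > 0, got {self.beta}")
        for name in ("r0", "a_donor", "a_acceptor"):
            v = getattr(self, name)
            if v <= 0:
                raise DomainError(f"{name} must be > 0, got {v}")
        if self.eps_da < 1:
            raise DomainError(f"eps_da must be >= 1, got {self.eps_da}")
        if not self.eps_optical < self.eps_static:
            raise DomainError(
                f"eps_optical ({self.eps_optical}) must be < eps_static ({self.eps_static})"
            )
        if self.temperature <= 0:
            raise DomainError(f"temperature must be > 0, got {self.temperature}")

    @property
    def kbt(self) -> float:
        """Thermal energy k_B T in eV."""
        return BOLTZMANN_EV_PER_K * self.temperature

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ETParameters":
        return cls(**d)

    @classmethod
    def from_config(cls, path: str | Path) -> "ETParameters":
        """Load parameters from a JSON/TOML config with unit-suffixed keys.

        Recognised keys: nu0_per_ps, beta_per_nm, r0_nm, eps_da, eps_static,
        eps_optical, a_donor_nm, a_acceptor_nm, temperature_k, e_ip_ev,
        e_ea_ev. Unknown keys are rejected.
        """
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(path.read_text())
        else:
            raw = json.loads(path.read_text())
        return cls.from_unit_keys(raw)

    _UNIT_KEYS = {
        "nu0_per_ps": "nu0",
        "beta_per_nm": "beta",
        "r0_nm": "r0",
        "eps_da": "eps_da",
        "eps_static": "eps_static",
        "eps_optical": "eps_optical",
        "a_donor_nm": "a_donor",
        "a_acceptor_nm": "a_acceptor",
        "temperature_k": "temperature",
        "e_ip_ev": "e_ip",
        "e_ea_ev": "e_ea",
    }

    @classmethod
    def from_unit_keys(cls, raw: dict) -> "ETParameters":
        unknown = set(raw) - set(cls._UNIT_KEYS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{cls._UNIT_KEYS[k]: float(v) for k, v in raw.items()})

    def to_unit_keys(self) -> dict:
        inv = {v: k for k, v in self._UNIT_KEYS.items()}
        return {inv[k]: v for k, v in self.to_dict().items()}


@dataclass(frozen=True)
class ChargeSite:
    """A point charge in the protein environment (positions in nm, charge in e)."""

    position: tuple[float, float, float]
    charge: float
    label: str = ""

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise DomainError(f"non-finite position for charge site {self.label!r}")
        if not math.isfinite(self.charge):
            raise DomainError(f"non-finite charge for site {self.label!r}")


@dataclass(frozen=True)
class SnapshotGeometry:
    """Donor/acceptor centers, their separation and surrounding point charges."""

    rc: float
    donor_center: tuple[float, float, float] | None = None
    acceptor_center: tuple[float, float, float] | None = None
    charges: tuple[ChargeSite, ...] = ()

    def __post_init__(self) -> None:
        if self.rc <= 0:
            raise DomainError(f"rc must be > 0, got {self.rc}")
        if self.donor_center is not None and self.acceptor_center is not None:
            sep = math.dist(self.donor_center, self.acceptor_center)
            if not math.isclose(sep, self.rc, rel_tol=1e-6, abs_tol=1e-9):
                raise DomainError(
                    f"rc={self.rc} inconsistent with center separation {sep:.6g}"
                )


@dataclass
class Snapshot:
    """One MD time point: distance, free-energy gap, reorganization energy, rate.

    ``dg0`` is the standard free-energy gap dG0(t) in eV (negative when ET is
    favourable); ``lam`` and ``ln_rate`` may be absent until filled by
    :func:`trajectory_rates`.
    """

    t: float
    rc: float
    dg0: float | None = None
    lam: float | None = None
    ln_rate: float | None = None

    def __post_init__(self) -> None:
        if self.rc <= 0:
            raise DomainError(f"rc must be > 0, got {self.rc}")
        if self.lam is not None and self.lam <= 0:
            raise DomainError(f"lam must be > 0, got {self.lam}")


@dataclass
class DonorSeries:
    """An ordered snapshot series for one donor in one subunit.

    ``wavelength`` tags the emission wavelength (nm) when the underlying
    fluorescence component is wavelength-resolved, else ``None``.
    """

    protein: str
    donor: str
    subunit: str
    snapshots: list[Snapshot] = field(default_factory=list)
    wavelength: float | None = None

    def __len__(self) -> int:
        return len(self.snapshots)

    def column(self, name: str) -> np.ndarray:
        """Extract one snapshot attribute as a float array (None -> nan)."""
        vals = [getattr(s, name) for s in self.snapshots]
        return np.array([np.nan if v is None else v for v in vals], dtype=float)

    @property
    def neg_sfeg(self) -> np.ndarray:
        """-dG0(t), the axis against which the energy gap law is plotted."""
        return -self.column("dg0")


# ---------------------------------------------------------------------------
# model operations


def reorganization_energy(rc, params: ETParameters):
    """Marcus two-sphere solvent reorganization energy, eV.

    lambda = C_e (1/(2 a_D) + 1/(2 a_A) - 1/Rc)(1/eps_opt - 1/eps_static)

    Accepts a scalar or array ``rc`` (nm). Strictly increasing in Rc, and
    positive whenever the spheres do not engulf the gap and the Pekar factor
    is positive.
    """
    rc = np.asarray(rc, dtype=float)
    if np.any(rc <= 0):
        raise DomainError("rc must be > 0")
    pekar = 1.0 / params.eps_optical - 1.0 / params.eps_static
    geom = 1.0 / (2 * params.a_donor) + 1.0 / (2 * params.a_acceptor) - 1.0 / rc
    lam = COULOMB_EV_NM * geom * pekar
    return lam if lam.ndim else float(lam)


def coulomb_pair_energy(rc, eps_da: float):
    """Magnitude of the donor-cation / acceptor-anion Coulomb attraction, eV.

    Returns C_e / (eps_da Rc); the stabilizing (negative) sign with which it
    enters dG0 is applied by :func:`free_energy_gap`.
    """
    rc = np.asarray(rc, dtype=float)
    if np.any(rc <= 0):
        raise DomainError("rc must be > 0")
    if eps_da < 1:
        raise DomainError(f"eps_da must be >= 1, got {eps_da}")
    e = COULOMB_EV_NM / (eps_da * rc)
    return e if e.ndim else float(e)


def net_electrostatic_energy(geom: SnapshotGeometry, eps_net: float) -> float:
    """Electrostatic energy between the photo-generated ion pair and protein charges.

    E_net = sum_j C_e q_j [ -1/(eps |r_j - r_A|) + 1/(eps |r_j - r_D|) ]

    i.e. each protein charge interacts with the acceptor anion (-1 e) and the
    donor cation (+1 e). Zero for an empty charge list.
    """
    if not geom.charges:
        return 0.0
    if geom.donor_center is None or geom.acceptor_center is None:
        raise DomainError("net_electrostatic_energy requires donor and acceptor centers")
    r_d = np.asarray(geom.donor_center)
    r_a = np.asarray(geom.acceptor_center)
    total = 0.0
    for site in geom.charges:
        r_j = np.asarray(site.position)
        d_a = float(np.linalg.norm(r_j - r_a))
        d_d = float(np.linalg.norm(r_j - r_d))
        if d_a == 0.0 or d_d == 0.0:
            raise DomainError(
                f"charge site {site.label!r} coincides with donor or acceptor center"
            )
        total += COULOMB_EV_NM * site.charge * (-1.0 / (eps_net * d_a) + 1.0 / (eps_net * d_d))
    return total


def free_energy_gap(
    geom: SnapshotGeometry, params: ETParameters, eps_net: float | None = None
) -> float:
    """Standard free-energy gap dG0(t) of Iso* + donor -> Iso- + donor+, eV.

    dG0 = (E_IP - E_EA) - C_e/(eps_da Rc) + E_net

    The ion-pair Coulomb term stabilizes the products (lowers dG0); in the
    large-Rc, no-charge limit dG0 reduces to the electronic gap E_IP - E_EA.
    """
    if eps_net is None:
        eps_net = params.eps_da
    dg_e = params.e_ip - params.e_ea
    pair = coulomb_pair_energy(geom.rc, params.eps_da)
    return dg_e - pair + net_electrostatic_energy(geom, eps_net)


def ln_rate(rc, dg0, lam, params: ETParameters):
    """ln of the MKM electron-transfer rate (rate in ps^-1).

    ln k = ln nu0 - ln(1 + exp[beta (Rc - R0)]) - (dG0 + lambda)^2 / (4 lambda kB T)

    For fixed Rc this is an exact downward parabola in -dG0 with vertex at
    -dG0 = lambda and curvature -1/(4 lambda kB T): the energy gap law.
    For Rc far beyond R0 the gate term tends to -beta (Rc - R0): the classical
    linear Dutton decay.
    """
    rc = np.asarray(rc, dtype=float)
    dg0 = np.asarray(dg0, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(rc <= 0):
        raise DomainError("rc must be > 0")
    if np.any(lam <= 0):
        raise DomainError("lam must be > 0")
    # ln(1 + e^x) computed overflow-safely as logaddexp(0, x)
    gate = -np.logaddexp(0.0, params.beta * (rc - params.r0))
    fc = -((dg0 + lam) ** 2) / (4.0 * lam * params.kbt)
    out = math.log(params.nu0) + gate + fc
    return out if out.ndim else float(out)


def et_rate(rc, dg0, lam, params: ETParameters):
    """MKM electron-transfer rate k in ps^-1 (exp of :func:`ln_rate`)."""
    out = np.exp(ln_rate(rc, dg0, lam, params))
    return out if np.ndim(out) else float(out)


def trajectory_rates(series: DonorSeries, params: ETParameters) -> DonorSeries:
    """Fill ``lam`` and ``ln_rate`` for every snapshot of a series, in place.

    lambda is recomputed from Rc via :func:`reorganization_energy`; ``dg0``
    must already be present on every snapshot. Snapshot order and count are
    preserved; the series is also returned for chaining.
    """
    for i, snap in enumerate(series.snapshots):
        try:
            if snap.dg0 is None:
                raise DomainError("snapshot has no dg0 and no geometry to compute it")
            snap.lam = reorganization_energy(snap.rc, params)
            if snap.lam <= 0:
                raise DomainError(
                    f"non-positive reorganization energy {snap.lam:.4g} at rc={snap.rc}"
                )
            snap.ln_rate = ln_rate(snap.rc, snap.dg0, snap.lam, params)
        except DomainError as exc:
            raise DomainError(f"snapshot {i} (t={snap.t}): {exc}") from exc
    return series
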