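"""Unit and property tests for the MKM rate model and its energy terms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flavoet import (
    BOLTZMANN_EV_PER_K,
    COULOMB_EV_NM,
    ChargeSite,
    DonorSeries,
    ETParameters,
    Snapshot,
    SnapshotGeometry,
    coulomb_pair_energy,
    et_rate,
    free_energy_gap,
    ln_rate,
    net_electrostatic_energy,
    reorganization_energy,
    trajectory_rates,
)
from flavoet.core import DomainError


class TestReorganizationEnergy:
    def test_vanishing_pekar_factor(self):
        p = ETParameters(eps_optical=4.999999, eps_static=5.0)
        assert reorganization_energy(0.7, p) == pytest.approx(0.0, abs=1e-4)

    def test_hand_evaluated_closed_form(self):
        # C_e (1/(2*0.25) + 1/(2*0.25) - 1/0.75)(1/2 - 1/5) = 1.439964 * 8/3 * 0.3
        p = ETParameters(a_donor=0.25, a_acceptor=0.25, eps_optical=2, eps_static=5)
        assert reorganization_energy(0.75, p) == pytest.approx(1.1519712, rel=1e-9)

    def test_monotone_increasing_in_rc(self, params):
        rc = np.linspace(0.3, 3.0, 200)
        lam = reorganization_energy(rc, params)
        assert np.all(np.diff(lam) > 0)

    def test_rejects_nonpositive_rc(self, params):
        with pytest.raises(DomainError):
            reorganization_energy(0.0, params)

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(DomainError):
            ETParameters(a_donor=-0.1)


class TestCoulombPairEnergy:
    def test_hand_value(self):
        assert coulomb_pair_energy(0.72, 2.0) == pytest.approx(1.439964 / 1.44, rel=1e-12)

    def test_decays_to_zero(self):
        assert coulomb_pair_energy(1e9, 2.0) == pytest.approx(0.0, abs=1e-8)

    def test_linear_in_inverse_dielectric(self):
        assert coulomb_pair_energy(0.8, 4.0) == pytest.approx(
            coulomb_pair_energy(0.8, 2.0) / 2, rel=1e-12
        )

    def test_rejects_bad_inputs(self):
        with pytest.raises(DomainError):
            coulomb_pair_energy(-1.0, 2.0)


class TestNetElectrostaticEnergy:
    def test_empty_charge_list_is_zero(self):
        geom = SnapshotGeometry(rc=0.7)
        assert net_electrostatic_energy(geom, 4.0) == 0.0

    def test_symmetric_charge_cancels(self):
        geom = SnapshotGeometry(
            rc=1.0,
            donor_center=(0, 0, 0),
            acceptor_center=(1, 0, 0),
            charges=(ChargeSite(position=(0.5, 1.0, 0.0), charge=1.0),),
        )
        assert net_electrostatic_energy(geom, 4.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_and_brute_force(self):
        # -1 e charge 0.5 nm from the acceptor anion and 1.0 nm from the
        # donor cation, eps = 4: C_e * 0.25 = 0.359991 eV
        geom = SnapshotGeometry(
            rc=0.5,
            donor_center=(0.5, 0, 0),
            acceptor_center=(0, 0, 0),
            charges=(ChargeSite(position=(-0.5, 0, 0), charge=-1.0, label="Asp"),),
        )
        val = net_electrostatic_energy(geom, 4.0)
        assert val == pytest.approx(0.359991, rel=1e-6)
        # independent brute-force pairwise sum over (charge, ion) pairs
        expected = 0.0
        for q, pos in [(-1.0, (-0.5, 0, 0))]:
            for q_ion, center in [(-1.0, (0, 0, 0)), (+1.0, (0.5, 0, 0))]:
                d = math.dist(pos, center)
                expected += COULOMB_EV_NM * q * q_ion / (4.0 * d)
        assert val == pytest.approx(expected, rel=1e-12)

    def test_coincident_charge_raises(self):
        geom = SnapshotGeometry(
            rc=0.5,
            donor_center=(0.5, 0, 0),
            acceptor_center=(0, 0, 0),
            charges=(ChargeSite(position=(0, 0, 0), charge=1.0),),
        )
        with pytest.raises(DomainError):
            net_electrostatic_energy(geom, 4.0)


class TestFreeEnergyGap:
    def test_large_separation_reduces_to_electronic_gap(self):
        p = ETParameters(e_ip=7.0, e_ea=6.4)
        geom = SnapshotGeometry(rc=1e9)
        assert free_energy_gap(geom, p) == pytest.approx(0.6, abs=1e-8)

    def test_ion_pair_term_stabilizes(self):
        # dG_e = 0.5 eV, rc = 0.72, eps_da = 2 -> dG0 ~ 0.5 - 1.000 = -0.500
        p = ETParameters(e_ip=7.0, e_ea=6.5, eps_da=2.0)
        geom = SnapshotGeometry(rc=0.72)
        assert free_energy_gap(geom, p) == pytest.approx(-0.499975, abs=1e-5)

    def test_ea_shift_moves_gap_linearly(self):
        geom = SnapshotGeometry(rc=0.72)
        a = free_energy_gap(geom, ETParameters(e_ea=6.5))
        b = free_energy_gap(geom, ETParameters(e_ea=6.6))
        assert b - a == pytest.approx(-0.1, rel=1e-9)


class TestRate:
    def test_half_gate_unit_franck_condon(self, params):
        # dG0 = -lam and Rc = R0: the Gaussian factor is 1 and the gate is 1/2
        k = et_rate(params.r0, -1.0, 1.0, params)
        assert k == pytest.approx(params.nu0 / 2, rel=1e-12)

    def test_hand_arithmetic_example(self):
        p = ETParameters(nu0=1.0, beta=10.0, r0=0.5, temperature=298.0)
        k = et_rate(0.5, -0.5, 1.0, p)
        # 0.5 * exp(-0.25 / (4 * kB * 298)) = 0.043850
        expected = 0.5 * math.exp(-0.25 / (4 * BOLTZMANN_EV_PER_K * 298.0))
        assert k == pytest.approx(expected, rel=1e-12)
        assert k == pytest.approx(0.0439, abs=5e-4)

    def test_dutton_asymptote(self, params):
        # far beyond R0 at dG0 = -lam: ln k ~ ln nu0 - beta (Rc - R0)
        rc = params.r0 + 2.0
        lk = ln_rate(rc, -1.0, 1.0, params)
        assert lk == pytest.approx(math.log(params.nu0) - params.beta * 2.0, abs=1e-6)

    def test_ln_rate_quadratic_coefficient(self, params):
        # fixed rc: curvature in -dG0 is -1/(4 lam kB T)
        lam = 1.0
        x = np.array([0.5, 1.0, 1.5])
        y = np.array([ln_rate(params.r0, -xi, lam, params) for xi in x])
        a = np.polyfit(x, y, 2)[0]
        assert a == pytest.approx(-1.0 / (4 * lam * params.kbt), rel=1e-9)
        assert a == pytest.approx(-9.73, abs=0.05)

    def test_parabola_identity(self, params):
        lam = 0.9
        diff = ln_rate(0.7, -lam, lam, params) - ln_rate(0.7, 0.0, lam, params)
        assert diff == pytest.approx(lam / (4 * params.kbt), rel=1e-9)

    def test_vertex_by_dense_grid_search(self, params):
        lam = 1.1
        dg0 = np.linspace(-3, 1, 400001)
        lk = ln_rate(0.7, dg0, lam, params)
        best = -dg0[np.argmax(lk)]
        assert abs(best - lam) < 1e-5

    def test_dutton_slope_matches_beta(self, params):
        # |d ln k / d Rc + beta| small once the gate is saturated
        rc = params.r0 + 1.0
        h = 1e-6
        d = (ln_rate(rc + h, -1.0, 1.0, params) - ln_rate(rc - h, -1.0, 1.0, params)) / (2 * h)
        assert abs(d + params.beta) < 1e-3

    def test_rejects_nonpositive_lambda(self, params):
        with pytest.raises(DomainError):
            et_rate(0.7, -1.0, 0.0, params)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        rc=st.floats(0.3, 3.0),
        dg0=st.floats(-3.0, 1.0),
        lam=st.floats(0.1, 3.0),
    )
    def test_exp_ln_rate_equals_rate(self, rc, dg0, lam):
        p = ETParameters()
        assert math.exp(ln_rate(rc, dg0, lam, p)) == pytest.approx(
            et_rate(rc, dg0, lam, p), rel=1e-12
        )


class TestTrajectoryRates:
    def _series(self, snaps):
        return DonorSeries(protein="P", donor="Trp1", subunit="A", snapshots=snaps)

    def test_single_snapshot_matches_et_rate(self, params):
        s = self._series([Snapshot(t=0.0, rc=0.7, dg0=-1.0)])
        trajectory_rates(s, params)
        lam = reorganization_energy(0.7, params)
        assert s.snapshots[0].lam == pytest.approx(lam, rel=1e-12)
        assert math.exp(s.snapshots[0].ln_rate) == pytest.approx(
            et_rate(0.7, -1.0, lam, params), rel=1e-12
        )

    def test_constant_rc_gives_constant_lambda(self, params):
        s = self._series([Snapshot(t=i, rc=0.8, dg0=-1.0 - 0.01 * i) for i in range(5)])
        trajectory_rates(s, params)
        lams = {snap.lam for snap in s.snapshots}
        assert len(lams) == 1

    def test_matches_independent_scalar_loop(self, params):
        # independent scalar re-implementation with math only
        rng = np.random.default_rng(42)
        snaps = [
            Snapshot(t=float(i), rc=float(rng.uniform(0.4, 2.0)),
                     dg0=float(rng.uniform(-2.5, 0.0)))
            for i in range(1000)
        ]
        s = self._series(snaps)
        trajectory_rates(s, params)
        kbt = BOLTZMANN_EV_PER_K * params.temperature
        pek = 1 / params.eps_optical - 1 / params.eps_static
        for snap in s.snapshots:
            lam = COULOMB_EV_NM * (1 / (2 * params.a_donor) + 1 / (2 * params.a_acceptor)
                                   - 1 / snap.rc) * pek
            gate = 1.0 / (1.0 + math.exp(params.beta * (snap.rc - params.r0)))
            lnk = math.log(params.nu0 * gate) - (snap.dg0 + lam) ** 2 / (4 * lam * kbt)
            assert snap.lam == pytest.approx(lam, rel=1e-12)
            assert snap.ln_rate == pytest.approx(lnk, rel=1e-12)

    def test_invalid_snapshot_reports_index(self, params):
        s = self._series(
            [Snapshot(t=0.0, rc=0.7, dg0=-1.0), Snapshot(t=1.0, rc=0.7, dg0=None)]
        )
        with pytest.raises(DomainError, match="snapshot 1"):
            trajectory_rates(s, params)


class TestValidation:
    def test_eps_ordering_enforced(self):
        with pytest.raises(DomainError):
            ETParameters(eps_optical=5.0, eps_static=2.0)

    def test_geometry_center_consistency(self):
        with pytest.raises(DomainError):
            SnapshotGeometry(rc=0.5, donor_center=(0, 0, 0), acceptor_center=(1, 0, 0))

    def test_unit_key_round_trip(self):
        p = ETParameters(nu0=500.0, e_ea=6.1)
        assert ETParameters.from_unit_keys(p.to_unit_keys()) == p

    def test_unknown_unit_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ETParameters.from_unit_keys({"nu0_ps": 1.0})
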