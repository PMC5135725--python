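"""Kinetic mechanisms: reduced closure models, the full master-equation
oracle, and the signature reduction."""

import math

import numpy as np
import pytest

import amyturb.kinetics as kin
from amyturb.kinetics import (
    OosawaParams,
    RedistributionParams,
    SeededCompetitionParams,
    SeededTypeParams,
    SignatureUndefinedError,
    SmoluchowskiSystem,
    TruncationError,
    kinetic_signature,
    simulate_nucleated_growth,
    simulate_redistribution,
    simulate_seeded_competition,
    simulate_smoluchowski,
)

FIG8 = OosawaParams(f_N=1e-7, f_A=10.0, n=2, b_A=0.0, c_tot_M=1e-3)
GRID = np.concatenate([[0.0], np.logspace(2, 7, 200)])


@pytest.fixture(scope="module")
def fig8_run():
    return simulate_nucleated_growth(FIG8, GRID)


class TestNucleatedGrowth:
    def test_no_nucleation_stays_flat(self):
        p = OosawaParams(f_N=0.0, f_A=10.0, n=2, c_tot_M=1e-3)
        traj = simulate_nucleated_growth(p, np.linspace(0, 1e6, 20))
        assert np.all(traj.species["fibril"].mass_conc_M == pytest.approx(0.0, abs=1e-12))
        assert traj.monomer_M[-1] == pytest.approx(1e-3)

    def test_sigmoidal_approach_to_total(self, fig8_run):
        mass = fig8_run.species["fibril"].mass_conc_M
        assert np.all(np.diff(mass) >= -1e-15)
        # plateau just below c_tot (residual nucleus mass)
        assert 0.99e-3 < mass[-1] < 1e-3
        sig = kinetic_signature(fig8_run.t_s, mass)
        assert sig.t10_s < sig.t50_s

    def test_mass_conservation(self, fig8_run):
        assert np.max(np.abs(fig8_run.mass_balance_residual())) < 1e-8

    def test_irreversible_limit_of_breakage_model(self):
        t = np.linspace(0, 2e6, 50)
        a = simulate_nucleated_growth(FIG8, t)
        from dataclasses import replace
        b = simulate_nucleated_growth(replace(FIG8, b_A=0.0), t)
        np.testing.assert_array_equal(a.species["fibril"].mass_conc_M,
                                      b.species["fibril"].mass_conc_M)

    def test_breakage_accelerates_kinetics(self):
        # faster scission -> earlier lag and growth phases
        from dataclasses import replace
        t10s, t50s = [], []
        for ba in (0.0, 1e-9, 1e-8):
            traj = simulate_nucleated_growth(replace(FIG8, b_A=ba), GRID)
            sig = kinetic_signature(traj.t_s, traj.species["fibril"].mass_conc_M)
            t10s.append(sig.t10_s)
            t50s.append(sig.t50_s)
        assert t10s[0] > t10s[1] > t10s[2]
        assert t50s[0] > t50s[1] > t50s[2]

    def test_faster_nucleation_gives_smaller_fibrils(self):
        from dataclasses import replace
        finals = []
        for fn in (1e-7, 1e-6, 1e-4):
            traj = simulate_nucleated_growth(replace(FIG8, f_N=fn), GRID)
            finals.append(traj.species["fibril"].mean_degree[-1])
        assert finals[0] > finals[1] > finals[2]


class TestRedistribution:
    def test_zero_rates_identical_to_plain_growth(self):
        t = np.linspace(0, 2e6, 40)
        a = simulate_nucleated_growth(FIG8, t)
        b = simulate_redistribution(FIG8, RedistributionParams(), t)
        np.testing.assert_allclose(a.species["fibril"].mass_conc_M,
                                   b.species["fibril"].mass_conc_M, rtol=1e-12)
        np.testing.assert_allclose(a.species["fibril"].number_conc_M,
                                   b.species["fibril"].number_conc_M, rtol=1e-12)

    def test_end_to_end_mass_invariant_degree_grows(self):
        base = simulate_redistribution(FIG8, RedistributionParams(), GRID)
        joined = simulate_redistribution(FIG8, RedistributionParams(f_JEE=1.0), GRID)
        m0 = base.species["fibril"].mass_conc_M
        m1 = joined.species["fibril"].mass_conc_M
        assert np.max(np.abs(m1 - m0)) < 1e-10  # incorporation untouched
        late = GRID > 3e6  # past the mass plateau
        d0 = base.species["fibril"].mean_degree[late]
        d1 = joined.species["fibril"].mean_degree[late]
        assert np.all(d1 > d0)
        assert np.all(np.diff(d1) > 0)

    def test_number_times_degree_identity(self):
        traj = simulate_redistribution(FIG8, RedistributionParams(f_JEE=0.5), GRID)
        sp = traj.species["fibril"]
        sel = sp.number_conc_M > 0
        np.testing.assert_allclose(
            sp.number_conc_M[sel] * sp.mean_degree[sel], sp.mass_conc_M[sel],
            rtol=1e-12)

    def test_lateral_dimers_carry_double_degree(self):
        traj = simulate_redistribution(FIG8, RedistributionParams(f_JLA=10.0), GRID)
        proto = traj.species["fibril"]
        dimer = traj.species["lateral_dimer"]
        late = traj.t_s > 1e6
        sel = late & (dimer.number_conc_M > 0) & (proto.number_conc_M > 0)
        np.testing.assert_allclose(dimer.mean_degree[sel],
                                   2 * proto.mean_degree[sel], rtol=1e-9)
        assert np.max(np.abs(traj.mass_balance_residual())) < 1e-8


class TestSeededCompetition:
    @staticmethod
    def _params(f1=250.0, b1=1e-3, f2=250.0, b2=1e-2):
        return SeededCompetitionParams(
            types=(SeededTypeParams("amyloid", f1, b1, 1e-7, 100.0),
                   SeededTypeParams("amorphous", f2, b2, 1e-7, 100.0)),
            c_tot_M=1e-3)

    def test_symmetric_types_identical(self):
        p = self._params(f1=100.0, b1=1e-3, f2=100.0, b2=1e-3)
        traj = simulate_seeded_competition(p, np.linspace(0, 1e6, 50))
        np.testing.assert_allclose(traj.species["amyloid"].mass_conc_M,
                                   traj.species["amorphous"].mass_conc_M,
                                   rtol=1e-9)

    def test_fast_amorphous_overshoot_and_decay(self):
        traj = simulate_seeded_competition(self._params(),
                                           np.concatenate([[0.0], np.logspace(1, 6.5, 300)]))
        g = traj.species["amorphous"].mass_conc_M
        a = traj.species["amyloid"].mass_conc_M
        k = int(np.argmax(g))
        assert 0 < k < len(g) - 1
        assert g[k] > 10 * g[-1]  # transient excursion, then dissolution
        assert a[-1] > 0.9e-3  # monomer ends in the stable amyloid form

    def test_equilibrium_monomer_is_critical_concentration(self):
        traj = simulate_seeded_competition(self._params(),
                                           np.linspace(0, 5e6, 60))
        # b_A / f_A of the stable (amyloid) type, far from its seed floor
        assert traj.monomer_M[-1] == pytest.approx(1e-3 / 250.0, rel=1e-3)

    def test_seed_floor_never_undercut(self):
        traj = simulate_seeded_competition(self._params(),
                                           np.concatenate([[0.0], np.logspace(1, 6.5, 300)]))
        for sp in traj.species.values():
            assert np.all(sp.mean_degree >= 100.0 - 1e-6)

    def test_mass_conservation(self):
        traj = simulate_seeded_competition(self._params(),
                                           np.linspace(0, 3e6, 80))
        assert np.max(np.abs(traj.mass_balance_residual())) < 1e-8


class TestSmoluchowskiOracle:
    def test_dimerization_closed_form(self):
        z, f, c0 = 8, 100.0, 1e-3
        fmat = np.zeros((z, z))
        fmat[0, 0] = f
        sys = SmoluchowskiSystem(z=z, f_mat=fmat, b_mat=np.zeros((z, z)),
                                 c0=np.r_[c0, np.zeros(z - 1)])
        t = np.linspace(0, 1e5, 25)
        traj = simulate_smoluchowski(sys, t)
        exact = c0 / (1 + 2 * f * c0 * t)
        np.testing.assert_allclose(traj.conc_M[0], exact, rtol=1e-5)
        # the lost monomer is all in dimers
        np.testing.assert_allclose(traj.conc_M[1], (c0 - exact) / 2, rtol=1e-5)

    def test_zero_rates_constant_state(self):
        z = 5
        c0 = np.array([1e-3, 1e-5, 1e-6, 0.0, 0.0])
        sys = SmoluchowskiSystem(z=z, f_mat=np.zeros((z, z)),
                                 b_mat=np.zeros((z, z)), c0=c0)
        traj = simulate_smoluchowski(sys, np.linspace(0, 1e4, 5))
        np.testing.assert_allclose(traj.conc_M, c0[:, None] * np.ones((1, 5)),
                                   atol=1e-18)

    def test_detailed_balance_equilibrium(self):
        # monomer addition/loss chain: C_{i+1}/C_i -> f C1 / b
        z, f, b = 12, 1e3, 1e-2
        fmat = np.zeros((z, z))
        fmat[0, :] = f
        fmat[:, 0] = f
        bmat = np.zeros((z, z))
        bmat[0, 0] = b  # symmetric (1,1) partition carries the whole rate
        for parent in range(3, z + 1):
            bmat[0, parent - 2] = b / 2
            bmat[parent - 2, 0] = b / 2
        sys = SmoluchowskiSystem(z=z, f_mat=fmat, b_mat=bmat,
                                 c0=np.r_[1e-4, np.zeros(z - 1)])
        traj = simulate_smoluchowski(sys, np.linspace(0, 2e5, 8),
                                     boundary_tol=1.0)
        c = traj.conc_M[:, -1]
        expected = f * c[0] / b
        np.testing.assert_allclose(c[1:6] / c[0:5], expected, rtol=5e-3)

    def test_mass_conserved(self):
        # closed z boundary conserves mass even when the distribution piles
        # up against it, so the truncation guard is disabled here
        p = OosawaParams(f_N=3e-3, f_A=10.0, n=2, c_tot_M=1e-3)
        traj = simulate_smoluchowski(SmoluchowskiSystem.oosawa(p, z=60),
                                     np.linspace(0, 5e4, 15), boundary_tol=1.0)
        np.testing.assert_allclose(traj.total_monomer_M(), 1e-3, rtol=1e-8)

    def test_truncation_guard_trips(self):
        # aggressive growth in a tiny system must hit the z boundary
        p = OosawaParams(f_N=3e-3, f_A=10.0, n=2, c_tot_M=1e-3)
        with pytest.raises(TruncationError):
            simulate_smoluchowski(SmoluchowskiSystem.oosawa(p, z=10),
                                  np.linspace(0, 2e5, 10))

    def test_reduced_model_matches_full_distribution(self):
        # scaled-rate run keeps <i> << z so the truncated system is exact
        p = OosawaParams(f_N=3e-3, f_A=10.0, n=2, c_tot_M=1e-3)
        t = np.linspace(0, 2e5, 60)
        red = simulate_nucleated_growth(p, t)
        full = simulate_smoluchowski(SmoluchowskiSystem.oosawa(p, z=200), t)
        cma_red = red.species["fibril"].mass_conc_M
        cma_full = full.aggregate_mass_M(min_degree=3)
        sup = np.max(np.abs(cma_red - cma_full)) / np.max(cma_full)
        assert sup < 0.05


class TestKineticSignature:
    def test_logistic_closed_form(self):
        tm, k = 5e5, 2e-5
        t = np.linspace(0, 2e6, 4000)
        y = 1e-3 / (1 + np.exp(-k * (t - tm)))
        sig = kinetic_signature(t, y)
        assert sig.t50_s == pytest.approx(tm, rel=1e-3)
        assert sig.t10_s == pytest.approx(tm - math.log(9) / k, rel=1e-3)
        assert sig.asymptote_M == pytest.approx(1e-3, rel=1e-3)

    def test_time_axis_scaling(self):
        t = np.linspace(0, 1e6, 2000)
        y = 1e-3 / (1 + np.exp(-1e-5 * (t - 3e5)))
        a = kinetic_signature(t, y)
        b = kinetic_signature(7.0 * t, y)
        assert b.t10_s == pytest.approx(7 * a.t10_s, rel=1e-9)
        assert b.t50_s == pytest.approx(7 * a.t50_s, rel=1e-9)

    def test_unconverged_rejected(self):
        t = np.linspace(0, 1e5, 100)
        y = 1e-3 * t / t[-1]  # still rising linearly at the end
        with pytest.raises(SignatureUndefinedError):
            kinetic_signature(t, y)

    def test_non_monotone_rejected(self):
        t = np.linspace(0, 1e5, 200)
        y = 1e-3 * np.sin(t / t[-1] * 2.2)
        with pytest.raises(SignatureUndefinedError):
            kinetic_signature(t, y)


class TestReproducibility:
    def test_bit_identical_reruns(self):
        a = simulate_nucleated_growth(FIG8, GRID)
        b = simulate_nucleated_growth(FIG8, GRID)
        np.testing.assert_array_equal(a.species["fibril"].mass_conc_M,
                                      b.species["fibril"].mass_conc_M)
        np.testing.assert_array_equal(a.monomer_M, b.monomer_M)
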