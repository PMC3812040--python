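import itertools
import math

import numpy as np
import pytest

from actomotility import motorsim as ms


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def master_equation_occupancy(N, p: ms.MotorParams):
    """Stationary site-state distribution by brute force (c = 0 only).

    Enumerates all 3^N site-state combinations (0 detached, 1 pre-stroke,
    2 post-stroke), builds the generator with the model's attachment rule
    (slow re-engagement when nothing is bound) and solves for the
    stationary distribution.  Valid for c = 0, where transition rates do
    not depend on strain.
    """
    assert p.c_coupling == 0
    states = list(itertools.product(range(3), repeat=N))
    index = {s: i for i, s in enumerate(states)}
    Q = np.zeros((len(states), len(states)))
    for s in states:
        i = index[s]
        n_bound = sum(1 for x in s if x != 0)
        for site, x in enumerate(s):
            if x == 0:
                rate = p.k_reengage if n_bound == 0 else p.k_attach
                t = list(s)
                t[site] = 1
            elif x == 1:
                rate = p.k_stroke
                t = list(s)
                t[site] = 2
            else:
                rate = p.k_detach
                t = list(s)
                t[site] = 0
            j = index[tuple(t)]
            Q[i, j] += rate
            Q[i, i] -= rate
    # stationary distribution: pi Q = 0, sum pi = 1
    A = np.vstack([Q.T, np.ones(len(states))])
    b = np.zeros(len(states) + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    occ = {}
    for s, w in zip(states, pi):
        key = (sum(1 for x in s if x == 1), sum(1 for x in s if x == 2))
        occ[key] = occ.get(key, 0.0) + w
    return occ


def elastic_energy(anchors, z):
    return 0.5 * sum((z - a) ** 2 for a in anchors)


# ---------------------------------------------------------------------------
# Elementary bookkeeping
# ---------------------------------------------------------------------------

class TestSites:
    @pytest.mark.parametrize("L,expected", [
        (0.0355, 1), (3.55, 100), (0.3, 8), (3.25, 92)])
    def test_site_count_from_helix_repeat(self, L, expected):
        assert ms.n_sites(L) == expected

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            ms.n_sites(0.0)


class TestEquilibrate:
    def test_single_motor_carries_no_strain(self):
        assert ms.equilibrate([7.0]) == 7.0

    def test_two_motors_share_strain_symmetrically(self):
        z = ms.equilibrate([0.0, 10.0])
        assert z == 5.0
        assert elastic_energy([0, 10], z) == pytest.approx(25.0)

    def test_stroke_of_one_among_n_shifts_filament_by_d_over_n(self):
        for n in (2, 3, 5, 8):
            anchors = [0.0] * n
            z0 = ms.equilibrate(anchors)
            anchors[0] += 6.0
            assert ms.equilibrate(anchors) - z0 == pytest.approx(6.0 / n)


class TestTransitionRates:
    @pytest.fixture
    def params(self, fast_params):
        return fast_params

    def test_decoupled_limit_recovers_unstrained_rates(self, params):
        for s in (-5.0, 0.0, 7.0):
            assert ms.stroke_rate(s, 4, params) == params.k_stroke
            assert ms.detach_rate(s, 4, params) == params.k_detach

    def test_single_unloaded_motor_recovers_unstrained_rates(self, params):
        p = ms.MotorParams(**{**params.to_dict(), "c_coupling": 1.5})
        assert ms.stroke_rate(0.0, 1, p) == pytest.approx(p.k_stroke)
        assert ms.detach_rate(0.0, 1, p) == pytest.approx(p.k_detach)

    def test_stroke_rate_monotone_in_strain(self, params):
        p = ms.MotorParams(**{**params.to_dict(), "c_coupling": 1.0})
        strains = np.linspace(-8, 8, 30)
        rates = [ms.stroke_rate(s, 4, p) for s in strains]
        assert np.all(np.diff(rates) > 0)  # favourable strain accelerates

    def test_stroke_energy_matches_brute_force(self, params):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(1, 7)
            anchors = list(rng.normal(0, 5, n))
            z = ms.equilibrate(anchors)
            i = rng.integers(n)
            dE_formula = ms.stroke_energy(z - anchors[i], n, params) \
                / params.kappa_pn_nm
            after = list(anchors)
            after[i] += params.d_main_nm
            dE_brute = elastic_energy(after, ms.equilibrate(after)) \
                - elastic_energy(anchors, z)
            assert dE_formula == pytest.approx(dE_brute, abs=1e-9)

    def test_detach_step_energy_matches_brute_force(self, params):
        # the rate-modulating energy is the work of the secondary step
        # itself (anchor moves by d_second, filament re-equilibrates)
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(1, 7)
            anchors = list(rng.normal(0, 5, n))
            z = ms.equilibrate(anchors)
            i = rng.integers(n)
            dE_formula = ms.detach_energy(z - anchors[i], n, params) \
                / params.kappa_pn_nm
            after = list(anchors)
            after[i] += params.d_second_nm
            dE_brute = elastic_energy(after, ms.equilibrate(after)) \
                - elastic_energy(anchors, z)
            assert dE_formula == pytest.approx(dE_brute, abs=1e-9)


class TestConditionParams:
    def test_baseline_is_identity(self, baseline_params):
        assert ms.condition_params("baseline", baseline_params) \
            == baseline_params

    def test_condition_multipliers_match_published_values(self,
                                                          baseline_params):
        a = ms.condition_params("alphaA-TmAlpha", baseline_params)
        assert a.k_attach == pytest.approx(1.15 * baseline_params.k_attach)
        assert a.k_stroke == pytest.approx(1.15 * baseline_params.k_stroke)
        assert a.k_detach == pytest.approx(1.15 * baseline_params.k_detach)
        b = ms.condition_params("gammaA-TmAlpha", baseline_params)
        assert b.c_coupling == pytest.approx(
            1.2 * baseline_params.c_coupling)
        c = ms.condition_params("gammaA-TmBeta", baseline_params)
        assert c.k_detach == pytest.approx(0.75 * baseline_params.k_detach)
        assert c.c_coupling == pytest.approx(
            0.8 * baseline_params.c_coupling)

    def test_unknown_condition_rejected(self):
        with pytest.raises(KeyError):
            ms.condition_params("no-such-condition")


# ---------------------------------------------------------------------------
# Stochastic simulation vs closed forms
# ---------------------------------------------------------------------------

class TestGillespie:
    def test_no_attachment_means_flat_trajectory(self, fast_params):
        p = ms.MotorParams(**{**fast_params.to_dict(),
                              "k_attach": 0.0, "k_reengage": 0.0})
        traj = ms.gillespie_run(p, 1.0, 5.0, seed=1)
        assert np.all(traj.z_true_um == 0.0)

    def test_reproducible_under_fixed_seed(self, baseline_params):
        a = ms.gillespie_run(baseline_params, 1.5, 5.0, seed=42)
        b = ms.gillespie_run(baseline_params, 1.5, 5.0, seed=42)
        np.testing.assert_array_equal(a.z_um, b.z_um)
        np.testing.assert_array_equal(a.n_pre, b.n_pre)

    def test_single_motor_cycle_advances_main_plus_secondary(self,
                                                             fast_params):
        traj = ms.gillespie_run(fast_params, 0.0355, 200.0, seed=3,
                                record_events=True)
        n_cycles = int(np.sum(traj.event_kinds == 3))
        advance = traj.z_true_um[-1] * 1000
        expected = n_cycles * (fast_params.d_main_nm
                               + fast_params.d_second_nm)
        # the last cycle may be incomplete (partial advance <= d1 + d2)
        assert abs(advance - expected) <= (fast_params.d_main_nm
                                           + fast_params.d_second_nm)

    def test_uncoupled_single_site_velocity_matches_renewal_form(
            self, fast_params):
        p = fast_params
        traj = ms.gillespie_run(p, 0.0355, 3000.0, seed=7)
        v = traj.z_true_um[-1] * 1000 / 3000.0
        cycle = 1 / p.k_attach + 1 / p.k_stroke + 1 / p.k_detach
        expected = (p.d_main_nm + p.d_second_nm) / cycle
        assert v == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("N", [2, 3])
    def test_occupancy_matches_master_equation(self, N, fast_params):
        p = ms.MotorParams(**{**fast_params.to_dict(), "k_reengage": 2.0})
        traj = ms.gillespie_run(p, N * p.site_spacing_um, 2000.0, seed=11,
                                dt_s=0.1)
        occ = master_equation_occupancy(N, p)
        samples = np.column_stack([traj.n_pre, traj.n_post])[1:]
        n_batches = 20
        batches = np.array_split(samples, n_batches)
        for key, target in occ.items():
            if target < 0.01:
                continue
            hits = np.array([(np.all(b == key, axis=1)).mean()
                             for b in batches])
            est = hits.mean()
            se = hits.std(ddof=1) / math.sqrt(n_batches)
            assert abs(est - target) <= max(3 * se, 0.01), \
                f"state {key}: {est:.4f} vs {target:.4f} (SE {se:.4f})"


class TestSimulateCondition:
    def test_record_schema_and_reproducibility(self, baseline_params):
        a = ms.simulate_condition(baseline_params, 10, 10.0, seed=5,
                                  condition="b")
        b = ms.simulate_condition(baseline_params, 10, 10.0, seed=5,
                                  condition="b")
        assert list(a.columns)[:5] == ["condition", "chamber", "video",
                                       "filament", "L_um"]
        np.testing.assert_allclose(a["v_f2f_mean_um_s"],
                                   b["v_f2f_mean_um_s"])

    def test_velocity_and_motile_fraction_rise_with_length(self,
                                                           baseline_params):
        rec = ms.simulate_condition(baseline_params, 90, 20.0, seed=2,
                                    condition="b")
        short = rec[rec.L_um < 1.0]
        mid = rec[(rec.L_um >= 1.0) & (rec.L_um < 2.2)]
        long = rec[rec.L_um >= 2.2]
        assert short.f_mot.mean() < mid.f_mot.mean() <= long.f_mot.mean() \
            + 0.05
        assert short.v_f2f_mean_um_s.mean() < long.v_f2f_mean_um_s.mean()
        # run times grow with length
        runs = [g.run_time_sum_s.sum() / max(g.n_runs.sum(), 1)
                for g in (short, long)]
        assert runs[0] < runs[1]


class TestParameterSweep:
    def test_multiplier_grid_is_linspace(self, fast_params):
        out = ms.parameter_sweep(fast_params, "k_stroke", 0.25, 1.75,
                                 n_steps=15, n_filaments=2, T_s=2.0,
                                 cut=0.1)
        np.testing.assert_allclose(sorted(out),
                                   np.linspace(0.25, 1.75, 15))
        cs = next(iter(out.values()))
        assert len(cs.centers) == 25

    def test_single_site_velocity_follows_renewal_form_across_sweep(
            self, fast_params):
        p = fast_params
        mults = (0.5, 1.0, 1.5)
        vs = []
        for m in mults:
            q = p.with_multipliers(k_stroke=m)
            traj = ms.gillespie_run(q, 0.0355, 1500.0, seed=13)
            vs.append(traj.z_true_um[-1] * 1000 / 1500.0)
        for m, v in zip(mults, vs):
            cycle = 1 / p.k_attach + 1 / (m * p.k_stroke) + 1 / p.k_detach
            assert v == pytest.approx(
                (p.d_main_nm + p.d_second_nm) / cycle, rel=0.05)
        assert vs[0] < vs[1] < vs[2]
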