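"""Generator construction, Master-equation dynamics and the stochastic sampler."""
import numpy as np
import pytest

from g4pull.kinetic_model import (
    BellEdge,
    DwellConstants,
    RateSet,
    ReducibleChainError,
    StateModel,
    gillespie_simulate,
    master_solve,
    parallel_model,
    pfold_predict,
    rate_matrix,
    sequential_model,
    stationary_distribution,
)
from g4pull.presets import DWELL_CONSTANTS, alpha_rate_set
from g4pull.trace_synthesis import ForceProtocol


def two_state_model(k12=0.2, k21=0.1):
    return StateModel(
        states=("U", "S"),
        edges=(BellEdge("U", "S", k12), BellEdge("S", "U", k21)),
        folded_states=frozenset({"S"}),
    )


class TestRateMatrix:
    def test_zero_force_gives_k0(self, model_5pn):
        q = rate_matrix(model_5pn, 0.0)
        for e in model_5pn.edges:
            i, j = model_5pn.index(e.source), model_5pn.index(e.target)
            assert q[j, i] == pytest.approx(e.k0)

    def test_bell_ratio_for_folding_edge(self, kbt):
        edge = BellEdge("U", "S", 1.0, dx=-3.0)
        ratio = edge.rate(7.0) / edge.rate(1.0)
        assert ratio == pytest.approx(np.exp(-3.0 * 6.0 / kbt), rel=1e-12)
        assert ratio == pytest.approx(1 / 84.0, rel=0.02)

    def test_columns_sum_to_zero(self, model_5pn):
        q = rate_matrix(model_5pn, 5.0)
        assert np.allclose(q.sum(axis=0), 0.0, atol=1e-15)

    def test_unknown_state_rejected(self):
        with pytest.raises(KeyError):
            StateModel(
                states=("U", "S"),
                edges=(BellEdge("U", "X", 1.0),),
                folded_states=frozenset({"S"}),
            )


class TestMasterSolve:
    def test_initial_condition_exact(self, model_5pn):
        p0 = np.array([0.4, 0.3, 0.3])
        occ = master_solve(model_5pn, 5.0, p0, [0.0])
        assert np.array_equal(occ[0], p0)

    def test_two_state_closed_form(self):
        k12, k21 = 0.35, 0.15
        m = two_state_model(k12, k21)
        t = np.linspace(0, 30, 61)
        occ = master_solve(m, 0.0, [1.0, 0.0], t)
        p_eq = k21 / (k12 + k21)
        expected = p_eq + (1 - p_eq) * np.exp(-(k12 + k21) * t)
        assert np.max(np.abs(occ[:, 0] - expected)) < 1e-6

    def test_probability_conservation(self, model_5pn):
        t = np.linspace(0, 200, 101)
        occ = master_solve(model_5pn, 5.0, [1, 0, 0], t)
        assert np.max(np.abs(occ.sum(axis=1) - 1.0)) < 1e-8
        assert np.all(occ >= -1e-10)

    def test_long_time_limit_is_stationary(self, model_5pn):
        occ = master_solve(model_5pn, 5.0, [1, 0, 0], [2000.0])
        pi = stationary_distribution(model_5pn, 5.0)
        assert np.allclose(occ[0], pi, atol=1e-6)

    def test_bad_p0_rejected(self, model_5pn):
        with pytest.raises(ValueError):
            master_solve(model_5pn, 5.0, [0.7, 0.2, 0.0], [1.0])


class TestPfoldPredict:
    def test_starts_unfolded(self, model_5pn):
        assert pfold_predict(model_5pn, 5.0, 0.0) == 0.0

    def test_5pn_alpha10_plateau(self):
        model = sequential_model(alpha_rate_set(5.0, 10.0), include_ul=False)
        assert 0.7 <= pfold_predict(model, 5.0, 60.0) <= 0.9

    def test_nondecreasing_with_absorbing_folded_set(self):
        m = StateModel(
            states=("U", "S", "L"),
            edges=(BellEdge("U", "S", 0.1), BellEdge("S", "L", 0.3),
                   BellEdge("L", "S", 0.05)),
            folded_states=frozenset({"S", "L"}),
        )
        t = np.linspace(0, 50, 40)
        pf = pfold_predict(m, 5.0, t)
        assert np.all(np.diff(pf) >= -1e-12)


class TestStationaryDistribution:
    def test_two_state_detailed_balance(self):
        m = two_state_model(0.2, 0.05)
        pi = stationary_distribution(m, 0.0)
        assert pi[1] / pi[0] == pytest.approx(0.2 / 0.05, rel=1e-10)

    def test_birth_death_chain(self, model_5pn, rates_5pn):
        pi = stationary_distribution(model_5pn, 5.0)
        rs = rates_5pn
        assert pi[2] / pi[0] == pytest.approx(
            (rs.k12 / rs.k21) * (rs.k23 / rs.k32), rel=1e-10
        )

    def test_reducible_chain_flagged(self):
        m = StateModel(
            states=("U", "S"),
            edges=(BellEdge("U", "S", 0.5),),
            folded_states=frozenset({"S"}),
        )
        with pytest.raises(ReducibleChainError):
            stationary_distribution(m, 0.0)


class TestGillespie:
    def test_no_rates_single_dwell(self):
        m = StateModel(
            states=("U", "S"),
            edges=(BellEdge("S", "U", 1e-30),),
            folded_states=frozenset({"S"}),
        )
        traj = gillespie_simulate(m, (5.0, 100.0), seed=1)
        assert len(traj.times) == 1
        assert traj.states == ["U"]

    def test_mean_unfolded_dwell(self, model_5pn, rates_5pn):
        traj = gillespie_simulate(model_5pn, (5.0, 3e4), seed=7)
        d, folded = traj.class_dwells()
        u = d[~folded][1:-1] if not folded[0] else d[~folded][:-1]
        tau = 1.0 / rates_5pn.k12
        assert abs(u.mean() - tau) < 3 * tau / np.sqrt(len(u))

    def test_occupancy_matches_stationary(self, model_5pn):
        traj = gillespie_simulate(model_5pn, (5.0, 5e4), seed=3)
        pi = stationary_distribution(model_5pn, 5.0)
        occ = np.array([traj.occupancy(s) for s in model_5pn.states])
        # 3 SE with an effective sample size of the slow folding cycles
        n_eff = 5e4 / (1 / 0.0633 + 24.0)
        assert np.all(np.abs(occ - pi) < 3 * np.sqrt(pi * (1 - pi) / n_eff) + 0.01)

    def test_reproducible_under_seed(self, model_5pn):
        t1 = gillespie_simulate(model_5pn, (5.0, 2000.0), seed=42)
        t2 = gillespie_simulate(model_5pn, (5.0, 2000.0), seed=42)
        assert np.array_equal(t1.times, t2.times)
        assert t1.states == t2.states

    def test_topology_respected(self, model_5pn):
        traj = gillespie_simulate(model_5pn, (5.0, 2e4), seed=5)
        allowed = {(e.source, e.target) for e in model_5pn.edges}
        jumps = set(zip(traj.states[:-1], traj.states[1:]))
        assert jumps <= allowed


class TestUltraLongLived:
    def test_ul_survival_1000s_at_5_to_7pn(self):
        model = sequential_model(alpha_rate_set(5.0), include_ul=True)
        for force in (5.0, 7.0):
            survived = 0
            n = 200
            rng = np.random.default_rng(int(force))
            for _ in range(n):
                traj = gillespie_simulate(
                    model, (force, 1000.0), seed=rng, initial_state="UL"
                )
                if traj.states[-1] in model.folded_states:
                    survived += 1
            assert survived / n >= 0.95

    def test_ul_modal_rupture_force_calibration(self):
        from g4pull.inference import peak_force
        from g4pull.kinetic_model import UL_RUPTURE_DX, UL_RUPTURE_K0

        edge = BellEdge("UL", "U", UL_RUPTURE_K0, UL_RUPTURE_DX)
        assert 42.0 <= peak_force(edge, 2.0) <= 43.0


class TestRateSet:
    def test_spectral_inversion_round_trip(self):
        d = DwellConstants(15.8, 3.0, 45.0, n_ratio=1.0)
        rs = RateSet.from_dwell_constants(5.0, d, "spectral")
        ts, tl, nr = rs.folded_dwell_mixture()
        assert ts == pytest.approx(3.0, rel=1e-9)
        assert tl == pytest.approx(45.0, rel=1e-9)
        assert nr == pytest.approx(1.0, rel=1e-9)

    def test_naive_rule(self):
        d = DwellConstants(15.8, 3.0, 45.0, n_ratio=2.0)
        rs = RateSet.from_dwell_constants(5.0, d, "naive")
        assert rs.k21 == pytest.approx(1 / 3.0)
        assert rs.k32 == pytest.approx(1 / 45.0)
        assert rs.k23 == pytest.approx(rs.k21 * 2.0)

    def test_alpha_constraint_bounds(self):
        with pytest.raises(ValueError):
            RateSet.alpha_constrained(5.0, 0.06, 0.02, alpha=3.0)

    def test_simulated_mixture_matches_spectral_truth(self, model_5pn):
        # ergodic check: folded dwells from a long SSA run reproduce the
        # printed mixture constants, not the naive-rule ones
        traj = gillespie_simulate(model_5pn, (5.0, 6e4), seed=11)
        d, folded = traj.class_dwells()
        fd = d[folded][1:-1] if folded[0] else d[folded][:-1]
        from g4pull.inference import fit_exponential

        fit = fit_exponential(fd, 2)
        assert abs(fit.lifetimes[0] - 3.0) < 3 * 0.3
        assert abs(fit.lifetimes[1] - 45.0) < 3 * 3.5


class TestParallelTopology:
    def test_constructed_shape(self):
        m = parallel_model(0.05, 0.2, 0.01, 0.02)
        assert m.topology == "parallel"
        assert {(e.source, e.target) for e in m.edges} == {
            ("U", "S"), ("S", "U"), ("U", "L"), ("L", "U"),
        }

    def test_stationary_folded_fraction(self):
        m = parallel_model(0.05, 0.2, 0.01, 0.02)
        pi = stationary_distribution(m, 0.0)
        expected = (0.05 / 0.2 + 0.01 / 0.02)
        assert (pi[1] + pi[2]) / pi[0] == pytest.approx(expected, rel=1e-10)


class TestPresetsConsistency:
    def test_tabulated_forces(self):
        assert set(DWELL_CONSTANTS) == {5.0, 6.0, 7.0}

    def test_ramp_protocol_shapes(self):
        p = ForceProtocol.clamp_then_ramp(6.5, 60.0)
        assert p.segments[0].kind == "clamp"
        assert p.segments[1].kind == "ramp"
        f = p.force_at(np.array([30.0, 60.0, 61.0]))
        assert f[0] == 6.5
        assert f[2] == pytest.approx(6.5 + 2.0, rel=1e-9)
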