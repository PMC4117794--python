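"""Step detection, dwell extraction and rupture finding on synthetic traces."""
import numpy as np
import pytest

from g4pull.kinetic_model import BellEdge, StateModel
from g4pull.polymer_mechanics import step_size
from g4pull.trace_analysis import (
    DetectorConfig,
    detect_rupture,
    detect_steps,
    extract_dwells,
    smooth_trace,
)
from g4pull.trace_synthesis import (
    ForceProtocol,
    NoiseParams,
    synthesize_trace,
)

from synthetic_helpers import make_trace, two_state_trace


class TestSmoothTrace:
    def test_constant_trace_unchanged(self):
        tr = make_trace(np.full(1000, 3.5))
        assert np.allclose(smooth_trace(tr, 0.5).extension, 3.5)

    def test_white_noise_variance_reduction(self, rng):
        tr = make_trace(rng.normal(0, 2.0, 40000))
        sm = smooth_trace(tr, 0.5)
        assert sm.extension[100:-100].std() == pytest.approx(0.2, rel=0.15)

    def test_plateau_levels_preserved_across_step(self):
        x = np.concatenate([np.zeros(2000), np.full(2000, 6.0)])
        sm = smooth_trace(make_trace(x), 0.5)
        assert sm.extension[500:1500].mean() == pytest.approx(0.0, abs=1e-12)
        assert sm.extension[2500:3500].mean() == pytest.approx(6.0, abs=1e-12)

    def test_window_validation(self):
        tr = make_trace(np.zeros(100))
        with pytest.raises(ValueError):
            smooth_trace(tr, 1.0)  # longer than trace
        with pytest.raises(ValueError):
            smooth_trace(tr, 0.001)  # below 2 samples


class TestDetectSteps:
    def test_noiseless_transitions_recovered_exactly(self, model_5pn):
        noise = NoiseParams(sigma_x=0.0, force_bias_cv=0.0)
        tr = synthesize_trace(
            model_5pn, ForceProtocol.clamp(5.0, 600.0), noise, seed=21
        )
        cfg = DetectorConfig(window_s=0.1, min_dwell_s=0.2)
        res = detect_steps(tr, cfg)
        true_change = np.flatnonzero(np.diff(tr.true_folded.astype(int))) + 1
        true_change = true_change[
            (true_change > 40) & (true_change < len(tr) - 40)
        ]
        # transitions flanking dwells below the dead time are merged by design
        min_len = int(cfg.dead_time * tr.sampling_rate)
        runs = np.diff(np.concatenate([[0], true_change, [len(tr)]]))
        keep = (runs[:-1] >= min_len) & (runs[1:] >= min_len)
        det_times = np.array([e.time for e in res.events])
        assert keep.any()
        for s in true_change[keep]:
            assert np.min(np.abs(det_times - tr.time[s])) <= 1.5 / tr.sampling_rate

    def test_sensitivity_and_false_rate_at_snr3(self):
        # 6 nm steps, 2 nm noise, dwells >= 2 s, 20 independent recordings
        found, total, false, span = 0, 0, 0, 0.0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            tr, bounds, _ = two_state_trace(rng)
            res = detect_steps(tr, DetectorConfig(window_s=0.5))
            det = np.array([e.time for e in res.events])
            for b in bounds:
                total += 1
                if len(det) and np.min(np.abs(det - b)) < 1.0:
                    found += 1
            extra = sum(1 for d in det if np.min(np.abs(bounds - d)) >= 1.0)
            false += extra
            span += 100.0
        assert found / total >= 0.95
        assert false / total <= 0.02

    def test_no_events_on_monotone_trace(self):
        x = np.linspace(0, 1.0, 4000)  # slow 1 nm drift, no step
        res = detect_steps(make_trace(x), DetectorConfig())
        assert res.events == []

    def test_invariance_to_offset_and_drift(self, rng):
        tr, bounds, _ = two_state_trace(rng)
        res0 = detect_steps(tr, DetectorConfig())
        shifted = make_trace(tr.extension + 100.0 + 0.01 * tr.time)
        res1 = detect_steps(shifted, DetectorConfig())
        t0 = np.array([e.time for e in res0.events])
        t1 = np.array([e.time for e in res1.events])
        assert len(t0) == len(t1)
        assert np.allclose(t0, t1, atol=0.5)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_steps(make_trace(np.zeros(5)), DetectorConfig())


class TestExtractDwells:
    def test_k_transitions_give_k_plus_one_dwells(self):
        path = np.repeat([False, True, False, True], 500)
        dw = extract_dwells(path, 200.0)
        assert len(dw) == 4
        cens = dw.records["censored"].tolist()
        assert cens[0] == "left" and cens[-1] == "right"
        assert cens[1:-1] == ["none", "none"]

    def test_all_folded_path_single_doubly_censored_dwell(self):
        dw = extract_dwells(np.ones(1000, dtype=bool), 200.0)
        assert len(dw) == 1
        assert dw.records["censored"].iloc[0] == "both"
        assert dw.records["state_class"].iloc[0] == "folded"

    def test_merging_below_min_dwell(self):
        path = np.concatenate(
            [np.zeros(1000), np.ones(10), np.zeros(1000)]
        ).astype(bool)
        dw = extract_dwells(path, 200.0, min_dwell=0.2)
        assert len(dw) == 1
        assert dw.records["duration"].iloc[0] == pytest.approx(2010 / 200.0)

    def test_simulated_unfolded_dwell_mean(self, model_5pn, rates_5pn):
        noise = NoiseParams(sigma_x=0.0, force_bias_cv=0.0)
        tr = synthesize_trace(
            model_5pn, ForceProtocol.clamp(5.0, 20000.0), noise, seed=13
        )
        dw = extract_dwells(tr.true_folded, tr.sampling_rate, force=5.0)
        u, cens = dw.durations("unfolded")
        u = u[~cens]
        tau = 1.0 / rates_5pn.k12
        assert abs(u.mean() - tau) < 3 * tau / np.sqrt(len(u))


class TestDetectRupture:
    def _ramp_model(self):
        return StateModel(
            states=("F", "U"),
            edges=(BellEdge("F", "U", 0.009, 0.8),),
            folded_states=frozenset({"F"}),
        )

    def test_noiseless_rupture_force_exact(self):
        noise = NoiseParams(sigma_x=0.0, force_bias_cv=0.0)
        tr = synthesize_trace(
            self._ramp_model(), ForceProtocol.ramp(1.0, 2.0, 50.0), noise,
            seed=2, initial_state="F",
        )
        traj = tr.metadata["trajectory"]
        assert len(traj.times) == 2  # one rupture
        true_force = 1.0 + 2.0 * traj.times[1]
        out = detect_rupture(tr)
        assert out is not None
        force, step = out
        assert force == pytest.approx(true_force, abs=0.5)
        assert step == pytest.approx(step_size(true_force), abs=0.5)

    def test_no_rupture_returns_none(self):
        noise = NoiseParams(sigma_x=1.0, force_bias_cv=0.0)
        x = np.random.default_rng(0).normal(0, 1.0, 5000)
        tr = make_trace(x)
        assert detect_rupture(tr) is None

    def test_mean_rupture_force_over_many_ramps(self):
        noise = NoiseParams(force_bias_cv=0.0).decimated(10)
        rng = np.random.default_rng(77)
        model = self._ramp_model()
        forces = []
        for _ in range(300):
            tr = synthesize_trace(
                model, ForceProtocol.ramp(1.0, 2.0, 55.0), noise,
                seed=rng, initial_state="F",
            )
            out = detect_rupture(tr)
            if out is not None:
                forces.append(out[0])
        forces = np.array(forces)
        assert len(forces) > 280
        assert forces.mean() == pytest.approx(17.0, abs=1.0)
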