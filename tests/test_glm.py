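"""GLM-stage tests: 24-regressor motion expansion, cosine high-pass,
confound residualisation and per-trial "Add"-model beta estimation."""

import numpy as np
import pytest

from allodecode.glm import (
    ConfoundMatrix,
    cosine_drift_basis,
    estimate_trial_betas,
    friston24_expansion,
    highpass,
    highpass_array,
    preprocess_run,
    residualize,
    trial_boxcar,
)
from allodecode.synth import MotionSeries, RoiTimeSeries


def _ts(data, tr=2.0, run=1):
    return RoiTimeSeries(roi_label="r", data=np.asarray(data, dtype=float), tr_s=tr, run=run)


class TestFriston24:
    def test_block_structure(self):
        rng = np.random.default_rng(0)
        cm = friston24_expansion(MotionSeries(rng.normal(size=(6, 50))))
        assert cm.rows.shape == (24, 50)
        assert np.allclose(cm.rows[12:18], cm.rows[0:6] ** 2)
        assert np.allclose(cm.rows[18:24], cm.rows[6:12] ** 2)

    def test_zero_motion_all_zero(self):
        cm = friston24_expansion(MotionSeries(np.zeros((6, 20))))
        assert np.all(cm.rows == 0)

    def test_hand_computed_ramp(self):
        p = np.zeros((6, 5))
        p[0] = [0, 1, 2, 3, 4]
        cm = friston24_expansion(MotionSeries(p))
        assert np.array_equal(cm.rows[0], [0, 1, 2, 3, 4])
        assert np.array_equal(cm.rows[6], [0, 1, 1, 1, 1])  # backward diff, first 0
        assert np.array_equal(cm.rows[12], [0, 1, 4, 9, 16])
        assert np.array_equal(cm.rows[18], [0, 1, 1, 1, 1])

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            friston24_expansion(MotionSeries(np.zeros((5, 20))))
        with pytest.raises(ValueError):
            friston24_expansion(MotionSeries(np.zeros((6, 1))))


class TestHighpass:
    def test_constant_series_unchanged(self):
        out = highpass(_ts(np.full((3, 445), 7.5)))
        assert np.allclose(out.data, 7.5)

    def test_slow_cosine_removed_fast_preserved(self):
        T, tr = 445, 2.0
        t = np.arange(T) * tr
        slow = np.cos(2 * np.pi * t / 300.0)
        fast = np.cos(2 * np.pi * t / 50.0)
        out = highpass_array(np.stack([slow, fast]), tr)
        rms = lambda v: np.sqrt(np.mean((v - v.mean()) ** 2))
        assert rms(out[0]) / rms(slow) < 0.05
        assert abs(rms(out[1]) / rms(fast) - 1.0) < 0.05

    def test_matches_projection_oracle(self):
        """Residual equals brute-force OLS projection onto [1, drift basis]."""
        T, tr = 200, 2.0
        rng = np.random.default_rng(3)
        data = rng.normal(size=(4, T))
        basis = cosine_drift_basis(T, tr, 128.0)
        X = np.column_stack([np.ones(T), basis])
        beta, *_ = np.linalg.lstsq(X, data.T, rcond=None)
        expected = data - (X @ beta).T + data.mean(axis=1, keepdims=True)
        assert np.allclose(highpass_array(data, tr), expected, atol=1e-10)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            highpass(_ts(np.zeros((2, 50))), cutoff_s=4.0)


class TestResidualize:
    def _confounds(self, T, seed=0):
        rng = np.random.default_rng(seed)
        return friston24_expansion(MotionSeries(rng.normal(size=(6, T)) * 0.1))

    def test_confound_replica_removed(self):
        cm = self._confounds(120)
        data = np.tile(cm.rows[3], (5, 1))
        out = residualize(_ts(data), cm)
        assert np.allclose(out.data, 0.0, atol=1e-8)

    def test_residuals_orthogonal_to_confounds(self):
        cm = self._confounds(150, seed=1)
        rng = np.random.default_rng(2)
        out = residualize(_ts(rng.normal(size=(6, 150))), cm)
        dots = cm.rows @ out.data.T
        norms = np.linalg.norm(cm.rows, axis=1)[:, None] * np.linalg.norm(out.data, axis=1)[None, :].T.T
        assert np.all(np.abs(dots) <= 1e-6 * np.maximum(norms, 1e-12))

    def test_matches_normal_equations_oracle(self):
        cm = self._confounds(100, seed=5)
        rng = np.random.default_rng(6)
        data = rng.normal(size=(3, 100))
        X = np.column_stack([cm.rows.T, np.ones(100)])
        beta = np.linalg.solve(X.T @ X, X.T @ data.T)
        expected = data - (X @ beta).T
        out = residualize(_ts(data), cm)
        assert np.allclose(out.data, expected, atol=1e-8)

    def test_rank_deficient_warns_but_projects(self, caplog):
        rows = np.zeros((24, 80))
        rows[0] = np.sin(np.arange(80))
        rows[6] = rows[0]  # duplicate -> rank deficient
        rows[12] = rows[0] ** 2
        rows[18] = rows[6] ** 2
        cm = ConfoundMatrix(rows=rows)
        rng = np.random.default_rng(0)
        with caplog.at_level("WARNING"):
            out = residualize(_ts(rng.normal(size=(2, 80))), cm)
        assert "rank-deficient" in caplog.text
        assert np.abs(rows[0] @ out.data.T).max() < 1e-6


class TestTrialBetas:
    def test_window_placement_exhaustive(self, table):
        T, tr = 445, 2.0
        for ev in table.events(1):
            box = trial_boxcar(ev.onset_s, T, tr)
            mids = (np.arange(T) + 0.5) * tr
            active = mids[box == 1]
            assert np.all(active >= ev.onset_s + 6.0)
            assert np.all(active < ev.onset_s + 12.0)
            assert int(box.sum()) in (2, 3, 4)  # 3 for on-grid onsets

    def test_constructed_design_recovers_coefficients(self, table):
        """Series built as 2 x own boxcar + 1 x union of others -> beta = 2."""
        onsets = [e.onset_s for e in table.events(1)][:20]
        T, tr = 445, 2.0
        boxes = np.stack([trial_boxcar(o, T, tr) for o in onsets])
        t_of_interest = 5
        others = (np.delete(boxes, t_of_interest, axis=0).sum(axis=0) > 0).astype(float)
        series = 2.0 * boxes[t_of_interest] + 1.0 * others
        tb = estimate_trial_betas(_ts(series[None, :]), onsets)
        assert tb.betas[t_of_interest, 0] == pytest.approx(2.0, abs=1e-8)

    def test_planted_per_trial_amplitudes_recovered_exactly(self, table):
        """Noise-free boxcar series with per-trial amplitudes -> exact betas."""
        onsets = np.array([e.onset_s for e in table.events(1)])
        T, tr = 445, 2.0
        rng = np.random.default_rng(8)
        amps = rng.normal(1.0, 0.5, size=(len(onsets), 3))  # 3 voxels
        boxes = np.stack([trial_boxcar(o, T, tr) for o in onsets])
        assert boxes.sum(axis=0).max() == 1.0  # windows must not overlap for exactness
        series = (amps.T @ boxes)
        tb = estimate_trial_betas(_ts(series), onsets)
        assert np.allclose(tb.betas, amps, atol=1e-8)

    def test_zero_series_zero_betas_and_count(self, table):
        onsets = [e.onset_s for e in table.events(2)]
        tb = estimate_trial_betas(_ts(np.zeros((4, 445))), onsets)
        assert tb.betas.shape == (96, 4)
        assert np.allclose(tb.betas, 0.0)

    def test_window_past_run_end_rejected(self):
        with pytest.raises(ValueError, match="trial 1"):
            estimate_trial_betas(_ts(np.zeros((2, 50))), [10.0, 95.0])


class TestConfoundEfficacy:
    def test_motion_coupled_null_data_decodes_at_chance(self):
        """Strong motion leakage but no planted direction signal: after the
        full preprocessing chain, decoding stays at chance."""
        from allodecode.pipeline import DecodingConfig, GlmConfig, analyze_participant
        from allodecode.synth import CohortConfig, NoiseConfig, RoiSpec, simulate_participant

        cfg = CohortConfig(
            n_participants=3,
            rois={"r": RoiSpec(n_voxels=60, amp_boundary=0.0, amp_goal=0.0)},
            noise=NoiseConfig(motion_coupling_sd=3.0, n_coupled=4),
            motion_step_sd=0.1,
            master_seed=13,
        )
        accs = []
        for p in range(cfg.n_participants):
            part = simulate_participant(cfg, p)
            s = analyze_participant(part, GlmConfig(), DecodingConfig())
            accs.append(s["r"]["allo_boundary"].mean_accuracy)
        assert abs(np.mean(accs) - 0.25) < 0.10


class TestPreprocessRun:
    def test_motion_coupled_drift_suppressed(self):
        """Motion leakage plus slow drift is largely removed by the full
        preprocessing chain."""
        from allodecode.synth import NoiseConfig, generate_condition_patterns, generate_motion
        from allodecode.synth import simulate_roi_timeseries
        import allodecode as ad

        env = ad.build_environment()
        table = ad.build_trial_table(ad.enumerate_paths(env), env, seed=2)
        pats = {
            "allo_boundary": generate_condition_patterns(10, "allo_boundary", 0.0, 0),
            "allo_goal": generate_condition_patterns(10, "allo_goal", 0.0, 1),
        }
        for ps in pats.values():
            ps.patterns[:] = 0
        motion = generate_motion(445, 0.1, seed=3)
        cfg = NoiseConfig(ar_sd=0.0, white_sd=0.0, drift_sd=2.0, motion_coupling_sd=3.0)
        ts = simulate_roi_timeseries(table.events(1), pats, motion, cfg, seed=4)
        clean = preprocess_run(ts, motion)
        assert np.std(clean.data) < 0.05 * np.std(ts.data)
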