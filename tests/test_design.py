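"""Design-module tests: geometry of the 24 paths, trial-table balance,
JRD combinatorics and boundary-proximity occupancy."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import allodecode as ad
from allodecode.design import (
    DIRECTIONS,
    EGO_POSITIONS,
    DesignError,
    heading_for,
    read_events_tsv,
    rotate_direction,
    side_masks,
    write_events_tsv,
)

_VEC = {"N": (0, 1), "E": (1, 0), "S": (0, -1), "W": (-1, 0)}


def _rot_ccw(v):
    return (-v[1], v[0])


def ego_position_oracle(heading: str, boundary_dir: str) -> str:
    """Vector-geometry oracle: where is the boundary relative to the heading?"""
    h, d = _VEC[heading], _VEC[boundary_dir]
    if d == h:
        return "front"
    if d == _rot_ccw(h):
        return "left"
    if _rot_ccw(d) == h:
        return "right"
    return "behind"


class TestEnvironment:
    def test_default_environment_structure(self, env):
        assert len(env.boundaries) == 4
        axes = [b.long_axis for b in env.boundaries]
        assert axes.count("NS") == 2 and axes.count("EW") == 2
        assert env.landmark_compass["Mountain"] == "N"
        assert sorted(env.landmark_compass.values()) == sorted(DIRECTIONS)

    def test_invalid_configs_rejected(self):
        with pytest.raises(DesignError):
            ad.build_environment(landmarks=["A", "B", "C"])
        with pytest.raises(DesignError):
            ad.build_environment(textures=["t", "t", "u", "v"])
        with pytest.raises(DesignError):
            ad.build_environment(boundary_offset=260.0)  # outside explorable area


class TestPaths:
    def test_24_paths_exhaustive_nonredundant(self, paths):
        assert len(paths) == 24
        keys = {(p.boundary_id, p.boundary_side, p.ego_boundary) for p in paths}
        assert len(keys) == 24
        # 3 paths per (boundary, side); one per egocentric position
        for b, side in {(p.boundary_id, p.boundary_side) for p in paths}:
            egos = sorted(
                p.ego_boundary for p in paths
                if (p.boundary_id, p.boundary_side) == (b, side)
            )
            assert egos == sorted(EGO_POSITIONS)

    def test_heading_geometry_matches_vector_oracle(self, paths):
        # brute force over all 8 sides x 3 positions
        for p in paths:
            assert ego_position_oracle(p.heading, p.boundary_side) == p.ego_boundary

    @pytest.mark.parametrize(
        "side,ego,heading",
        [("N", "left", "E"), ("N", "right", "W"), ("N", "front", "N"),
         ("W", "left", "N"), ("S", "front", "S")],
    )
    def test_heading_examples(self, side, ego, heading):
        assert heading_for(side, ego) == heading


class TestTrialTable:
    def test_run_counts_and_marginals(self, table):
        df = table.to_dataframe()
        assert sorted(df["run"].unique()) == [1, 2, 3]
        for run, sub in df.groupby("run"):
            assert len(sub) == 96
            for factor in ("allo_boundary", "allo_goal"):
                assert sub[factor].value_counts().to_dict() == {d: 24 for d in DIRECTIONS}
            reps = sub.groupby(["path_id", "cue_side"]).size()
            assert (reps == 2).all() and len(reps) == 48  # 24 paths x 2 sides, twice each

    def test_onsets_increase_and_span(self, table):
        for run in table.runs:
            onsets = [e.onset_s for e in table.events(run)]
            assert np.all(np.diff(onsets) > 0)
            gaps = np.diff(onsets) - 8.0  # ITIs between consecutive trials
            assert np.all(gaps >= 0.5 - 1e-9) and np.all(gaps <= 1.5 + 1e-9)
            assert abs(np.mean(gaps) - 1.0) < 0.1

    def test_goal_rule_roundtrip(self, table):
        env = ad.build_environment()
        inv = env.compass_landmark
        for run in table.runs:
            for ev in table.events(run):
                offset = 90 if ev.cue_side == "right" else -90
                assert ev.allo_goal == rotate_direction(ev.heading, offset)
                assert ev.correct_response_landmark == inv[ev.allo_goal]
                assert ev.facing_landmark == inv[ev.heading]

    def test_determinism_and_seed_sensitivity(self, paths, env):
        a = ad.build_trial_table(paths, env, seed=5).to_dataframe()
        b = ad.build_trial_table(paths, env, seed=5).to_dataframe()
        c = ad.build_trial_table(paths, env, seed=6).to_dataframe()
        assert a.equals(b)
        assert not a.equals(c)

    def test_odd_reps_rejected(self, paths, env):
        with pytest.raises(DesignError):
            ad.build_trial_table(paths, env, reps_per_run=3)

    @given(seed=st.integers(0, 10_000))
    def test_marginals_any_seed(self, seed):
        env = ad.build_environment()
        tbl = ad.build_trial_table(ad.enumerate_paths(env), env, n_runs=1, seed=seed)
        df = tbl.to_dataframe()
        assert df["allo_boundary"].value_counts().tolist() == [24] * 4
        assert df["allo_goal"].value_counts().tolist() == [24] * 4


class TestRelativeLandmark:
    @pytest.mark.parametrize(
        "facing,offset,expected",
        [("Mountain", 90, "ClockTower"), ("Cathedral", 180, "Mountain"),
         ("City", 90, "Mountain"), ("ClockTower", 270, "Mountain")],
    )
    def test_examples(self, env, facing, offset, expected):
        assert ad.relative_landmark(facing, offset, env) == expected

    def test_identity_and_errors(self, env):
        for lm in env.landmark_compass:
            assert ad.relative_landmark(lm, 0, env) == lm
        with pytest.raises(DesignError):
            ad.relative_landmark("Mountain", 45, env)
        with pytest.raises(DesignError):
            ad.relative_landmark("Volcano", 90, env)


class TestJrd:
    def test_enumeration(self, env):
        qs = ad.enumerate_jrd(env)
        assert len(qs) == 12
        for lm in env.landmark_compass:
            mine = [q for q in qs if q.facing_landmark == lm]
            assert len(mine) == 3
            assert sorted(q.angular_disparity for q in mine) == [90, 180, 270]
            assert all(q.probe_landmark != lm for q in mine)

    def test_response_mapping(self, env):
        qs = {(q.facing_landmark, q.probe_landmark): q for q in ad.enumerate_jrd(env)}
        q = qs[("Mountain", "Cathedral")]
        assert q.angular_disparity == 180 and q.correct_response == "behind"
        q = qs[("Mountain", "ClockTower")]
        assert q.angular_disparity == 90 and q.correct_response == "right"
        q = qs[("Mountain", "City")]
        assert q.angular_disparity == 270 and q.correct_response == "left"


class TestBalance:
    def test_default_table_balanced_both_factors(self, table, env):
        for factor in ("allo_boundary", "allo_goal"):
            rep = ad.verify_balance(table, factor, env)
            assert rep.all_pass, rep.flags
            assert rep.n_trials == 288

    def test_ego_counts_per_run(self, table, env):
        rep = ad.verify_balance(table, "allo_boundary", env)
        for run_counts in rep.level_counts["N"].values():
            assert run_counts["ego_boundary"] == {"left": 8, "right": 8, "front": 8}

    def test_constructed_violation_fails(self, table, env):
        import dataclasses

        broken = ad.TrialTable(
            runs={
                run: [dataclasses.replace(ev, cue_side="left") for ev in evs]
                for run, evs in table.runs.items()
            },
            design_seed=table.design_seed,
        )
        rep = ad.verify_balance(broken, "allo_boundary", env)
        assert not all(f["cue_side_balanced"] for f in rep.flags.values())


class TestOccupancy:
    def test_uniform_occupancy_mask_fractions(self, env):
        xs = np.arange(-247.5, 250, 5.0)
        X, Y = np.meshgrid(xs, xs)
        pos = np.column_stack([X.ravel(), Y.ravel()])
        occ = ad.occupancy_fraction(pos, np.arange(len(pos), dtype=float), env)
        assert occ["n_bins"] == 10_000
        assert occ["histogram"].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(occ["histogram"] >= 0)
        # 8 masks x (40 x 5) m2 out of 500 x 500 m2
        assert occ["total"] == pytest.approx(8 * 200 / 250_000, abs=1e-12)
        for d in DIRECTIONS:
            assert occ["per_direction"][d] == pytest.approx(2 * 200 / 250_000, abs=1e-12)

    def test_trajectory_confined_to_one_mask(self, env):
        x0, x1, y0, y1 = side_masks(env)["N"][0]
        rng = np.random.default_rng(0)
        pos = np.column_stack(
            [rng.uniform(x0 + 0.1, x1 - 0.1, 40), rng.uniform(y0 + 0.1, y1 - 0.1, 40)]
        )
        occ = ad.occupancy_fraction(pos, np.arange(40.0), env)
        assert occ["per_direction"]["N"] == pytest.approx(1.0)
        assert occ["total"] == pytest.approx(1.0)

    def test_errors(self, env):
        with pytest.raises(DesignError):
            ad.occupancy_fraction(np.empty((0, 2)), np.empty(0), env)
        with pytest.raises(DesignError):
            ad.occupancy_fraction([[0, 0], [1, 1]], [1.0, 0.5], env)
        with pytest.raises(DesignError):
            ad.occupancy_fraction([[300, 0]], [0.0], env)


class TestEventsIO:
    def test_events_tsv_roundtrip(self, table, tmp_path):
        files = write_events_tsv(table, tmp_path)
        assert len(files) == 3
        df = read_events_tsv(files[0])
        assert len(df) == 96
        assert list(df.columns) == [
            "onset", "duration", "trial_type", "path_id", "cue_side",
            "allo_boundary", "allo_goal", "ego_boundary",
            "facing_landmark", "response_landmark",
        ]
        orig = [ev.onset_s for ev in table.events(1)]
        assert np.allclose(df["onset"], np.round(orig, 3), atol=5e-4)
        assert (df["duration"] == 8.0).all()
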