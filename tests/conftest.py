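import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import allodecode as ad
from allodecode.synth import CohortConfig, NoiseConfig, RoiSpec

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def env():
    return ad.build_environment()


@pytest.fixture(scope="session")
def paths(env):
    return ad.enumerate_paths(env)


@pytest.fixture(scope="session")
def table(paths, env):
    return ad.build_trial_table(paths, env, seed=7)


@pytest.fixture(scope="session")
def small_cfg():
    """Small, fast cohort: 2 runs of 48 trials, 20 voxels, short runs."""
    return CohortConfig(
        n_participants=2,
        rois={"roi": RoiSpec(n_voxels=20, amp_boundary=2.0, amp_goal=0.0)},
        noise=NoiseConfig(),
        n_runs=2,
        n_volumes=250,
        reps_per_run=2,
        master_seed=123,
    )


def cohort_accuracies(cfg, factors=("allo_boundary", "allo_goal")):
    """Mean nested-CV accuracy arrays per (roi, factor) over a cohort."""
    from allodecode.pipeline import DecodingConfig, GlmConfig, analyze_participant
    from allodecode.synth import iter_cohort

    out = {roi: {f: [] for f in factors} for roi in cfg.rois}
    for part in iter_cohort(cfg):
        scores = analyze_participant(part, GlmConfig(), DecodingConfig())
        for roi in cfg.rois:
            for f in factors:
                out[roi][f].append(scores[roi][f].mean_accuracy)
    return {roi: {f: np.asarray(v) for f, v in d.items()} for roi, d in out.items()}
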