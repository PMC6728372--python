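"""Synthetic ROI BOLD data with planted allocentric direction codes.

Every downstream stage of the pipeline (confound regression, beta-series
estimation, run averaging, decoding, group inference) is exercised on data
generated here, with known ground truth. A participant's ROI time series is
built additively:

    data = sum_trials [pattern(allo_boundary) + pattern(allo_goal)]
             x HRF-convolved trial regressor
         + low-frequency cosine drift
         + motion-coupled baseline shifts
         + AR(1) + white noise

Each factor (boundary / goal direction) contributes four multivoxel patterns,
one per cardinal direction: a shared baseline response plus ``effect_amplitude``
times mutually orthonormal direction components, so all four class patterns
have identical norm and the factor carries no signal when its amplitude is 0.
The neural event of a trial is a boxcar over the stationary (blank-screen)
phase 2-6 s after trial onset, convolved with the canonical double-gamma HRF
and normalised to unit peak, so planted amplitudes are in units of peak
evoked response and are directly comparable to the betas recovered by the
estimator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from nilearn.glm.first_level import spm_hrf
from scipy.signal import lfilter

from .design import (
    DIRECTIONS,
    BLANK_S,
    MOVEMENT_S,
    TrialEvent,
    TrialTable,
    build_environment,
    build_trial_table,
    enumerate_paths,
    write_events_tsv,
)

__all__ = [
    "ConditionPatternSet",
    "MotionSeries",
    "RoiTimeSeries",
    "NoiseConfig",
    "RoiSpec",
    "CohortConfig",
    "ParticipantData",
    "generate_condition_patterns",
    "generate_motion",
    "simulate_roi_timeseries",
    "simulate_participant",
    "simulate_cohort",
    "load_participant_dir",
]

FACTORS = ("allo_boundary", "allo_goal")

#: default planted effect amplitude (peak-response units per orthonormal
#: direction component); calibrated so a 28-participant cohort at default
#: noise recovers the planted factor well above chance while leaving the
#: unplanted factor at chance (the task geometry couples the two factors at
#: the axis level, so a much louder signal would bleed across factors).
DEFAULT_EFFECT_AMPLITUDE = 0.6

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass
class ConditionPatternSet:
    """Ground-truth mean multivoxel response per direction for one factor."""

    factor: str
    patterns: np.ndarray  # (4, n_voxels), row order follows DIRECTIONS
    effect_amplitude: float

    def row(self, direction: str) -> np.ndarray:
        return self.patterns[DIRECTIONS.index(direction)]

    def validate(self) -> None:
        if self.patterns.shape[0] != 4:
            raise ValueError("need one pattern row per direction")
        norms = np.linalg.norm(self.patterns, axis=1)
        if np.ptp(norms) > 1e-6 * max(norms.max(), 1.0):
            raise ValueError("direction patterns must have equal norm")


@dataclass
class MotionSeries:
    """Six rigid-body realignment parameters (mm / radians) over a run."""

    params: np.ndarray  # (6, T)

    @property
    def n_volumes(self) -> int:
        return self.params.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.params.T, columns=list(MOTION_COLUMNS))


@dataclass
class RoiTimeSeries:
    """Voxel x volume BOLD series for one ROI and run."""

    roi_label: str
    data: np.ndarray  # (n_voxels, T)
    tr_s: float = 2.0
    run: int = 1

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ROI time series contains non-finite values")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive nuisance model for the simulator.

    ``ar_sd`` is the stationary standard deviation of the AR(1) component,
    ``white_sd`` that of the independent white component (both in the same
    arbitrary units as the planted patterns' peak response). Drift periods are
    all >= 128 s so the high-pass stage can remove them; the first
    ``n_coupled`` motion parameters leak linearly into voxel baselines with
    per-voxel weights of scale ``motion_coupling_sd``.
    """

    ar_sd: float = 1.0
    ar_phi: float = 0.3
    white_sd: float = 0.5
    drift_sd: float = 1.0
    drift_periods: tuple[float, ...] = (890.0, 445.0, 297.0)
    motion_coupling_sd: float = 0.5
    n_coupled: int = 2

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(ar_sd=0.0, white_sd=0.0, drift_sd=0.0, motion_coupling_sd=0.0)


def generate_condition_patterns(
    n_voxels: int, factor: str, effect_amplitude: float, seed: int
) -> ConditionPatternSet:
    """Draw four direction patterns: shared baseline + amplitude x orthonormal
    direction components (baseline projected off their span so all rows have
    exactly equal norm)."""
    if effect_amplitude < 0:
        raise ValueError("effect_amplitude must be non-negative")
    if n_voxels < 4:
        raise ValueError("need at least 4 voxels for 4 orthonormal components")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(0.0, 1.0, n_voxels)
    raw = rng.normal(size=(4, n_voxels))
    q, _ = np.linalg.qr(raw.T)  # (n_voxels, 4), orthonormal columns
    comps = q.T
    baseline = baseline - comps.T @ (comps @ baseline)
    patterns = baseline[None, :] + effect_amplitude * comps
    ps = ConditionPatternSet(factor=factor, patterns=patterns, effect_amplitude=effect_amplitude)
    ps.validate()
    return ps


def generate_motion(
    T: int, step_sd: float | Sequence[float] = 0.05, seed: int = 0, bound_steps: float = 50.0
) -> MotionSeries:
    """Bounded random-walk realignment parameters.

    ``step_sd`` may be a scalar (applied to all six parameters) or a length-6
    sequence (mm for translations, radians for rotations); each walk is
    clipped to ``+/- bound_steps * step_sd``.
    """
    if T < 2:
        raise ValueError("need at least 2 volumes")
    sds = np.broadcast_to(np.asarray(step_sd, dtype=float), (6,)).copy()
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, 1.0, (6, T)) * sds[:, None]
    params = np.zeros((6, T))
    bounds = bound_steps * sds
    for t in range(1, T):
        params[:, t] = np.clip(params[:, t - 1] + steps[:, t], -bounds, bounds)
    return MotionSeries(params=params)


# --- trial response shape ---------------------------------------------------

_FINE_DT = 0.02


def _canonical_trial_response(tr_s: float, max_lag_s: float = 40.0):
    """Unit-peak HRF-convolved response of one trial's stationary-phase boxcar,
    as a function of time since trial onset (fine grid)."""
    t = np.arange(0.0, max_lag_s, _FINE_DT)
    box = ((t >= MOVEMENT_S) & (t < MOVEMENT_S + BLANK_S)).astype(float)
    hrf = spm_hrf(_FINE_DT, oversampling=1, time_length=32.0)
    resp = np.convolve(box, hrf)[: len(t)]
    return t, resp / resp.max()


def trial_regressor_matrix(
    onsets: np.ndarray, T: int, tr_s: float = 2.0
) -> np.ndarray:
    """(n_trials, T) matrix of unit-peak convolved trial responses sampled at
    volume acquisition midpoints."""
    lag_grid, resp = _canonical_trial_response(tr_s)
    mids = (np.arange(T) + 0.5) * tr_s
    R = np.zeros((len(onsets), T))
    for i, onset in enumerate(onsets):
        lags = mids - onset
        R[i] = np.interp(lags, lag_grid, resp, left=0.0, right=0.0)
    return R


def simulate_roi_timeseries(
    events: Sequence[TrialEvent],
    patterns: Mapping[str, ConditionPatternSet],
    motion: MotionSeries | None,
    noise_cfg: NoiseConfig,
    seed: int,
    T: int = 445,
    tr_s: float = 2.0,
    roi_label: str = "roi",
    run: int = 1,
) -> RoiTimeSeries:
    """Simulate one run of voxel x volume BOLD for one ROI.

    The noise draws depend only on ``noise_cfg``, the shapes and ``seed`` —
    never on the planted amplitudes — so simulations with different pattern
    sets but the same seed share their noise exactly (signal additivity).
    """
    n_voxels = {ps.patterns.shape[1] for ps in patterns.values()}
    if len(n_voxels) != 1:
        raise ValueError("pattern sets disagree on voxel count")
    V = n_voxels.pop()
    if motion is not None and motion.n_volumes != T:
        raise ValueError("motion series length does not match T")

    onsets = np.array([ev.onset_s for ev in events])
    last_needed = onsets.max() + 12.0
    if last_needed > T * tr_s:
        raise ValueError(
            f"trial window extends past run end ({last_needed:.1f} s > {T * tr_s:.1f} s)"
        )
    R = trial_regressor_matrix(onsets, T, tr_s)  # (n_trials, T)

    amp = np.zeros((len(events), V))
    for factor, ps in patterns.items():
        labels = [getattr(ev, factor) for ev in events]
        amp += np.stack([ps.row(lab) for lab in labels])
    data = amp.T @ R  # (V, T)

    rng = np.random.default_rng(seed)
    t = np.arange(T) * tr_s
    # drift: per-voxel random amplitude and phase per period
    for period in noise_cfg.drift_periods:
        coeff = rng.normal(0.0, 1.0, V) * noise_cfg.drift_sd
        phase = rng.uniform(0, 2 * np.pi, V)
        data += coeff[:, None] * np.cos(2 * np.pi * t[None, :] / period + phase[:, None])
    # motion coupling into voxel baselines
    weights = rng.normal(0.0, 1.0, (V, noise_cfg.n_coupled)) * noise_cfg.motion_coupling_sd
    if motion is not None and noise_cfg.n_coupled > 0:
        data += weights @ motion.params[: noise_cfg.n_coupled]
    # AR(1) + white noise
    innov = rng.normal(0.0, 1.0, (V, T))
    white = rng.normal(0.0, 1.0, (V, T))
    if noise_cfg.ar_sd > 0:
        sd_innov = noise_cfg.ar_sd * np.sqrt(1 - noise_cfg.ar_phi**2)
        data += lfilter([1.0], [1.0, -noise_cfg.ar_phi], sd_innov * innov, axis=1)
    data += noise_cfg.white_sd * white

    ts = RoiTimeSeries(roi_label=roi_label, data=data, tr_s=tr_s, run=run)
    ts.validate()
    return ts


# --- cohort -----------------------------------------------------------------


@dataclass(frozen=True)
class RoiSpec:
    """Voxel count and planted per-factor amplitudes for one synthetic ROI."""

    n_voxels: int = 100
    amp_boundary: float = DEFAULT_EFFECT_AMPLITUDE
    amp_goal: float = 0.0

    def amplitude(self, factor: str) -> float:
        return self.amp_boundary if factor == "allo_boundary" else self.amp_goal


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort (defaults mirror the scanned
    sample: 28 participants, 3 runs of 445 volumes at TR 2 s, 96 trials/run,
    and a posterior ROI carrying boundary direction only vs an anterior ROI
    carrying goal direction only)."""

    n_participants: int = 28
    rois: dict[str, RoiSpec] = field(
        default_factory=lambda: {
            "posterior": RoiSpec(amp_boundary=DEFAULT_EFFECT_AMPLITUDE, amp_goal=0.0),
            "anterior": RoiSpec(amp_boundary=0.0, amp_goal=DEFAULT_EFFECT_AMPLITUDE),
        }
    )
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    n_runs: int = 3
    n_volumes: int = 445
    tr_s: float = 2.0
    reps_per_run: int = 4
    iti_mean_s: float = 1.0
    motion_step_sd: float = 0.05
    master_seed: int = 0


@dataclass
class ParticipantData:
    """In-memory bundle for one simulated participant."""

    index: int
    table: TrialTable
    motion: dict[int, MotionSeries]  # run -> series
    roi_series: dict[str, dict[int, RoiTimeSeries]]  # roi -> run -> series
    patterns: dict[str, dict[str, ConditionPatternSet]]  # roi -> factor -> set
    seed: int


def _participant_seeds(master_seed: int, pidx: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence([int(master_seed), int(pidx)])
    return ss.generate_state(n) & 0x7FFFFFFF


def simulate_participant(cfg: CohortConfig, pidx: int) -> ParticipantData:
    """Deterministically simulate participant ``pidx`` of a cohort: trial
    tables, motion traces and per-ROI BOLD, all seeded from
    ``(master_seed, pidx)``."""
    env = build_environment()
    paths = enumerate_paths(env)
    n_rois = len(cfg.rois)
    seeds = _participant_seeds(
        cfg.master_seed, pidx, 1 + cfg.n_runs + 2 * n_rois + cfg.n_runs * n_rois
    )
    k = 0
    table = build_trial_table(
        paths,
        env,
        n_runs=cfg.n_runs,
        reps_per_run=cfg.reps_per_run,
        iti_mean=cfg.iti_mean_s,
        seed=int(seeds[k]),
    )
    k += 1
    motion = {}
    for run in range(1, cfg.n_runs + 1):
        motion[run] = generate_motion(cfg.n_volumes, cfg.motion_step_sd, seed=int(seeds[k]))
        k += 1
    roi_series: dict[str, dict[int, RoiTimeSeries]] = {}
    all_patterns: dict[str, dict[str, ConditionPatternSet]] = {}
    for roi_label, spec in cfg.rois.items():
        pats = {}
        for factor in FACTORS:
            pats[factor] = generate_condition_patterns(
                spec.n_voxels, factor, spec.amplitude(factor), seed=int(seeds[k])
            )
            k += 1
        all_patterns[roi_label] = pats
        roi_series[roi_label] = {}
        for run in range(1, cfg.n_runs + 1):
            roi_series[roi_label][run] = simulate_roi_timeseries(
                table.events(run),
                pats,
                motion[run],
                cfg.noise,
                seed=int(seeds[k]),
                T=cfg.n_volumes,
                tr_s=cfg.tr_s,
                roi_label=roi_label,
                run=run,
            )
            k += 1
    return ParticipantData(
        index=pidx,
        table=table,
        motion=motion,
        roi_series=roi_series,
        patterns=all_patterns,
        seed=int(cfg.master_seed),
    )


def iter_cohort(cfg: CohortConfig):
    """Yield the cohort's participants one at a time (memory-friendly)."""
    for pidx in range(cfg.n_participants):
        yield simulate_participant(cfg, pidx)


def simulate_cohort(cfg: CohortConfig, out_dir: str | Path, overwrite: bool = False) -> Path:
    """Simulate the whole cohort and persist it to ``out_dir``.

    Layout: ``manifest.json`` at the top, then per participant ``sub-XX/``
    with BIDS-style events TSVs, confounds TSVs (six motion columns), and one
    NIfTI (voxels unravelled along the first axis) plus a flat ``.npy`` +
    JSON header per ROI and run.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists; pass overwrite=True to replace it")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": _config_to_jsonable(cfg),
        "participants": [],
    }
    for part in iter_cohort(cfg):
        sub = out_dir / f"sub-{part.index + 1:02d}"
        write_events_tsv(part.table, sub / "events")
        (sub / "confounds").mkdir(parents=True, exist_ok=True)
        for run, mo in part.motion.items():
            mo.to_frame().to_csv(
                sub / "confounds" / f"run-{run:02d}_confounds.tsv", sep="\t", index=False
            )
        for roi_label, by_run in part.roi_series.items():
            roi_dir = sub / f"roi-{roi_label}"
            roi_dir.mkdir(parents=True, exist_ok=True)
            for run, ts in by_run.items():
                img = nib.Nifti1Image(
                    ts.data[:, None, None, :].astype(np.float32), affine=np.eye(4)
                )
                img.header.set_zooms((1.0, 1.0, 1.0, ts.tr_s))
                nib.save(img, roi_dir / f"run-{run:02d}_bold.nii.gz")
                np.save(roi_dir / f"run-{run:02d}_bold.npy", ts.data)
                (roi_dir / f"run-{run:02d}_bold.json").write_text(
                    json.dumps(
                        {
                            "roi_label": roi_label,
                            "run": run,
                            "tr_s": ts.tr_s,
                            "shape": list(ts.data.shape),
                            "dtype": str(ts.data.dtype),
                        }
                    )
                )
        manifest["participants"].append(
            {
                "index": part.index,
                "dir": sub.name,
                "design_seed": part.table.design_seed,
                "ground_truth": {
                    roi: {f: ps.effect_amplitude for f, ps in pats.items()}
                    for roi, pats in part.patterns.items()
                },
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def _config_to_jsonable(cfg: CohortConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["rois"] = {k: dataclasses.asdict(v) if not isinstance(v, dict) else v for k, v in cfg.rois.items()}
    return d


def load_participant_dir(sub_dir: str | Path) -> dict:
    """Load one persisted participant: events DataFrames, confounds and ROI
    series, keyed the way the GLM stage consumes them."""
    sub_dir = Path(sub_dir)
    events = {}
    for f in sorted((sub_dir / "events").glob("*_events.tsv")):
        run = int(f.stem.split("run-")[1].split("_")[0])
        events[run] = pd.read_csv(f, sep="\t")
    confounds = {}
    for f in sorted((sub_dir / "confounds").glob("run-*_confounds.tsv")):
        run = int(f.stem.split("run-")[1].split("_")[0])
        confounds[run] = MotionSeries(pd.read_csv(f, sep="\t").to_numpy().T)
    rois: dict[str, dict[int, RoiTimeSeries]] = {}
    for roi_dir in sorted(sub_dir.glob("roi-*")):
        label = roi_dir.name[len("roi-"):]
        rois[label] = {}
        for f in sorted(roi_dir.glob("run-*_bold.npy")):
            run = int(f.stem.split("run-")[1].split("_")[0])
            meta = json.loads(f.with_suffix(".json").read_text())
            rois[label][run] = RoiTimeSeries(
                roi_label=label, data=np.load(f), tr_s=meta["tr_s"], run=run
            )
    return {"events": events, "confounds": confounds, "rois": rois}
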