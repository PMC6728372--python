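"""Virtual-environment task design: arena geometry, passive paths, trial tables.

The task takes place in a square arena bounded by invisible walls and
surrounded by four global landmarks rendered at infinity, one per cardinal
direction. Four elongated rectangular boundaries stand inside the arena, two
with their long axis running north--south and two east--west. Each boundary
exposes two long faces, so there are eight "boundary sides"; a trial shows the
participant a passive approach along one of three predefined paths per side,
with the boundary ending up to the participant's left, right, or straight
ahead (24 paths in total). A cue object placed left or right of the path
defines an allocentric goal direction (the participant's heading rotated
+/-90 degrees), and the required response is the landmark lying in that
direction.

Compass convention: north = +y, east = +x, clockwise-positive angular
offsets, so "right of heading" means heading rotated +90 degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DIRECTIONS",
    "EGO_POSITIONS",
    "Boundary",
    "EnvironmentSpec",
    "PathSpec",
    "TrialEvent",
    "TrialTable",
    "JrdQuestion",
    "BalanceReport",
    "DesignError",
    "rotate_direction",
    "build_environment",
    "enumerate_paths",
    "build_trial_table",
    "relative_landmark",
    "enumerate_jrd",
    "verify_balance",
    "occupancy_fraction",
    "side_masks",
    "write_events_tsv",
]

#: Cardinal directions in clockwise order starting north.
DIRECTIONS = ("N", "E", "S", "W")

#: Egocentric positions of the boundary relative to the participant.
EGO_POSITIONS = ("left", "right", "front")

_ANGLE = {"N": 0, "E": 90, "S": 180, "W": 270}
_FROM_ANGLE = {v: k for k, v in _ANGLE.items()}

DEFAULT_LANDMARKS = {"Mountain": "N", "Cathedral": "S", "ClockTower": "E", "City": "W"}
DEFAULT_TEXTURES = ("brick_red", "brick_grey", "brick_yellow", "brick_brown")


class DesignError(ValueError):
    """Raised for invalid design configurations."""


def rotate_direction(direction: str, offset_deg: float) -> str:
    """Rotate a cardinal direction clockwise by a multiple of 90 degrees."""
    if offset_deg % 90 != 0:
        raise DesignError(f"offset must be a multiple of 90 degrees, got {offset_deg}")
    return _FROM_ANGLE[(_ANGLE[direction] + int(offset_deg)) % 360]


@dataclass(frozen=True)
class Boundary:
    """One rectangular boundary inside the arena.

    ``long_axis`` is ``"NS"`` (long side runs north--south, faces visible from
    east and west) or ``"EW"`` (faces visible from north and south).
    """

    boundary_id: int
    texture: str
    centre_xy: tuple[float, float]
    long_axis: str  # "NS" | "EW"
    length: float = 40.0
    width: float = 2.0

    @property
    def sides(self) -> tuple[str, str]:
        """Allocentric boundary directions served by this boundary.

        A participant south of an EW boundary looks at its south face and has
        the boundary to their north, so an EW boundary serves allocentric
        directions N and S; an NS boundary serves E and W.
        """
        return ("N", "S") if self.long_axis == "EW" else ("E", "W")

    def face_outward_normal(self, side: str) -> str:
        """Compass direction of the outward normal of the face whose viewers
        have allocentric boundary direction ``side`` (the opposite compass
        direction: the N side is viewed from the south)."""
        return rotate_direction(side, 180)


@dataclass(frozen=True)
class EnvironmentSpec:
    """Geometry and labelling of the virtual arena."""

    arena_extent: tuple[float, float] = (600.0, 600.0)
    explorable_extent: tuple[float, float] = (500.0, 500.0)
    boundaries: tuple[Boundary, ...] = ()
    landmark_compass: Mapping[str, str] = field(default_factory=dict)
    boundary_mask_depth: float = 5.0

    @property
    def compass_landmark(self) -> dict[str, str]:
        """Inverse landmark map: cardinal direction -> landmark name."""
        return {d: lm for lm, d in self.landmark_compass.items()}

    def validate(self) -> None:
        if len(self.boundaries) != 4:
            raise DesignError(f"expected 4 boundaries, got {len(self.boundaries)}")
        axes = [b.long_axis for b in self.boundaries]
        if axes.count("NS") != 2 or axes.count("EW") != 2:
            raise DesignError("need exactly 2 NS and 2 EW boundaries")
        dirs = sorted(self.landmark_compass.values())
        if dirs != sorted(DIRECTIONS) or len(self.landmark_compass) != 4:
            raise DesignError("landmark_compass must be a bijection over N/S/E/W")
        textures = [b.texture for b in self.boundaries]
        if len(set(textures)) != 4:
            raise DesignError("boundary textures must be distinct")
        hx, hy = self.explorable_extent[0] / 2, self.explorable_extent[1] / 2
        for b in self.boundaries:
            lx, ly = (b.width, b.length) if b.long_axis == "NS" else (b.length, b.width)
            cx, cy = b.centre_xy
            if abs(cx) + lx / 2 >= hx or abs(cy) + ly / 2 >= hy:
                raise DesignError(f"boundary {b.boundary_id} outside explorable area")


def build_environment(
    landmarks: Mapping[str, str] | Sequence[str] | None = None,
    textures: Sequence[str] = DEFAULT_TEXTURES,
    boundary_offset: float = 125.0,
    arena_extent: tuple[float, float] = (600.0, 600.0),
    explorable_extent: tuple[float, float] = (500.0, 500.0),
    boundary_mask_depth: float = 5.0,
) -> EnvironmentSpec:
    """Build the default arena: 600 x 600 m with a centred 500 x 500 m
    explorable area, four 40 x 2 m boundaries placed symmetrically about the
    centre, and one landmark per cardinal direction.

    ``landmarks`` may be a mapping name -> direction or a sequence of four
    names assigned to N, S, E, W in order; by default Mountain faces north,
    Cathedral south, ClockTower east and City west.
    """
    if landmarks is None:
        lm_map = dict(DEFAULT_LANDMARKS)
    elif isinstance(landmarks, Mapping):
        lm_map = dict(landmarks)
    else:
        if len(landmarks) != 4:
            raise DesignError(f"need 4 landmarks, got {len(landmarks)}")
        lm_map = dict(zip(landmarks, ("N", "S", "E", "W")))
    if len(set(lm_map)) != 4:
        raise DesignError("landmark labels must be distinct")
    if len(set(textures)) != 4 or len(tuple(textures)) != 4:
        raise DesignError("need 4 distinct boundary textures")
    t = tuple(textures)
    boundaries = (
        Boundary(1, t[0], (0.0, +boundary_offset), "EW"),
        Boundary(2, t[1], (0.0, -boundary_offset), "EW"),
        Boundary(3, t[2], (+boundary_offset, 0.0), "NS"),
        Boundary(4, t[3], (-boundary_offset, 0.0), "NS"),
    )
    env = EnvironmentSpec(
        arena_extent=tuple(arena_extent),
        explorable_extent=tuple(explorable_extent),
        boundaries=boundaries,
        landmark_compass=lm_map,
        boundary_mask_depth=boundary_mask_depth,
    )
    env.validate()
    return env


@dataclass(frozen=True)
class PathSpec:
    """One of the 24 predefined passive approach paths.

    ``boundary_side`` is the allocentric boundary direction of trials on this
    path: the compass direction of the boundary as seen from the participant.
    ``heading`` follows from the egocentric position of the boundary: a
    "front" path heads straight at the boundary; on a "left" path the
    participant heads 90 degrees clockwise of the boundary direction (so the
    boundary lies to their left), and mirror-image for "right".
    """

    path_id: int
    boundary_id: int
    boundary_side: str
    ego_boundary: str
    heading: str


_EGO_TO_OFFSET = {"front": 0, "left": 90, "right": -90}


def heading_for(boundary_side: str, ego_boundary: str) -> str:
    """Heading implied by an allocentric boundary direction and an egocentric
    boundary position (front => toward it; left => boundary 90 deg CCW)."""
    return rotate_direction(boundary_side, _EGO_TO_OFFSET[ego_boundary])


def enumerate_paths(env: EnvironmentSpec) -> list[PathSpec]:
    """Enumerate the 24 paths: 4 boundaries x 2 sides x 3 egocentric positions."""
    env.validate()
    paths = []
    pid = 1
    for b in env.boundaries:
        for side in b.sides:
            for ego in EGO_POSITIONS:
                paths.append(PathSpec(pid, b.boundary_id, side, ego, heading_for(side, ego)))
                pid += 1
    return paths


# --- trial table ------------------------------------------------------------

MOVEMENT_S = 2.0
BLANK_S = 4.0
DECISION_S = 2.0
TRIAL_SPAN_S = MOVEMENT_S + BLANK_S + DECISION_S  # 8 s


@dataclass(frozen=True)
class TrialEvent:
    run: int
    trial_index: int
    onset_s: float
    path_id: int
    cue_side: str  # left | right
    allo_boundary: str
    allo_goal: str
    ego_boundary: str
    heading: str
    facing_landmark: str
    correct_response_landmark: str
    iti_s: float
    movement_duration: float = MOVEMENT_S
    blank_duration: float = BLANK_S
    decision_duration: float = DECISION_S


@dataclass
class TrialTable:
    """Per-run ordered trial lists for one scan session."""

    runs: dict[int, list[TrialEvent]]
    design_seed: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def events(self, run: int) -> list[TrialEvent]:
        return self.runs[run]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for run in sorted(self.runs):
            for ev in self.runs[run]:
                rows.append(
                    {
                        "run": run,
                        "trial_index": ev.trial_index,
                        "onset": ev.onset_s,
                        "duration": TRIAL_SPAN_S,
                        "path_id": ev.path_id,
                        "cue_side": ev.cue_side,
                        "allo_boundary": ev.allo_boundary,
                        "allo_goal": ev.allo_goal,
                        "ego_boundary": ev.ego_boundary,
                        "heading": ev.heading,
                        "facing_landmark": ev.facing_landmark,
                        "response_landmark": ev.correct_response_landmark,
                        "iti": ev.iti_s,
                    }
                )
        return pd.DataFrame(rows)


def build_trial_table(
    paths: Sequence[PathSpec],
    env: EnvironmentSpec,
    n_runs: int = 3,
    reps_per_run: int = 4,
    iti_mean: float = 1.0,
    iti_jitter: float = 0.5,
    lead_in_s: float = 10.0,
    seed: int = 0,
) -> TrialTable:
    """Build the randomised trial tables: each path repeated ``reps_per_run``
    times per run, the cue object on the left for half the repetitions and on
    the right for the other half, trial order permuted independently per run,
    and inter-trial intervals drawn uniformly from
    ``iti_mean +/- iti_jitter`` seconds.
    """
    if reps_per_run % 2 != 0:
        raise DesignError("reps_per_run must be even to balance cue side")
    compass_landmark = env.compass_landmark
    rng = np.random.default_rng(seed)
    runs: dict[int, list[TrialEvent]] = {}
    for run in range(1, n_runs + 1):
        stubs = [
            (p, side)
            for p in paths
            for side in ["left"] * (reps_per_run // 2) + ["right"] * (reps_per_run // 2)
        ]
        order = rng.permutation(len(stubs))
        itis = rng.uniform(iti_mean - iti_jitter, iti_mean + iti_jitter, size=len(stubs))
        events = []
        onset = lead_in_s
        for idx, k in enumerate(order):
            path, cue_side = stubs[k]
            goal = rotate_direction(path.heading, 90 if cue_side == "right" else -90)
            events.append(
                TrialEvent(
                    run=run,
                    trial_index=idx,
                    onset_s=onset,
                    path_id=path.path_id,
                    cue_side=cue_side,
                    allo_boundary=path.boundary_side,
                    allo_goal=goal,
                    ego_boundary=path.ego_boundary,
                    heading=path.heading,
                    facing_landmark=compass_landmark[path.heading],
                    correct_response_landmark=compass_landmark[goal],
                    iti_s=float(itis[idx]),
                )
            )
            onset += TRIAL_SPAN_S + itis[idx]
        runs[run] = events
    return TrialTable(runs=runs, design_seed=seed)


def relative_landmark(facing: str, offset_deg: float, env: EnvironmentSpec) -> str:
    """Landmark located ``offset_deg`` clockwise of the ``facing`` landmark.

    E.g. facing the north landmark, +90 degrees (to the right) names the east
    landmark.
    """
    if facing not in env.landmark_compass:
        raise DesignError(f"unknown landmark {facing!r}")
    d = rotate_direction(env.landmark_compass[facing], offset_deg)
    return env.compass_landmark[d]


@dataclass(frozen=True)
class JrdQuestion:
    """One judgement-of-relative-direction question: imagine facing one
    landmark, report whether another lies to your right (90 deg clockwise),
    behind (180) or left (270)."""

    facing_landmark: str
    probe_landmark: str
    angular_disparity: int  # 90 | 180 | 270 clockwise
    correct_response: str  # right | behind | left


_DISPARITY_RESPONSE = {90: "right", 180: "behind", 270: "left"}


def enumerate_jrd(env: EnvironmentSpec) -> list[JrdQuestion]:
    """All 12 ordered landmark pairs with the clockwise disparity and response."""
    env.validate()
    questions = []
    for facing, fd in env.landmark_compass.items():
        for probe, pd_ in env.landmark_compass.items():
            if probe == facing:
                continue
            disparity = (_ANGLE[pd_] - _ANGLE[fd]) % 360
            questions.append(
                JrdQuestion(facing, probe, disparity, _DISPARITY_RESPONSE[disparity])
            )
    return questions


# --- balance verification ---------------------------------------------------


@dataclass
class BalanceReport:
    """Counter-balancing audit for one grouping factor of a trial table.

    For every level of the factor (and every run) it tabulates the cue side,
    egocentric boundary position, boundary texture and the complementary
    allocentric factor, and flags whether the design is balanced the way the
    orthogonality of the two allocentric factors requires.
    """

    factor: str
    n_trials: int
    level_counts: dict[str, dict[str, dict]]  # level -> run -> counts
    flags: dict[str, dict[str, bool]]  # level -> named flag -> pass

    @property
    def all_pass(self) -> bool:
        return all(v for level in self.flags.values() for v in level.values())


def verify_balance(table: TrialTable, factor: str, env: EnvironmentSpec) -> BalanceReport:
    """Audit the trial table's counter-balancing with respect to ``factor``
    (``"allo_boundary"`` or ``"allo_goal"``).

    For each level of the factor, balance requires (per run): equal left/right
    cue-side counts, equal left/right/front egocentric boundary counts, equal
    representation of both boundary textures serving that direction, and all
    four levels of the other allocentric factor present.
    """
    if factor not in ("allo_boundary", "allo_goal"):
        raise DesignError(f"unknown balance factor {factor!r}")
    other = "allo_goal" if factor == "allo_boundary" else "allo_boundary"
    texture_of = {b.boundary_id: b.texture for b in env.boundaries}
    # the two boundaries whose faces serve a given allocentric direction
    level_textures = {
        d: {b.texture for b in env.boundaries if d in b.sides} for d in DIRECTIONS
    }
    df = table.to_dataframe()
    path_boundary = {
        p.path_id: p.boundary_id for p in enumerate_paths(env)
    }
    df["texture"] = df["path_id"].map(lambda pid: texture_of[path_boundary[pid]])

    level_counts: dict[str, dict[str, dict]] = {}
    flags: dict[str, dict[str, bool]] = {}
    for level in DIRECTIONS:
        level_counts[level] = {}
        cue_ok = ego_ok = tex_ok = other_ok = True
        for run, sub in df[df[factor] == level].groupby("run"):
            cue = sub["cue_side"].value_counts().to_dict()
            ego = sub["ego_boundary"].value_counts().to_dict()
            tex = sub["texture"].value_counts().to_dict()
            oth = sub[other].value_counts().to_dict()
            level_counts[level][str(run)] = {
                "cue_side": cue,
                "ego_boundary": ego,
                "texture": tex,
                other: oth,
            }
            cue_ok &= len(set(cue.get(s, 0) for s in ("left", "right"))) == 1
            ego_ok &= len(set(ego.get(s, 0) for s in EGO_POSITIONS)) == 1
            own = [tex.get(t, 0) for t in level_textures[level]]
            tex_ok &= min(own) > 0 and len(set(own)) == 1
            other_ok &= set(oth) == set(DIRECTIONS)
        flags[level] = {
            "cue_side_balanced": cue_ok,
            "ego_boundary_balanced": ego_ok,
            "textures_balanced": tex_ok,
            "other_factor_complete": other_ok,
        }
    return BalanceReport(
        factor=factor, n_trials=len(df), level_counts=level_counts, flags=flags
    )


# --- behavioural occupancy --------------------------------------------------


def side_masks(env: EnvironmentSpec, bin_size: float = 5.0) -> dict[str, list[tuple]]:
    """Bin-aligned boundary-proximity masks, keyed by allocentric direction.

    Each of the 8 boundary faces gets a 40 m x ``mask_depth`` strip on its
    outward side, snapped to the occupancy grid (bins whose centres lie within
    the strip). Returns direction -> list of (xmin, xmax, ymin, ymax) rects.
    """
    masks: dict[str, list[tuple]] = {d: [] for d in DIRECTIONS}
    depth = env.boundary_mask_depth
    for b in env.boundaries:
        cx, cy = b.centre_xy
        for side in b.sides:
            normal = b.face_outward_normal(side)  # direction the face points
            if b.long_axis == "EW":
                x0, x1 = cx - b.length / 2, cx + b.length / 2
                face_y = cy + b.width / 2 if normal == "N" else cy - b.width / 2
                y0, y1 = (face_y, face_y + depth) if normal == "N" else (face_y - depth, face_y)
            else:
                y0, y1 = cy - b.length / 2, cy + b.length / 2
                face_x = cx + b.width / 2 if normal == "E" else cx - b.width / 2
                x0, x1 = (face_x, face_x + depth) if normal == "E" else (face_x - depth, face_x)
            masks[side].append(_snap_rect((x0, x1, y0, y1), env, bin_size))
    return masks


def _snap_rect(rect, env, bin_size):
    """Snap a rectangle to grid-bin edges, keeping bins whose centres fall inside."""
    hx, hy = env.explorable_extent[0] / 2, env.explorable_extent[1] / 2
    x0, x1, y0, y1 = rect
    edges_x = np.arange(-hx, hx + bin_size / 2, bin_size)
    edges_y = np.arange(-hy, hy + bin_size / 2, bin_size)
    cx = (edges_x[:-1] + edges_x[1:]) / 2
    cy = (edges_y[:-1] + edges_y[1:]) / 2
    ix = np.where((cx > x0) & (cx < x1))[0]
    iy = np.where((cy > y0) & (cy < y1))[0]
    if len(ix) == 0 or len(iy) == 0:
        raise DesignError("mask strip does not cover any occupancy bin")
    return (edges_x[ix[0]], edges_x[ix[-1] + 1], edges_y[iy[0]], edges_y[iy[-1] + 1])


def occupancy_fraction(
    positions: np.ndarray,
    timestamps: np.ndarray,
    env: EnvironmentSpec,
    bin_size: float = 5.0,
) -> dict:
    """Fraction of exploration time spent next to the boundaries.

    The explorable area is divided into ``bin_size`` x ``bin_size`` m bins
    (100 x 100 = 10,000 bins at the defaults) and the dwell time per bin is
    normalised to sum to 1. Each position sample is weighted by the time to
    the next sample; the final sample gets the median sampling interval.
    Returns the full histogram, the time fraction per allocentric boundary
    direction (two 40 x 5 m face strips each) and the total across all eight
    strips.
    """
    positions = np.asarray(positions, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if positions.size == 0:
        raise DesignError("empty trajectory")
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise DesignError("positions must be (n, 2)")
    if len(timestamps) != len(positions):
        raise DesignError("timestamps and positions length mismatch")
    if np.any(np.diff(timestamps) <= 0):
        raise DesignError("timestamps must be strictly increasing")
    hx, hy = env.explorable_extent[0] / 2, env.explorable_extent[1] / 2
    if np.any(np.abs(positions[:, 0]) > hx) or np.any(np.abs(positions[:, 1]) > hy):
        raise DesignError("positions outside explorable extent")

    if len(timestamps) > 1:
        dt = np.diff(timestamps)
        weights = np.append(dt, np.median(dt))
    else:
        weights = np.ones(1)
    edges_x = np.arange(-hx, hx + bin_size / 2, bin_size)
    edges_y = np.arange(-hy, hy + bin_size / 2, bin_size)
    hist, _, _ = np.histogram2d(
        positions[:, 0], positions[:, 1], bins=[edges_x, edges_y], weights=weights
    )
    hist /= hist.sum()

    cx = (edges_x[:-1] + edges_x[1:]) / 2
    cy = (edges_y[:-1] + edges_y[1:]) / 2
    per_direction = {}
    for d, rects in side_masks(env, bin_size).items():
        frac = 0.0
        for (x0, x1, y0, y1) in rects:
            ix = (cx > x0) & (cx < x1)
            iy = (cy > y0) & (cy < y1)
            frac += hist[np.ix_(ix, iy)].sum()
        per_direction[d] = float(frac)
    return {
        "histogram": hist,
        "n_bins": hist.size,
        "per_direction": per_direction,
        "total": float(sum(per_direction.values())),
    }


# --- external interfaces ----------------------------------------------------

EVENTS_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "path_id",
    "cue_side",
    "allo_boundary",
    "allo_goal",
    "ego_boundary",
    "facing_landmark",
    "response_landmark",
]


def write_events_tsv(table: TrialTable, out_dir: str | Path, prefix: str = "task-allo") -> list[Path]:
    """Write one BIDS-style events TSV per run plus a design-seed sidecar JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for run in sorted(table.runs):
        rows = []
        for ev in table.runs[run]:
            rows.append(
                {
                    "onset": f"{ev.onset_s:.3f}",
                    "duration": f"{TRIAL_SPAN_S:.3f}",
                    "trial_type": f"B{ev.allo_boundary}-G{ev.allo_goal}",
                    "path_id": ev.path_id,
                    "cue_side": ev.cue_side,
                    "allo_boundary": ev.allo_boundary,
                    "allo_goal": ev.allo_goal,
                    "ego_boundary": ev.ego_boundary,
                    "facing_landmark": ev.facing_landmark,
                    "response_landmark": ev.correct_response_landmark,
                }
            )
        path = out_dir / f"{prefix}_run-{run:02d}_events.tsv"
        pd.DataFrame(rows, columns=EVENTS_COLUMNS).to_csv(path, sep="\t", index=False)
        written.append(path)
    sidecar = out_dir / f"{prefix}_design.json"
    sidecar.write_text(json.dumps({"design_seed": table.design_seed}, indent=1))
    return written


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    """Read one events TSV written by :func:`write_events_tsv`."""
    return pd.read_csv(path, sep="\t")
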