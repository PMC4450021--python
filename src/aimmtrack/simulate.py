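"""Synthetic multi-cell scenarios: ground truth, detections, images, PAP.

A :class:`ScenarioScript` declares, per cell, a birth frame, an initial
augmented state and a sequence of motion segments (constant velocity or
coordinate turn at a given rate), plus an event list: pairwise collision
spans (the partners co-locate and produce one merged detection with summed
area), divisions (the parent splits into two daughters of complementary
area placed half a mean diameter either side of the motion axis) and exits.
From the script the module generates

* ``simulate_truth`` — the exact per-frame states with lineage,
* ``render_detections`` — noisy (x, y, area) detection lists with Bernoulli
  misses and Poisson clutter,
* ``render_images`` — grayscale frames of Gaussian blobs whose integrated
  intensity is proportional to cell area, for exercising the detector,

and evaluates trackers with the PAP score (percentage of attained
positions): the share of ground-truth positions covered, within a match
radius, by a track whose label keeps the correct persistent identity
(labels are mapped to truth cells once, at their first match).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import Detection
from .dynamics import acv_apply, ct_apply, noise_gain


@dataclass(frozen=True)
class Segment:
    """One motion segment: 'cv' or 'ct' at turn rate omega for n_frames."""

    mode: str
    omega: float = 0.0
    n_frames: int = 10**9  # last segment extends to the end of the run

    def __post_init__(self) -> None:
        if self.mode not in ("cv", "ct"):
            raise ValueError("segment mode must be 'cv' or 'ct'")
        if self.n_frames <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class CellScript:
    cell_id: int
    birth_frame: int
    state0: tuple[float, float, float, float, float, float]  # x,y,vx,vy,omega,s
    segments: tuple[Segment, ...] = (Segment("cv"),)


@dataclass(frozen=True)
class CollisionEvent:
    """Cells a and b share one merged detection during frames [start, end]."""

    a: int
    b: int
    start: int
    end: int


@dataclass(frozen=True)
class DivisionEvent:
    """Cell divides at ``frame``; the parent id continues as the daughter
    holding ``frac`` of the area, a fresh id takes the rest."""

    cell: int
    frame: int
    frac: float = 0.5
    sep_speed: float = 0.5  # px/frame, daughters drift apart


@dataclass(frozen=True)
class ExitEvent:
    cell: int
    frame: int


@dataclass(frozen=True)
class ScenarioScript:
    n_frames: int
    width: float = 200.0
    height: float = 200.0
    cells: tuple[CellScript, ...] = ()
    collisions: tuple[CollisionEvent, ...] = ()
    divisions: tuple[DivisionEvent, ...] = ()
    exits: tuple[ExitEvent, ...] = ()
    T: float = 1.0
    process_noise: tuple[float, ...] = (0, 0, 0, 0, 0, 0)  # Q diagonal
    R: tuple[float, float, float] = (1.0, 1.0, 1.0)
    miss_rate: float = 0.02
    clutter_rate: float = 0.05  # expected clutter detections per frame
    mean_diameter: float = 12.0

    def validate(self) -> None:
        ids = {c.cell_id for c in self.cells}
        if len(ids) != len(self.cells):
            raise ValueError("duplicate cell ids")
        for ev in self.collisions:
            if ev.a not in ids or ev.b not in ids or ev.start > ev.end:
                raise ValueError(f"invalid collision event {ev}")
        for ev in self.divisions:
            if ev.cell not in ids or not 0 < ev.frac < 1:
                raise ValueError(f"invalid division event {ev}")
        for ev in self.exits:
            if ev.cell not in ids:
                raise ValueError(f"invalid exit event {ev}")
        if not 0 <= self.miss_rate < 1 or self.clutter_rate < 0:
            raise ValueError("invalid noise rates")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


TRUTH_COLUMNS = [
    "frame", "cell", "x", "y", "vx", "vy", "omega", "s", "parent", "merged_with",
]


def _segment_at(segments: tuple[Segment, ...], age: int) -> Segment:
    for seg in segments:
        if age < seg.n_frames:
            return seg
        age -= seg.n_frames
    return segments[-1]


def simulate_truth(
    script: ScenarioScript, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate exact per-frame ground truth as a tidy DataFrame.

    States propagate with the same constant-velocity / coordinate-turn
    kinematics the tracker assumes; optional process noise G v with
    v ~ N(0, diag(process_noise)) is added when an rng is supplied.
    During a collision span the partners' recorded positions are
    co-located at their midpoint and flagged with each other's id.
    """
    script.validate()
    if rng is None:
        rng = np.random.default_rng(0)
    q = np.asarray(script.process_noise, dtype=float)
    gain = np.diag(noise_gain(script.T))
    next_id = max((c.cell_id for c in script.cells), default=0) + 1
    states: dict[int, np.ndarray] = {}
    meta: dict[int, dict] = {}
    rows = []
    for k in range(script.n_frames):
        for c in script.cells:
            if c.birth_frame == k:
                states[c.cell_id] = np.asarray(c.state0, dtype=float)
                meta[c.cell_id] = {"segments": c.segments, "age": 0, "parent": -1}
        for ev in script.exits:
            if ev.frame == k and ev.cell in states:
                del states[ev.cell]
        for ev in script.divisions:
            if ev.frame == k and ev.cell in states:
                s = states[ev.cell]
                v = s[2:4]
                speed = float(np.hypot(*v))
                perp = (
                    np.array([-v[1], v[0]]) / speed if speed > 0 else np.array([0.0, 1.0])
                )
                off = perp * script.mean_diameter / 2.0
                sep = perp * ev.sep_speed
                area = s[5]
                d1 = s.copy()
                d1[:2] += off
                d1[2:4] += sep
                d1[5] = area * ev.frac
                d2 = s.copy()
                d2[:2] -= off
                d2[2:4] -= sep
                d2[5] = area * (1.0 - ev.frac)
                states[ev.cell] = d1
                states[next_id] = d2
                meta[next_id] = {
                    "segments": (Segment("cv"),),
                    "age": 0,
                    "parent": ev.cell,
                }
                meta[ev.cell] = dict(meta[ev.cell], segments=(Segment("cv"),), age=0)
                next_id += 1
        merged: dict[int, int] = {}
        shared: dict[int, np.ndarray] = {}
        for ev in script.collisions:
            if ev.start <= k <= ev.end and ev.a in states and ev.b in states:
                merged[ev.a] = ev.b
                merged[ev.b] = ev.a
                mid = (states[ev.a][:2] + states[ev.b][:2]) / 2.0
                shared[ev.a] = mid
                shared[ev.b] = mid
        for cid in sorted(states):
            s = states[cid]
            pos = shared.get(cid, s[:2])
            rows.append(
                (k, cid, pos[0], pos[1], s[2], s[3], s[4], s[5],
                 meta[cid]["parent"], merged.get(cid, -1))
            )
        # propagate to the next frame
        for cid in sorted(states):
            seg = _segment_at(meta[cid]["segments"], meta[cid]["age"])
            meta[cid]["age"] += 1
            s = states[cid][None, :]
            if seg.mode == "cv":
                out = acv_apply(s, script.T)
            else:
                s = s.copy()
                s[0, 4] = seg.omega
                out = ct_apply(s, script.T, 1.0)
            out = out[0]
            if np.any(q > 0):
                out = out + gain * np.sqrt(q) * rng.standard_normal(6)
                out[5] = max(out[5], 1.0)
            states[cid] = out
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def _bbox(x: float, y: float, area: float) -> tuple[int, int, int, int]:
    side = max(1, int(round(np.sqrt(max(area, 1.0)))))
    return (int(round(x - side / 2)), int(round(y - side / 2)), side, side)


def render_detections(
    truth: pd.DataFrame,
    R: tuple[float, float, float],
    miss_rate: float,
    clutter_rate: float,
    rng: np.random.Generator,
    width: float = 200.0,
    height: float = 200.0,
) -> list[list[Detection]]:
    """Noisy per-frame detection lists from ground truth.

    Each alive cell yields one (x, y, area) detection perturbed by N(0, R);
    partners in a collision span share a single detection with summed area.
    Detections are dropped with probability ``miss_rate`` and Poisson
    clutter (uniform position, cell-scale area) is appended.
    """
    r = np.sqrt(np.asarray(R, dtype=float))
    n_frames = int(truth["frame"].max()) + 1 if len(truth) else 0
    frames: list[list[Detection]] = []
    areas = truth["s"].to_numpy()
    typical_area = float(np.median(areas)) if len(areas) else 100.0
    for k in range(n_frames):
        sub = truth[truth["frame"] == k]
        dets: list[Detection] = []
        done_pairs: set[frozenset[int]] = set()
        for row in sub.itertuples(index=False):
            if row.merged_with >= 0:
                pair = frozenset((int(row.cell), int(row.merged_with)))
                if pair in done_pairs:
                    continue
                done_pairs.add(pair)
                partner = sub[sub["cell"] == row.merged_with]
                area = row.s + (float(partner["s"].iloc[0]) if len(partner) else 0.0)
            else:
                area = row.s
            if not (0 <= row.x < width and 0 <= row.y < height):
                continue
            if rng.uniform() < miss_rate:
                continue
            x = row.x + rng.normal(0.0, r[0])
            y = row.y + rng.normal(0.0, r[1])
            a = max(1, int(round(area + rng.normal(0.0, r[2]))))
            dets.append(Detection(x, y, a, _bbox(x, y, a)))
        for _ in range(rng.poisson(clutter_rate)):
            x = rng.uniform(0, width)
            y = rng.uniform(0, height)
            a = max(1, int(round(typical_area * rng.uniform(0.5, 1.5))))
            dets.append(Detection(x, y, a, _bbox(x, y, a)))
        frames.append(dets)
    return frames


def render_images(
    truth: pd.DataFrame,
    width: int = 200,
    height: int = 200,
    blob_sigma: float = 2.5,
    snr: float = 20.0,
    gain: float = 70.0,
    background: float = 20.0,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Grayscale frames of isotropic Gaussian blobs.

    Each cell contributes a blob of integrated intensity ``gain * area``
    (mass proportional to area), so a typical 100 px^2 cell peaks near
    gain * 100 / (2 pi sigma^2).  Gaussian background noise is added with
    std = typical peak / snr.  Frames are clipped to [0, 255].
    """
    if rng is None:
        rng = np.random.default_rng(0)
    yy, xx = np.mgrid[0:height, 0:width]
    n_frames = int(truth["frame"].max()) + 1 if len(truth) else 0
    peak_typ = gain * 100.0 / (2.0 * np.pi * blob_sigma**2)
    noise_std = peak_typ / snr
    frames = []
    for k in range(n_frames):
        sub = truth[truth["frame"] == k]
        img = np.full((height, width), background, dtype=float)
        for row in sub.itertuples(index=False):
            mass = gain * row.s
            amp = mass / (2.0 * np.pi * blob_sigma**2)
            img += amp * np.exp(
                -((xx - row.x) ** 2 + (yy - row.y) ** 2) / (2.0 * blob_sigma**2)
            )
        img += rng.normal(0.0, noise_std, img.shape)
        frames.append(np.clip(img, 0.0, 255.0))
    return frames


def map_labels(
    tracks: pd.DataFrame, truth: pd.DataFrame, match_radius: float
) -> dict[int, int]:
    """Persistent label -> truth-cell mapping, fixed at each label's first
    match (nearest alive truth position within the match radius)."""
    mapping: dict[int, int] = {}
    for label, grp in tracks.groupby("label", sort=True):
        grp = grp.sort_values("frame")
        for row in grp.itertuples(index=False):
            sub = truth[truth["frame"] == row.frame]
            if not len(sub):
                continue
            d = np.hypot(sub["x"] - row.x, sub["y"] - row.y)
            j = int(np.argmin(d.to_numpy()))
            if d.to_numpy()[j] <= match_radius:
                mapping[int(label)] = int(sub["cell"].to_numpy()[j])
                break
    return mapping


def pap(
    tracks: pd.DataFrame, truth: pd.DataFrame, match_radius: float = 10.0
) -> float:
    """Percentage of attained positions.

    A ground-truth position counts as correctly tracked when some track
    label mapped to that cell (see :func:`map_labels`) reports a position
    within ``match_radius`` in that frame.  Returns 100 * correct / total.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be positive")
    if not len(truth):
        raise ValueError("ground truth is empty")
    mapping = map_labels(tracks, truth, match_radius)
    correct = 0
    total = 0
    for row in truth.itertuples(index=False):
        total += 1
        sub = tracks[(tracks["frame"] == row.frame)]
        for trow in sub.itertuples(index=False):
            if mapping.get(int(trow.label)) != int(row.cell):
                continue
            if np.hypot(trow.x - row.x, trow.y - row.y) <= match_radius:
                correct += 1
                break
    return 100.0 * correct / total


# ---------------------------------------------------------------------------
# Scripted study scenarios
# ---------------------------------------------------------------------------

def cv_script(
    n_frames: int = 50,
    state0: tuple = (500.0, 500.0, 2.0, 1.0, 0.0, 100.0),
    process_noise: tuple = (30.0, 30.0, 0.1, 0.1, 0.01, 0.01),
    R: tuple = (1.0, 1.0, 1.0),
) -> ScenarioScript:
    """Single cell, straight-line motion with linear-Gaussian noise."""
    return ScenarioScript(
        n_frames=n_frames,
        width=1000.0,
        height=1000.0,
        cells=(CellScript(1, 0, state0),),
        process_noise=process_noise,
        R=R,
        miss_rate=0.0,
        clutter_rate=0.0,
    )


def ct_script(
    omega: float = 0.1,
    n_frames: int = 60,
    speed: float = 3.0,
    R: tuple = (1.0, 1.0, 1.0),
) -> ScenarioScript:
    """Single cell on a constant-rate coordinate turn."""
    return ScenarioScript(
        n_frames=n_frames,
        width=1000.0,
        height=1000.0,
        cells=(
            CellScript(
                1,
                0,
                (500.0, 500.0, speed, 0.0, omega, 100.0),
                (Segment("ct", omega),),
            ),
        ),
        R=R,
        miss_rate=0.0,
        clutter_rate=0.0,
    )


def collision_script(
    merge_frame: int = 10,
    span: int = 1,
    n_frames: int = 24,
    areas: tuple[float, float] = (45.0, 65.0),
    R: tuple = (0.0, 0.0, 0.0),
) -> ScenarioScript:
    """Two cells converge, share a merged detection for ``span`` frames
    starting at ``merge_frame``, then separate on opposite turns."""
    # geometry: vertical gap closes at 2 px/frame and reaches ~2 px at the
    # merge frame; opposite coordinate turns reopen it afterwards
    gap0 = 2.0 * merge_frame + 2.0
    turn_at = merge_frame + span
    # cell 1 starts below and crosses to above at the merge: turning
    # counterclockwise afterwards carries it further up, and vice versa
    segs_a = (Segment("cv", 0.0, turn_at), Segment("ct", 0.15, 12), Segment("cv"))
    segs_b = (Segment("cv", 0.0, turn_at), Segment("ct", -0.15, 12), Segment("cv"))
    return ScenarioScript(
        n_frames=n_frames,
        width=300.0,
        height=300.0,
        cells=(
            CellScript(1, 0, (30.0, 150.0 - gap0 / 2, 2.0, 1.0, 0.0, areas[0]), segs_a),
            CellScript(2, 0, (30.0, 150.0 + gap0 / 2, 2.0, -1.0, 0.0, areas[1]), segs_b),
        ),
        collisions=(CollisionEvent(1, 2, merge_frame, merge_frame + span - 1),),
        R=R,
        miss_rate=0.0,
        clutter_rate=0.0,
    )


def division_script(
    divide_frame: int = 10,
    n_frames: int = 24,
    area: float = 100.0,
    frac: float = 0.48,
    R: tuple = (0.0, 0.0, 0.0),
) -> ScenarioScript:
    """One cell divides into two daughters of complementary area."""
    return ScenarioScript(
        n_frames=n_frames,
        width=300.0,
        height=300.0,
        cells=(CellScript(1, 0, (50.0, 150.0, 2.5, 0.0, 0.0, area)),),
        divisions=(DivisionEvent(1, divide_frame, frac),),
        R=R,
        miss_rate=0.0,
        clutter_rate=0.0,
    )


def benchmark_script(n_frames: int = 40) -> ScenarioScript:
    """Collision-rich reference scenario: five initial cells, one
    collision with later split, one division, one exit and one entry."""
    return ScenarioScript(
        n_frames=n_frames,
        width=200.0,
        height=200.0,
        cells=(
            CellScript(1, 0, (30.0, 30.0, 2.5, 0.5, 0.0, 100.0)),
            CellScript(
                2, 0, (40.0, 80.0, 2.0, 1.0, 0.0, 45.0),
                (Segment("cv", 0.0, 21), Segment("ct", 0.15, 10), Segment("cv")),
            ),
            CellScript(
                3, 0, (40.0, 120.0, 2.0, -1.0, 0.0, 65.0),
                (Segment("cv", 0.0, 21), Segment("ct", -0.15, 10), Segment("cv")),
            ),
            CellScript(4, 0, (150.0, 160.0, -1.0, -1.5, 0.0, 100.0)),
            CellScript(5, 0, (170.0, 40.0, 2.2, 0.0, 0.0, 80.0)),
            CellScript(6, 12, (5.0, 170.0, 2.0, -0.8, 0.0, 90.0)),
        ),
        collisions=(CollisionEvent(2, 3, 18, 20),),
        divisions=(DivisionEvent(4, 26, 0.48),),
        exits=(ExitEvent(5, 15),),
        R=(1.0, 1.0, 1.0),
        miss_rate=0.02,
        clutter_rate=0.05,
    )
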