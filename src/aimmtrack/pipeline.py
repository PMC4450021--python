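"""Per-frame orchestration: detect -> assess events -> filter -> associate.

``track_sequence`` consumes either grayscale frames (running the
morphological detector) or pre-computed per-frame detection lists, and
produces a tidy tracks table (one row per frame per carried label) plus a
lineage table of division records.  Each frame it

1. predicts every live track's position one sampling interval ahead,
2. runs correspondence and label management (merge/split/division cases,
   births, terminations),
3. evaluates the collision/division event probabilities for each
   associated track — area ratio against the track's previously associated
   area, distances against the nearest neighbouring track/detection — and
   derives the controls lambda and kappa,
4. steps each track's AIMMPF with its assigned measurement (predict-only
   when coasting), and
5. appends the per-track estimates to the output log.

Runs are deterministic under a fixed seed; the configuration hash is
recorded in the output header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import aimmpf, assoc, events, simulate
from .aimmpf import FilterConfig
from .assoc import GateParams, Track
from .detect import DetectConfig, Detection, detect_cells, rescale_intensity
from .events import EventParams

logger = logging.getLogger(__name__)

TRACK_COLUMNS = [
    "frame", "label", "x", "y", "vx", "vy", "omega", "s",
    "p_acv", "p_act1", "p_act2", "lambda", "kappa", "status",
]
LINEAGE_COLUMNS = ["child", "parent", "frame"]


@dataclass(frozen=True)
class RunConfig:
    """Complete run configuration: one section per pipeline stage."""

    seed: int = 0
    mean_diameter: float = 12.0  # px; sets event-kernel length scales
    match_radius: float = 10.0
    detect: DetectConfig = field(default_factory=DetectConfig)
    events: EventParams = field(default_factory=EventParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    gates: GateParams = field(default_factory=GateParams)

    def digest(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTION_TYPES = {
    "detect": DetectConfig,
    "events": EventParams,
    "filter": FilterConfig,
    "gates": GateParams,
}
_ARRAY_FIELDS = {"trans", "init_mode_probs", "R"}


def config_from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from nested plain dicts, rejecting unknown keys."""
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            names = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - names
            if bad:
                raise ValueError(f"unknown keys in [{key}]: {sorted(bad)}")
            sect = {
                k: (np.asarray(v, dtype=float) if k in _ARRAY_FIELDS else
                    ({m: np.asarray(q, dtype=float) for m, q in v.items()}
                     if k == "Q" else v))
                for k, v in value.items()
            }
            kwargs[key] = cls(**sect)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def scenario1_config(**overrides) -> RunConfig:
    """Collision-rich profile: wide gates, fast initial turn rate."""
    return replace(RunConfig(), **overrides)


def scenario2_config(**overrides) -> RunConfig:
    """Division profile: tight gates, slow turn rate, larger position noise."""
    cfg = RunConfig(
        filter=FilterConfig(
            Q={
                "acv": np.array([50.0, 50.0, 0.1, 0.1, 0.01, 0.01]),
                "act1": np.array([80.0, 80.0, 0.1, 0.1, 0.01, 0.01]),
                "act2": np.array([40.0, 40.0, 0.1, 0.1, 0.01, 0.01]),
            },
            omega0=0.1,
        ),
        gates=GateParams(delta1=5.0, delta2=5.0),
    )
    return replace(cfg, **overrides)


def smooth_config(**overrides) -> RunConfig:
    """Low-noise profile for smooth, clean sequences (e.g. turn-rate
    studies): small process noise, sub-pixel measurement noise, neutral
    turn-rate prior."""
    cfg = RunConfig(
        filter=FilterConfig(
            Q={m: np.array([0.5, 0.5, 0.05, 0.05, 0.0025, 0.01])
               for m in ("acv", "act1", "act2")},
            R=np.array([0.25, 0.25, 1.0]),
            omega0=0.0,
            init_vel_std=3.0,
            init_omega_std=0.5,
        ),
    )
    return replace(cfg, **overrides)


PROFILES = {
    "scenario1": scenario1_config,
    "scenario2": scenario2_config,
    "smooth": smooth_config,
}


# ---------------------------------------------------------------------------
# frame IO
# ---------------------------------------------------------------------------

def _natural_key(name: str):
    return [int(t) if t.isdigit() else t.lower() for t in re.split(r"(\d+)", name)]


def load_frames(paths_or_dir: str | Path | Sequence[str | Path]) -> list[np.ndarray]:
    """Read single-channel TIFF/PNG frames in natural filename order,
    rescaled onto [0, 255]."""
    if isinstance(paths_or_dir, (str, Path)) and Path(paths_or_dir).is_dir():
        paths = sorted(
            (p for p in Path(paths_or_dir).iterdir()
             if p.suffix.lower() in (".tif", ".tiff", ".png")),
            key=lambda p: _natural_key(p.name),
        )
    else:
        paths = [Path(p) for p in paths_or_dir]  # type: ignore[union-attr]
    frames = []
    for p in paths:
        img = np.asarray(iio.imread(p))
        if img.ndim == 3:  # collapse RGB
            img = img.mean(axis=2)
        frames.append(rescale_intensity(img.astype(float)))
    return frames


def detections_to_frame_lists(df: pd.DataFrame) -> list[list[Detection]]:
    """Convert a detections table (frame, x, y, area, bbox_*) to per-frame
    Detection lists."""
    n = int(df["frame"].max()) + 1 if len(df) else 0
    out: list[list[Detection]] = [[] for _ in range(n)]
    for row in df.itertuples(index=False):
        bbox = (
            int(getattr(row, "bbox_x", round(row.x))),
            int(getattr(row, "bbox_y", round(row.y))),
            int(getattr(row, "bbox_w", 1)),
            int(getattr(row, "bbox_h", 1)),
        )
        out[int(row.frame)].append(
            Detection(float(row.x), float(row.y), int(row.area), bbox)
        )
    return out


def detections_to_table(frames: Sequence[Sequence[Detection]]) -> pd.DataFrame:
    rows = [
        (k, i, d.x, d.y, d.area, *d.bbox)
        for k, dets in enumerate(frames)
        for i, d in enumerate(dets)
    ]
    return pd.DataFrame(
        rows,
        columns=["frame", "id", "x", "y", "area",
                 "bbox_x", "bbox_y", "bbox_w", "bbox_h"],
    )


def write_table(df: pd.DataFrame, path: str | Path, config: RunConfig | None = None) -> None:
    """CSV writer with the config hash recorded in a comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_sha256={config.digest()}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

@dataclass
class TrackingResult:
    tracks: pd.DataFrame
    lineage: pd.DataFrame
    config: RunConfig


def _nearest_distance(idx: int, points: np.ndarray) -> float:
    if len(points) < 2:
        return np.inf
    d = np.hypot(points[:, 0] - points[idx, 0], points[:, 1] - points[idx, 1])
    d[idx] = np.inf
    return float(d.min())


def track_sequence(
    detections: Sequence[Sequence[Detection]] | None = None,
    frames: Sequence[np.ndarray] | None = None,
    config: RunConfig | None = None,
    bounds: tuple[float, float] | None = None,
) -> TrackingResult:
    """Track every cell through a sequence.

    Exactly one of ``detections`` (per-frame Detection lists) or ``frames``
    (grayscale images, run through the detector) must be given.  Tracks
    from the first frame are confirmed immediately; later births are
    confirmed after two consecutive associations and discarded otherwise.
    """
    if (detections is None) == (frames is None):
        raise ValueError("provide exactly one of detections/frames")
    cfg = config or RunConfig()
    rng = np.random.default_rng(cfg.seed)
    if frames is not None:
        if not len(frames):
            raise ValueError("need at least one frame")
        if bounds is None:
            bounds = (float(frames[0].shape[1]), float(frames[0].shape[0]))
        detections = [detect_cells(f, cfg.detect) for f in frames]

    tracks: list[Track] = []
    rows: list[tuple] = []
    lineage: list[tuple[int, int, int]] = []
    neighbor_cut = 3.0 * cfg.mean_diameter

    for k, dets in enumerate(detections):
        live = [t for t in tracks if t.in_play]
        # 1. one-step-ahead prediction for gating (position from the
        #    filter estimate, area from the last associated detection)
        prev_pos = {}
        prev_area = {}
        for t in live:
            if t.bank is not None:
                _, est = aimmpf.estimate(t.bank, k - 1)
                st = est.state
                t.pred_x = st.x + st.vx * cfg.filter.T
                t.pred_y = st.y + st.vy * cfg.filter.T
                t.vx, t.vy = st.vx, st.vy
                prev_pos[t.label] = (st.x, st.y)
            else:
                prev_pos[t.label] = (t.pred_x, t.pred_y)
            t.pred_area = t.last_area
            prev_area[t.label] = t.last_area

        # 2. correspondence and label management
        tracks, res = assoc.manage_frame(
            tracks, dets, cfg.gates, frame=k, bounds=bounds
        )
        if k == 0:
            for t in tracks:
                t.status = "active"  # initial detections define the cells
        lineage.extend(res.lineage)

        # 3+4. event assessment and filter stepping
        pos_arr = np.array([[d.x, d.y] for d in dets]) if dets else np.empty((0, 2))
        labels_pos = list(prev_pos)
        ppos_arr = np.array([prev_pos[l] for l in labels_pos]) if labels_pos else np.empty((0, 2))
        for t in tracks:
            if not t.in_play:
                continue
            j = res.assignments.get(t.label)
            lam, kap = 1.0, 0.0
            if t.label in res.reinit:
                jj, vx, vy = res.reinit[t.label]
                d = dets[jj]
                t.bank = aimmpf.make_bank(
                    d.x, d.y, d.area, cfg.filter, rng, vx=vx, vy=vy
                )
                t.bank, est = aimmpf.estimate(t.bank, k)
            elif j is not None and t.bank is not None:
                d = dets[j]
                alpha = d.area / prev_area.get(t.label, d.area)
                # distance to the nearest other track in the previous frame
                d_prev = np.inf
                if t.label in labels_pos:
                    d_prev = _nearest_distance(labels_pos.index(t.label), ppos_arr)
                d_curr = _nearest_distance(j, pos_arr) if len(pos_arr) else np.inf
                if d_prev <= neighbor_cut:
                    pc = events.collision_probability(alpha, d_prev, cfg.events)
                    lam = events.collision_control(pc)
                if d_curr <= neighbor_cut:
                    pb = events.division_probability(alpha, d_curr, cfg.events)
                    kap = events.division_control(pb)
                t.bank, est = aimmpf.step(
                    t.bank,
                    np.array([d.x, d.y, float(d.area)]),
                    cfg.filter,
                    rng,
                    lam=lam,
                    kappa=kap,
                    frame=k,
                )
            elif t.bank is not None:
                # coasting: predict-only
                t.bank, est = aimmpf.step(
                    t.bank, None, cfg.filter, rng, frame=k
                )
            else:
                continue
            st = est.state
            t.vx, t.vy = st.vx, st.vy
            emit = [t.label] + (t.merge_partners if t.is_carrier else [])
            for lab in emit:
                status = t.status if lab == t.label else f"merged-into:{t.label}"
                rows.append(
                    (k, lab, st.x, st.y, st.vx, st.vy, st.omega, st.s,
                     est.mode_probs[0], est.mode_probs[1], est.mode_probs[2],
                     lam, kap, status)
                )
        logger.info(
            "frame %d: %d detections, %d live tracks, %d births, %d closed",
            k, len(dets), sum(t.in_play for t in tracks),
            len(res.births), len(res.terminated),
        )

    tracks_df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    # drop labels that never survived confirmation
    confirmed = {t.label for t in tracks if t.status != "terminated" or t.hits >= 2}
    for t in tracks:
        confirmed.update(t.merge_partners)
    if len(tracks_df):
        tracks_df = tracks_df[tracks_df["label"].isin(confirmed)].reset_index(drop=True)
    lineage_df = pd.DataFrame(lineage, columns=LINEAGE_COLUMNS)
    return TrackingResult(tracks_df, lineage_df, cfg)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(
    tracks: pd.DataFrame,
    truth: pd.DataFrame,
    match_radius: float = 10.0,
) -> dict:
    """Tracking quality metrics against scripted ground truth.

    Returns PAP, counts of births (labels first seen after frame 0) and
    track endings, identity switches (changes in which label covers a
    truth cell), and the mean per-frame cardinality error
    |#tracks - #truth cells|.
    """
    if not len(truth):
        raise ValueError("ground truth is empty")
    frames_t = set(truth["frame"].unique())
    frames_e = set(tracks["frame"].unique()) if len(tracks) else set()
    if frames_e - frames_t:
        raise ValueError("track frames extend beyond ground truth")
    score = simulate.pap(tracks, truth, match_radius)
    first = tracks.groupby("label")["frame"].min() if len(tracks) else pd.Series(dtype=int)
    last = tracks.groupby("label")["frame"].max() if len(tracks) else pd.Series(dtype=int)
    n_birth = int((first > 0).sum())
    end_frame = int(truth["frame"].max())
    n_term = int((last < end_frame).sum())
    # identity switches: per truth cell, changes of the covering label
    mapping = simulate.map_labels(tracks, truth, match_radius)
    switches = 0
    for cell, grp in truth.groupby("cell"):
        prev_label = None
        for row in grp.sort_values("frame").itertuples(index=False):
            sub = tracks[tracks["frame"] == row.frame]
            best = None
            for trow in sub.itertuples(index=False):
                if mapping.get(int(trow.label)) != int(cell):
                    continue
                d = float(np.hypot(trow.x - row.x, trow.y - row.y))
                if d <= match_radius and (best is None or d < best[0]):
                    best = (d, int(trow.label))
            if best is not None:
                if prev_label is not None and best[1] != prev_label:
                    switches += 1
                prev_label = best[1]
    card = []
    for k in sorted(frames_t):
        n_t = int((truth["frame"] == k).sum())
        n_e = int(tracks[tracks["frame"] == k]["label"].nunique()) if len(tracks) else 0
        card.append(abs(n_e - n_t))
    return {
        "pap": score,
        "births": n_birth,
        "terminations": n_term,
        "label_switches": switches,
        "cardinality_error": float(np.mean(card)),
    }
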