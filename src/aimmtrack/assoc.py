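"""Frame-to-frame correspondence and track label management.

Nearest-neighbour association refined by cell area, with explicit handling
of the three interaction cases:

* **Case 1** (no interaction): a detection inside a track's distance gate
  whose area differs from the predicted area by less than ``delta2`` is
  associated one-to-one.
* **Case 2** (collision/merge and later split): when two tracks gate onto
  one detection whose area is about twice the mean of their predicted
  areas, the pair is merged — the spatially closer track carries both
  labels forward and the other is frozen with status ``merged-into``.
  When a carrier later gates onto two detections of about half its area,
  the original labels are re-attached by matching the detections to the
  saved *pre-merge* predicted areas (globally, minimizing the summed area
  difference over the feasible bijections).
* **Case 3** (division): a single track gating onto two detections of
  about half its predicted area divides — the closer daughter keeps the
  parent label, the other receives a fresh label, and both record the
  parent in the lineage.

Unassociated detections start tentative tracks (confirmed after two
consecutive associations); tracks coast for a bounded number of frames
before termination, and tracks whose prediction leaves the image bounds
are closed as exited.  All ties are broken by documented deterministic
rules (smaller area difference, then smaller distance, then smaller
index), so the whole frame update is deterministic given its inputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

from .detect import Detection


@dataclass(frozen=True)
class GateParams:
    """Association gates and bands.

    ``delta1``: distance gate (px); ``delta2``: area gate (px^2);
    ``merge_ratio_band``: acceptable detection-area / mean-predicted-area
    ratio for a merge (around 2); ``split_ratio_band``: acceptable
    daughter/parent area ratio for a split or division (around 0.5);
    ``max_coast``: consecutive unassociated frames before termination.
    """

    delta1: float = 25.0
    delta2: float = 8.0
    merge_ratio_band: tuple[float, float] = (1.7, 2.3)
    split_ratio_band: tuple[float, float] = (0.35, 0.65)
    max_coast: int = 2

    def __post_init__(self) -> None:
        if self.delta1 <= 0 or self.delta2 <= 0 or self.max_coast < 1:
            raise ValueError("gates must be positive and max_coast >= 1")
        for band in (self.merge_ratio_band, self.split_ratio_band):
            if not band[0] < band[1]:
                raise ValueError("ratio bands must be proper intervals")


@dataclass
class Track:
    """Bookkeeping for one labelled cell track.

    The motion filter itself is attached by the pipeline through ``bank``;
    the association layer only needs the predicted position/area for the
    current frame and a little history (previous associated area,
    velocity, coast count).
    """

    label: int
    pred_x: float = 0.0
    pred_y: float = 0.0
    pred_area: float = 1.0
    vx: float = 0.0
    vy: float = 0.0
    status: str = "tentative"  # tentative|active|merged-into:<l>|exited|terminated
    parent: int | None = None
    merge_partners: list[int] = field(default_factory=list)
    pre_merge: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    coast: int = 0
    hits: int = 0
    birth_frame: int = 0
    last_area: float = 1.0
    bank: Any = None

    @property
    def in_play(self) -> bool:
        return self.status in ("active", "tentative")

    @property
    def is_carrier(self) -> bool:
        return self.in_play and len(self.merge_partners) > 0


@dataclass
class FrameResult:
    """Outcome of one association frame, consumed by the pipeline."""

    assignments: dict[int, int] = field(default_factory=dict)  # label -> det idx
    births: list[int] = field(default_factory=list)
    terminated: list[int] = field(default_factory=list)
    lineage: list[tuple[int, int, int]] = field(default_factory=list)
    merges: list[tuple[int, int, int]] = field(default_factory=list)
    splits: list[tuple[int, int]] = field(default_factory=list)
    # labels whose filter must be (re)built from their detection this frame
    reinit: dict[int, tuple[int, float, float]] = field(default_factory=dict)


def distance_measure(pred_xy: Sequence[float], det: Detection) -> float:
    """Euclidean distance between a predicted position and a detection."""
    return math.hypot(pred_xy[0] - det.x, pred_xy[1] - det.y)


def area_measure(pred_area: float, det_area: float) -> float:
    """Absolute difference between predicted and detected area."""
    return abs(float(pred_area) - float(det_area))


def gate(
    tracks: Sequence[Track], detections: Sequence[Detection], delta1: float
) -> dict[int, list[int]]:
    """Per-track candidate detections within the distance gate (strict <)."""
    out: dict[int, list[int]] = {}
    for t in tracks:
        out[t.label] = [
            j
            for j, d in enumerate(detections)
            if distance_measure((t.pred_x, t.pred_y), d) < delta1
        ]
    return out


def resolve_case1(
    track: Track,
    candidates: Sequence[int],
    detections: Sequence[Detection],
    delta2: float,
) -> int | None:
    """One-to-one association: the gated candidate with the smallest area
    difference below delta2 (ties: smaller distance, then smaller index)."""
    best = None
    for j in candidates:
        da = area_measure(track.pred_area, detections[j].area)
        if da >= delta2:
            continue
        key = (da, distance_measure((track.pred_x, track.pred_y), detections[j]), j)
        if best is None or key < best[0]:
            best = (key, j)
    return None if best is None else best[1]


def detect_merge(
    pair: tuple[Track, Track], detection: Detection, params: GateParams
) -> bool:
    """Case-2 merge test: detection area over the mean of the pair's
    predicted areas lies in the merge band (about 2 for a blob holding
    both cells)."""
    mean_area = (pair[0].pred_area + pair[1].pred_area) / 2.0
    if mean_area <= 0:
        return False
    ratio = detection.area / mean_area
    lo, hi = params.merge_ratio_band
    return lo <= ratio <= hi


def resolve_split(
    merged: Track,
    det_pair: tuple[int, int],
    detections: Sequence[Detection],
    params: GateParams,
) -> dict[int, int]:
    """Re-attach a carrier's labels to two split detections.

    Each label's saved pre-merge predicted area is matched against the
    detection areas; the feasible (area difference < delta2) bijection
    with minimal summed area difference wins, distance breaking exact
    ties.  A label whose best detection fails the gate is left out (it
    will coast).
    """
    labels = [merged.label] + list(merged.merge_partners)
    if len(labels) != 2:
        # >2-way merges are resolved pairwise only; match the first two
        labels = labels[:2]
    areas = {
        lab: merged.pre_merge.get(lab, (merged.pred_area, 0.0, 0.0))[0]
        for lab in labels
    }
    best: tuple[tuple[float, float], dict[int, int]] | None = None
    for perm in itertools.permutations(det_pair):
        cost = 0.0
        dist = 0.0
        mapping: dict[int, int] = {}
        for lab, j in zip(labels, perm):
            da = area_measure(areas[lab], detections[j].area)
            if da < params.delta2:
                mapping[lab] = j
                cost += da
            else:
                cost += params.delta2 * 10.0  # infeasible pairing penalty
            dist += distance_measure((merged.pred_x, merged.pred_y), detections[j])
        key = (cost, dist)
        if best is None or key < best[0]:
            best = (key, mapping)
    return best[1] if best else {}


def resolve_division(
    track: Track,
    det_pair: tuple[int, int],
    detections: Sequence[Detection],
) -> tuple[int, int]:
    """Case-3 division: returns (kept_det, new_det) — the spatially closer
    daughter keeps the parent label."""
    d0 = distance_measure((track.pred_x, track.pred_y), detections[det_pair[0]])
    d1 = distance_measure((track.pred_x, track.pred_y), detections[det_pair[1]])
    if (d1, det_pair[1]) < (d0, det_pair[0]):
        return det_pair[1], det_pair[0]
    return det_pair[0], det_pair[1]


def _split_candidates(
    track: Track,
    candidates: Sequence[int],
    detections: Sequence[Detection],
    band: tuple[float, float],
) -> list[int]:
    """Gated detections whose area ratio to the track's predicted area lies
    in the half-area band, nearest first."""
    lo, hi = band
    if track.pred_area <= 0:
        return []
    out = [
        j for j in candidates if lo <= detections[j].area / track.pred_area <= hi
    ]
    out.sort(
        key=lambda j: (
            distance_measure((track.pred_x, track.pred_y), detections[j]),
            j,
        )
    )
    return out


def manage_frame(
    tracks: list[Track],
    detections: Sequence[Detection],
    params: GateParams,
    frame: int = 0,
    bounds: tuple[float, float] | None = None,
    next_label: int | None = None,
) -> tuple[list[Track], FrameResult]:
    """Run one frame of correspondence and label management.

    Case precedence: split of merged carriers, then division, then merge,
    then one-to-one association; leftover detections become tentative
    births and persistently unassociated or out-of-bounds tracks are
    closed.  Mutates the track objects' bookkeeping and returns them with
    a :class:`FrameResult` describing what the pipeline must do to the
    attached filters.
    """
    res = FrameResult()
    live = [t for t in tracks if t.in_play]
    by_label = {t.label: t for t in tracks}
    cands = gate(live, detections, params.delta1)
    unclaimed = set(range(len(detections)))
    unassigned = {t.label for t in live}
    if next_label is None:
        next_label = max((t.label for t in tracks), default=0) + 1

    def claim(track: Track, j: int) -> None:
        res.assignments[track.label] = j
        unclaimed.discard(j)
        unassigned.discard(track.label)
        track.last_area = float(detections[j].area)

    # --- Case 2b: splits of merged carriers -------------------------------
    for t in sorted((t for t in live if t.is_carrier), key=lambda t: t.label):
        open_c = [j for j in cands[t.label] if j in unclaimed]
        halves = _split_candidates(t, open_c, detections, params.split_ratio_band)
        if len(halves) < 2:
            continue
        mapping = resolve_split(t, (halves[0], halves[1]), detections, params)
        if not mapping:
            continue
        partners = list(t.merge_partners)
        for lab, j in sorted(mapping.items()):
            tr = by_label[lab]
            if lab == t.label:
                t.merge_partners = []
                claim(t, j)
                pm = t.pre_merge.get(lab)
                if pm is not None:
                    res.reinit[lab] = (j, pm[1], pm[2])
            else:
                pm = t.pre_merge.get(lab, (tr.pred_area, tr.vx, tr.vy))
                tr.status = "active"
                tr.coast = 0
                claim(tr, j)
                res.reinit[lab] = (j, pm[1], pm[2])
            res.splits.append((lab, j))
        # a partner whose detection failed the gate coasts from its
        # pre-merge state
        for lab in partners:
            if lab not in mapping:
                tr = by_label[lab]
                tr.status = "active"
                t.merge_partners = [p for p in t.merge_partners if p != lab]
        t.pre_merge = {}

    # --- Case 3: divisions -----------------------------------------------
    for t in sorted(
        (t for t in live if t.label in unassigned and not t.is_carrier
         and t.status == "active"),
        key=lambda t: t.label,
    ):
        open_c = [j for j in cands[t.label] if j in unclaimed]
        halves = _split_candidates(t, open_c, detections, params.split_ratio_band)
        if len(halves) < 2:
            continue
        keep, new = resolve_division(t, (halves[0], halves[1]), detections)
        claim(t, keep)
        daughter = Track(
            label=next_label,
            pred_x=detections[new].x,
            pred_y=detections[new].y,
            pred_area=float(detections[new].area),
            vx=t.vx,
            vy=t.vy,
            status="active",
            parent=t.label,
            hits=1,
            birth_frame=frame,
            last_area=float(detections[new].area),
        )
        next_label += 1
        tracks.append(daughter)
        by_label[daughter.label] = daughter
        res.assignments[daughter.label] = new
        unclaimed.discard(new)
        res.reinit[daughter.label] = (new, t.vx, t.vy)
        res.lineage.append((t.label, t.label, frame))
        res.lineage.append((daughter.label, t.label, frame))

    # --- Case 2a: merges ---------------------------------------------------
    det_to_tracks: dict[int, list[Track]] = {}
    for t in live:
        if t.label in unassigned and not t.is_carrier:
            for j in cands[t.label]:
                if j in unclaimed:
                    det_to_tracks.setdefault(j, []).append(t)
    for j in sorted(det_to_tracks):
        group = [t for t in det_to_tracks[j] if t.label in unassigned]
        if len(group) < 2:
            continue
        group.sort(
            key=lambda t: (
                distance_measure((t.pred_x, t.pred_y), detections[j]),
                t.label,
            )
        )
        pair = (group[0], group[1])
        if not detect_merge(pair, detections[j], params):
            continue
        carrier, other = pair
        carrier.merge_partners = [other.label]
        carrier.pre_merge = {
            carrier.label: (carrier.pred_area, carrier.vx, carrier.vy),
            other.label: (other.pred_area, other.vx, other.vy),
        }
        other.status = f"merged-into:{carrier.label}"
        unassigned.discard(other.label)
        claim(carrier, j)
        res.merges.append((carrier.label, other.label, j))

    # --- Case 1: one-to-one -----------------------------------------------
    pairs = []
    for t in live:
        if t.label not in unassigned:
            continue
        for j in cands[t.label]:
            if j not in unclaimed:
                continue
            da = area_measure(t.pred_area, detections[j].area)
            if da < params.delta2:
                d = distance_measure((t.pred_x, t.pred_y), detections[j])
                pairs.append((da, d, j, t.label))
    for da, d, j, lab in sorted(pairs):
        if lab in unassigned and j in unclaimed:
            claim(by_label[lab], j)

    # --- births ------------------------------------------------------------
    for j in sorted(unclaimed):
        t = Track(
            label=next_label,
            pred_x=detections[j].x,
            pred_y=detections[j].y,
            pred_area=float(detections[j].area),
            status="tentative",
            hits=1,
            birth_frame=frame,
            last_area=float(detections[j].area),
        )
        next_label += 1
        tracks.append(t)
        res.assignments[t.label] = j
        res.reinit[t.label] = (j, 0.0, 0.0)
        res.births.append(t.label)

    # --- coasting, confirmation, termination -------------------------------
    for t in live:
        if t.label in res.assignments:
            t.coast = 0
            t.hits += 1
            if t.status == "tentative" and t.hits >= 2:
                t.status = "active"
            continue
        if t.label not in unassigned:
            continue  # frozen into a merge this frame
        if t.status == "tentative":
            t.status = "terminated"
            res.terminated.append(t.label)
            continue
        out_of_bounds = bounds is not None and not (
            0.0 <= t.pred_x < bounds[0] and 0.0 <= t.pred_y < bounds[1]
        )
        t.coast += 1
        if out_of_bounds:
            t.status = "exited"
            res.terminated.append(t.label)
        elif t.coast >= params.max_coast:
            t.status = "terminated"
            res.terminated.append(t.label)
    return tracks, res
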