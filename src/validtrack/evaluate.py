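"""Scoring of tracking results against a reference (ground truth).

Three layers of evaluation, each usable on its own:

* **detection** — per-frame matching of detected against reference cell
  masks by dual overlap (both directional ratios must exceed a 30% floor,
  one-and-only-one partner each way), summarized as false acceptance rate
  FAR = FP/(TP+FP) and false rejection rate FRR = FN/(TP+FN);
* **paths** — path classification counts: detected vs correct
  mitoses, complete paths vs correct complete paths, and the
  "trustworthiness" quotients 100·correct/total;
* **genealogy** — the degree of relation between two cells (number of
  mitoses connecting them through the lineage tree, 0 = unrelated) and the
  per-frame FAR/FRR of genealogical assignments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .simulate import GroundTruth
from .tracking import PathFragment, pairwise_overlaps

__all__ = [
    "MatchCounts",
    "match_detections",
    "detection_error_rates",
    "trustworthiness",
    "complete_path_probability",
    "frame_correspondences",
    "classification_counts",
    "build_cell_forest",
    "degree_of_relation",
    "path_truth_ids",
    "genealogy_rates_at_frame",
    "genealogy_error_rates",
]


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int


def match_detections(
    detected: np.ndarray, reference: np.ndarray, overlap_floor: float = 0.3
) -> tuple[MatchCounts, dict[int, int]]:
    """Dual-overlap one-to-one matching of two label masks.

    A detected cell is a true positive iff both overlap ratios with exactly
    one reference cell exceed the floor and that reference cell matches only
    it.  Unmatched detected cells are false positives, unmatched reference
    cells false negatives — so a cell detected with insufficient accuracy
    (one overlap below the floor) is counted as both a FP and a FN.

    Returns the counts and the ``{detected label: reference label}`` map.
    """
    table = pairwise_overlaps(detected, reference)
    n_det = len(np.unique(detected)) - (1 if (np.asarray(detected) == 0).any() else 0)
    n_ref = len(np.unique(reference)) - (1 if (np.asarray(reference) == 0).any() else 0)
    if table.empty:
        return MatchCounts(tp=0, fp=n_det, fn=n_ref), {}
    cand = table[(table.o_fw > overlap_floor) & (table.o_bw > overlap_floor)]
    matches: dict[int, int] = {}
    if not cand.empty:
        na = cand.label_a.value_counts()
        nb = cand.label_b.value_counts()
        uniq = cand[(cand.label_a.map(na) == 1) & (cand.label_b.map(nb) == 1)]
        matches = dict(zip(uniq.label_a.astype(int), uniq.label_b.astype(int)))
    tp = len(matches)
    return MatchCounts(tp=tp, fp=n_det - tp, fn=n_ref - tp), matches


def detection_error_rates(counts: MatchCounts) -> tuple[float | None, float | None]:
    """FAR = FP/(TP+FP); FRR = FN/(TP+FN); ``None`` on empty denominators."""
    far = counts.fp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    frr = counts.fn / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    return far, frr


def trustworthiness(correct: int, total: int) -> float | None:
    """Percentage of returned items that are correct; ``None`` if none returned."""
    if correct < 0 or total < correct:
        raise ValueError("need 0 <= correct <= total")
    if total == 0:
        return None
    return 100.0 * correct / total


def complete_path_probability(per_frame_success: float, n_frames: int) -> float:
    """Probability that a path of given length survives i.i.d. per-frame errors.

    The error-propagation argument for why validation is mandatory: even a
    95% per-frame detection rate compounds to ``0.95**50 ≈ 7.7%`` over a
    50-frame cell life.
    """
    if not 0 <= per_frame_success <= 1:
        raise ValueError("per-frame success must lie in [0, 1]")
    return per_frame_success**n_frames


# ---------------------------------------------------------------------------
# path-level classification counts


def frame_correspondences(
    masks: list[np.ndarray], truth: GroundTruth, overlap_floor: float = 0.3
) -> list[dict[int, int]]:
    """Per-frame ``{detected label: true cell id}`` maps by dual matching."""
    return [
        match_detections(mask, tmask, overlap_floor)[1]
        for mask, tmask in zip(masks, truth.masks)
    ]


def _division_frames(truth: GroundTruth) -> dict[int, int]:
    return {parent: frame for parent, _, frame in truth.lineage}


def classification_counts(
    paths: dict[int, PathFragment],
    mitoses: list[tuple[int, int]],
    complete: dict[int, tuple[int, int]],
    frame_maps: list[dict[int, int]],
    truth: GroundTruth,
    frame_tolerance: int = 1,
) -> dict:
    """Classification counts and trustworthiness quotients for one tracker.

    Parameters
    ----------
    paths : all paths returned by the tracker.
    mitoses : detected divisions as ``(division frame, parent path id)``.
    complete : ``{path id: (start_frame, end_frame)}`` of the paths the
        tracker declares complete (mitosis-to-mitosis).
    frame_maps : per-frame detected-label -> true-id correspondences.
    truth : simulator ground truth.

    A detected mitosis is *correct* iff the parent path's terminal cell maps
    to a true cell whose division lies within ``frame_tolerance`` frames.  A
    complete path is *correct* iff every one of its cells maps to one and
    the same true cell and both endpoint mitoses are correct.
    """
    div_frame = _division_frames(truth)

    def true_id_of(path: PathFragment, t: int) -> int | None:
        lab = path.labels[t - path.start_frame]
        return frame_maps[t].get(lab)

    correct_mitoses = 0
    for frame, parent_id in mitoses:
        path = paths.get(parent_id)
        if path is None or not path.start_frame <= frame <= path.end_frame:
            continue
        tid = true_id_of(path, min(frame, path.end_frame))
        if tid is not None and tid in div_frame and abs(div_frame[tid] - frame) <= frame_tolerance:
            correct_mitoses += 1

    correct_complete = 0
    for pid, (start, end) in complete.items():
        path = paths[pid]
        ids = {true_id_of(path, t) for t in range(path.start_frame, path.end_frame + 1)}
        if len(ids) != 1 or None in ids:
            continue
        tid = ids.pop()
        cell = truth.cells.get(tid)
        if cell is None or cell.parent is None:
            continue
        birth_ok = abs(div_frame[cell.parent] - (start - 1)) <= frame_tolerance
        terminal_ok = tid in div_frame and abs(div_frame[tid] - end) <= frame_tolerance
        if birth_ok and terminal_ok:
            correct_complete += 1

    return {
        "paths": len(paths),
        "detected mitoses": len(mitoses),
        "correctly detected mitoses": correct_mitoses,
        "mitosis detection trustworthiness": trustworthiness(correct_mitoses, len(mitoses)),
        "complete paths (mitosis-mitosis)": len(complete),
        "correctly detected complete paths": correct_complete,
        "tracking trustworthiness": trustworthiness(correct_complete, len(complete)),
    }


# ---------------------------------------------------------------------------
# genealogy


def build_cell_forest(lineage: list[tuple[int, int, int]]) -> nx.DiGraph:
    """Directed forest over cell ids from (parent, daughter, frame) edges."""
    g = nx.DiGraph()
    for parent, daughter, frame in lineage:
        g.add_edge(parent, daughter, frame=frame)
    return g


def degree_of_relation(forest: nx.DiGraph, a, b) -> int:
    """Number of mitoses connecting two cells through their lineage tree.

    Siblings share one division (degree 1), as do parent and child; first
    cousins are connected through three divisions.  Cells in disjoint trees
    are unrelated: degree 0.  ``a == b`` is a contract error (0 is reserved
    for "unrelated").
    """
    if a == b:
        raise ValueError("degree of relation is undefined for a cell with itself")
    und = forest.to_undirected(as_view=True)
    if a not in und or b not in und:
        return 0
    try:
        nodes = nx.shortest_path(und, a, b)
    except nx.NetworkXNoPath:
        return 0
    events = set()
    for u, v in zip(nodes, nodes[1:]):
        events.add(u if forest.has_edge(u, v) else v)  # the dividing parent
    return len(events)


def path_truth_ids(accepted, frame_maps: list[dict[int, int]]) -> dict[int, int | None]:
    """True cell id each accepted path follows (None if inconsistent)."""
    out = {}
    for p in accepted:
        ids = {
            frame_maps[t].get(lab)
            for t, lab in zip(range(p.start_frame, p.end_frame + 1), p.labels)
        }
        out[p.id] = ids.pop() if len(ids) == 1 else None
    return out


def genealogy_rates_at_frame(
    fragments: dict[int, PathFragment],
    mitoses,
    truth: GroundTruth,
    frame_maps: list[dict[int, int]],
    frame: int,
) -> tuple[float | None, float | None]:
    """Genealogy FAR/FRR of a validated result at one frame.

    The predicted forest connects path fragments (complete paths and
    boundary stubs alike) through the validated mitoses — cells alive in the
    frame of interest can only be related through divisions the validator
    trusted.  ``mitoses`` is an iterable of ``(parent fragment id, (daughter
    fragment ids))``.  Reference cells present in the frame are paired and
    compared through the dual-overlap correspondence.
    """
    ref_forest = build_cell_forest(truth.lineage)
    ref_cells = [int(c) for c in np.unique(truth.masks[frame]) if c > 0]
    pred_forest = nx.DiGraph()
    for parent, daughters in mitoses:
        for d in daughters:
            pred_forest.add_edge(parent, d)
    correspondence: dict[int, int] = {}
    for fid, frag in fragments.items():
        if frag.start_frame <= frame <= frag.end_frame:
            tid = frame_maps[frame].get(frag.labels[frame - frag.start_frame])
            if tid is not None:
                correspondence[tid] = fid
    return genealogy_error_rates(pred_forest, ref_forest, ref_cells, correspondence)


def genealogy_error_rates(
    predicted: nx.DiGraph,
    reference: nx.DiGraph,
    ref_cells: list,
    correspondence: dict,
) -> tuple[float | None, float | None]:
    """Per-frame genealogy FAR/FRR over all related reference cell pairs.

    ``ref_cells`` are the reference cells present in the frame of interest;
    ``correspondence`` maps reference cells to predicted forest nodes (or
    None for cells the tracker did not resolve).  Relations never found get
    degree 0 and count as false rejections; relations assigned a wrong
    nonzero degree count as false acceptances.  Both are fractions of the
    total number of reference relations; ``None`` if there are none.
    """
    total = fr = fa = 0
    for a, b in itertools.combinations(sorted(ref_cells), 2):
        ref_deg = degree_of_relation(reference, a, b)
        if ref_deg == 0:
            continue
        total += 1
        pa, pb = correspondence.get(a), correspondence.get(b)
        pred_deg = (
            0 if pa is None or pb is None or pa == pb else degree_of_relation(predicted, pa, pb)
        )
        if pred_deg == 0:
            fr += 1
        elif pred_deg != ref_deg:
            fa += 1
    if total == 0:
        return None, None
    return fa / total, fr / total
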