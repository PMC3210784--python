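"""Path validation: error classification and conservative path acceptance.

The central idea: instead of trying to make detection or linking perfect,
systematically search the track structure for every way it can be wrong —
cells at the image border, cells the detector lost, optically merged cells,
fast debris — classify each path terminus, attempt the safe corrections
(local re-detection of vanished cells), and finally accept only *complete
paths*: whole cell lives running from one detected mitosis to the next, with
no unexplained terminus anywhere.  Anything doubtful is rejected wholesale.
Accepted paths are connected through their shared mitoses into a lineage
forest.

Terminus classes are assigned in a fixed priority order, from the most
conclusive explanation to the least:

    border -> merged -> mitosis -> vanished (recovery attempted) -> debris
    -> unresolved
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from skimage.measure import label as cc_label

from .detect import CONNECTIVITY, compute_global_threshold, detect_cells
from .features import CellRecord, SimilarityModel, difference_vector, extract_features, similarity_probability
from .tracking import Adjacency, AdjacencyEdge, PathFragment, pairwise_overlaps

__all__ = [
    "MitosisEvent",
    "MergeEvent",
    "CompletePath",
    "LineageForest",
    "attach_features",
    "assign_path_flags",
    "detect_merges",
    "detect_mitoses",
    "split_at_interior_branches",
    "recover_undetected",
    "classify_tracking_error",
    "validate_and_assemble",
]


@dataclass(frozen=True)
class MitosisEvent:
    """A validated division: parent fragment ends into exactly two daughters."""

    parent: int
    daughters: tuple[int, int]
    frame: int  # last frame of the parent
    probability: float


@dataclass(frozen=True)
class MergeEvent:
    """Reversed-Y junction: >=2 fragments end into one common successor."""

    predecessors: tuple[int, ...]
    successor: int
    frame: int  # first frame of the merged region


@dataclass
class CompletePath:
    """A whole cell life from its birth mitosis to its own division."""

    id: int
    fragment_id: int
    start_frame: int
    end_frame: int
    labels: list[int]
    birth_mitosis: MitosisEvent
    terminal_mitosis: MitosisEvent
    start_x: float = 0.0  # centroid at birth; used for the sibling ordering
    start_y: float = 0.0

    def lifetime_minutes(self, frame_interval_min: float) -> float:
        return (self.end_frame - self.start_frame) * frame_interval_min

    def cells(self):
        return [(self.start_frame + i, lab) for i, lab in enumerate(self.labels)]


@dataclass
class LineageForest:
    """Accepted complete paths (nodes) connected by mitoses (edges)."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_path(self, path: CompletePath) -> None:
        self.graph.add_node(path.id, path=path)

    def add_mitosis_edge(self, parent_path: int, daughter_path: int, event: MitosisEvent) -> None:
        self.graph.add_edge(parent_path, daughter_path, event=event)

    def trees(self) -> list[set]:
        return [set(c) for c in nx.weakly_connected_components(self.graph)]


# ---------------------------------------------------------------------------
# features along fragments


def attach_features(
    fragments: dict[int, PathFragment], masks: list[np.ndarray], images: list[np.ndarray]
) -> None:
    """Fill per-frame :class:`CellRecord` and per-step difference vectors."""
    per_frame: list[dict[int, CellRecord]] = []
    for t, (mask, img) in enumerate(zip(masks, images)):
        per_frame.append({r.label: r for r in extract_features(mask, img, frame_index=t)})
    for frag in fragments.values():
        frag.records = [per_frame[t][lab] for t, lab in frag.cells()]
        frag.diffs = [
            difference_vector(a, b) for a, b in zip(frag.records, frag.records[1:])
        ]


# ---------------------------------------------------------------------------
# terminus flags for path classification


def assign_path_flags(
    fragments: dict[int, PathFragment],
    adjacency: Adjacency,
    width: int,
    height: int,
    border_margin: float = 30.0,
    n_frames: int | None = None,
    min_area: float = 20.0,
) -> None:
    """Set begin/end, border-begin/-end, lost-begin/-end and cell-death flags.

    A terminus is *border* when it has no continuation candidate and its
    centroid lies within ``border_margin`` pixels of an image edge; *lost*
    when it has no candidate and is far from the border; termini with
    pending adjacency candidates are left to the junction detectors.
    """
    if n_frames is None:
        n_frames = max(f.end_frame for f in fragments.values()) + 1

    def near_border(rec: CellRecord) -> bool:
        return (
            rec.x < border_margin
            or rec.y < border_margin
            or rec.x >= width - border_margin
            or rec.y >= height - border_margin
        )

    for frag in fragments.values():
        frag.flags.discard("lost-begin")
        frag.flags.discard("lost-end")
        if frag.start_frame == 0:
            frag.flags.add("begin")
        elif not adjacency.predecessors(fragments, frag.id) and "mitosis-born" not in frag.flags:
            frag.flags.add("border-begin" if near_border(frag.records[0]) else "lost-begin")
        if frag.end_frame == n_frames - 1:
            frag.flags.add("end")
        elif not adjacency.successors(fragments, frag.id) and "mitosis" not in frag.flags:
            if near_border(frag.records[-1]):
                frag.flags.add("border-end")
            else:
                frag.flags.add("lost-end")
                areas = [r.area for r in frag.records[-3:]]
                if len(areas) == 3 and areas[0] > areas[1] > areas[2] and areas[2] < 2 * min_area:
                    frag.flags.add("cell-death")  # heuristic: sustained terminal shrinkage


# ---------------------------------------------------------------------------
# junction detectors


def detect_merges(fragments: dict[int, PathFragment], adjacency: Adjacency) -> list[MergeEvent]:
    """Find reversed-Y junctions and set the ``merged`` flag.

    A fragment is a merge successor when >=2 fragments end right before its
    start, all of them candidate-linked to it and to nothing else.  The
    merged region loses single-cell identity, so the successor carries the
    lost-begin/lost-end semantics of the ``merged`` flag.
    """
    events = []
    for frag in fragments.values():
        preds = adjacency.predecessors(fragments, frag.id)
        if len(preds) < 2:
            continue
        if all(adjacency.successors(fragments, p) == [frag.id] for p in preds):
            events.append(
                MergeEvent(
                    predecessors=tuple(sorted(preds)), successor=frag.id, frame=frag.start_frame
                )
            )
            frag.flags.add("merged")
            for p in preds:
                fragments[p].flags.add("merged-end")
    return events


def mitosis_window(frag: PathFragment, k: int = 2) -> np.ndarray | None:
    """Mean difference vector over the last ``k`` steps of a fragment."""
    if not frag.diffs:
        return None
    return np.mean(frag.diffs[-k:], axis=0)


def _split_fragment(
    fragments: dict[int, PathFragment], adjacency: Adjacency, f: PathFragment, t: int
) -> None:
    """Split fragment ``f`` after frame ``t``; adjacency edges are remapped
    and the head-tail continuation is recorded as a candidate edge."""
    idx = t - f.start_frame
    tail_id = max(fragments) + 1
    tail = PathFragment(
        id=tail_id,
        start_frame=t + 1,
        labels=f.labels[idx + 1 :],
        records=f.records[idx + 1 :],
        diffs=f.diffs[idx + 1 :],
    )
    fragments[tail_id] = tail
    f.labels = f.labels[: idx + 1]
    f.records = f.records[: idx + 1]
    f.diffs = f.diffs[:idx]
    for i, ed in enumerate(adjacency.edges):
        new_a, new_b = ed.frag_a, ed.frag_b
        if ed.frag_a == f.id and ed.boundary_frame > t:
            new_a = tail_id
        if ed.frag_b == f.id and ed.boundary_frame >= t:
            new_b = tail_id
        if (new_a, new_b) != (ed.frag_a, ed.frag_b):
            adjacency.edges[i] = AdjacencyEdge(new_a, new_b, ed.boundary_frame, ed.intersection)
    adjacency.add(f.id, tail_id, t, 1)


def split_at_interior_branches(
    fragments: dict[int, PathFragment], adjacency: Adjacency
) -> int:
    """Adjacency refinement: split fragments where a branch meets their interior.

    A candidate edge between a fragment terminus and the *interior* of
    another, continuing fragment is the structural trace of two error
    scenarios the unique-link construction cannot see:

    * a **missed division** — one daughter was linked uniquely to the
      dividing cell while the other appeared as a new fragment touching the
      chain's interior;
    * an **undetected merge** — one partner linked uniquely into the merged
      region while the other's chain ended against the region's interior.

    Splitting the continuing chain at the branch point turns both into
    explicit junctions (Y, reversed Y) which the mitosis and merge detectors
    then judge; junctions neither detector trusts stay unresolved and every
    involved path is rejected.  Returns the number of splits performed.
    """
    n_splits = 0
    changed = True
    while changed:
        changed = False
        for e in list(adjacency.edges):
            f_a = fragments.get(e.frag_a)
            f_b = fragments.get(e.frag_b)
            if f_a is None or f_b is None or f_a is f_b:
                continue
            t = e.boundary_frame
            # outgoing branch: a fresh fragment starts against f_a's interior
            if (
                f_b.start_frame == t + 1
                and f_a.start_frame <= t < f_a.end_frame
                and t - f_a.start_frame >= 1
            ):
                _split_fragment(fragments, adjacency, f_a, t)
            # incoming branch: a chain ends against f_b's interior
            elif (
                f_a.end_frame == t
                and f_b.start_frame < t + 1 <= f_b.end_frame
                and t + 1 - f_b.start_frame >= 1
            ):
                _split_fragment(fragments, adjacency, f_b, t)
            else:
                continue
            n_splits += 1
            changed = True
            break
    return n_splits


def detect_mitoses(
    fragments: dict[int, PathFragment],
    adjacency: Adjacency,
    model: SimilarityModel,
    t_mit: float,
    k: int = 2,
) -> list[MitosisEvent]:
    """Find validated divisions: Y-shape AND the pre-mitotic feature pattern.

    Both criteria are required: the fragment must end into exactly two
    candidate successors starting the next frame, and the terminal
    difference-vector window (area drop, rounding, brightening) must score
    ``Prob(d) > t_mit`` under the mitosis similarity model.  Daughters
    claimed by more than one surviving event indicate an unresolvable
    conflict; all involved events are dropped (if in doubt, reject).
    """
    events: list[MitosisEvent] = []
    for frag in fragments.values():
        if "merged" in frag.flags or "merged-end" in frag.flags or "border-end" in frag.flags:
            continue
        succs = adjacency.successors(fragments, frag.id)
        if len(succs) != 2:
            continue
        d = mitosis_window(frag, k)
        if d is None:
            continue
        p = similarity_probability(d, model)
        if p > t_mit:
            events.append(
                MitosisEvent(
                    parent=frag.id,
                    daughters=tuple(sorted(succs)),
                    frame=frag.end_frame,
                    probability=p,
                )
            )
    claimed: dict[int, int] = {}
    conflicted: set[int] = set()
    for i, ev in enumerate(events):
        for d in ev.daughters:
            if d in claimed:
                conflicted.add(i)
                conflicted.add(claimed[d])
            else:
                claimed[d] = i
    events = [ev for i, ev in enumerate(events) if i not in conflicted]
    for ev in events:
        fragments[ev.parent].flags.add("mitosis")
        fragments[ev.parent].flags.discard("lost-end")
        for d in ev.daughters:
            fragments[d].flags.add("mitosis-born")
            fragments[d].flags.discard("lost-begin")
            fragments[d].flags.discard("border-begin")
    return events


# ---------------------------------------------------------------------------
# recovery of vanished cells


def _local_detect(
    image8: np.ndarray,
    exclude: np.ndarray,
    center: tuple[float, float],
    half: int,
    erosion_radius: int,
    dilation_radius: int,
    min_area: int,
) -> tuple[np.ndarray, tuple[slice, slice]] | None:
    """Re-run detection with a *local* Otsu threshold inside a window.

    Pixels of already-detected cells (``exclude``) are removed both from the
    threshold histogram — so bright neighbours cannot pull the local
    threshold above a faint cell — and from the resulting binary.
    """
    h, w = image8.shape
    cx, cy = center
    x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, w)
    y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, h)
    if x0 >= x1 or y0 >= y1:
        return None
    win = (slice(y0, y1), slice(x0, x1))
    sub = image8[win]
    free = ~exclude[win]
    if free.sum() < 4:
        return None
    try:
        theta = compute_global_threshold(sub[free])
    except ValueError:
        return None
    masked = np.where(free, sub, 0)
    labels = detect_cells(masked, theta, erosion_radius, dilation_radius, min_area)
    if labels.max() == 0:
        return None
    return labels, win


def recover_undetected(
    frag: PathFragment,
    fragments: dict[int, PathFragment],
    adjacency: Adjacency,
    masks: list[np.ndarray],
    images8: list[np.ndarray],
    t_fw: float = 0.3,
    t_bw: float = 0.3,
    max_gap: int = 5,
    search_half: int = 30,
    erosion_radius: int = 1,
    dilation_radius: int = 1,
    min_area: int = 20,
) -> bool:
    """Try to bridge a lost-end fragment across undetected frames.

    A window around the terminal centroid is re-thresholded with a local
    Otsu in each following frame.  If a region satisfying the dual overlap
    criteria emerges, the fragment is extended; when the extension reaches a
    fragment that re-appeared (lost-begin), the two are joined and all flags
    recomputed.  Without a full bridge the fragment is left unchanged.
    """
    if "lost-end" not in frag.flags:
        return False
    T = len(masks)
    cur = masks[frag.end_frame] == frag.labels[-1]
    cur_area = int(cur.sum())
    center = (frag.records[-1].x, frag.records[-1].y)
    pending: list[tuple[int, np.ndarray]] = []  # (frame, boolean region)
    join_frag: int | None = None
    starters: dict[int, dict[int, int]] = {}  # frame -> {start label: fragment id}
    for g in fragments.values():
        if g.id != frag.id:
            starters.setdefault(g.start_frame, {})[g.labels[0]] = g.id
    for u in range(frag.end_frame + 1, min(frag.end_frame + 1 + max_gap, T)):
        # 1) did the cell re-appear as a freshly started detected fragment?
        inter = np.bincount(masks[u][cur].ravel())
        for lab in np.nonzero(inter)[0]:
            if lab == 0 or lab not in starters.get(u, {}):
                continue
            region_area = int((masks[u] == lab).sum())
            if inter[lab] / cur_area > t_fw and inter[lab] / region_area > t_bw:
                join_frag = starters[u][lab]
                break
        if join_frag is not None:
            break
        # 2) otherwise bridge with a locally thresholded detection
        local = _local_detect(
            images8[u], masks[u] > 0, center, search_half, erosion_radius, dilation_radius, min_area
        )
        if local is None:
            break
        labels, win = local
        best, best_inter = None, 0
        cur_win = cur[win]
        for lab in range(1, int(labels.max()) + 1):
            region = labels == lab
            ri = int((region & cur_win).sum())
            if ri == 0:
                continue
            if ri / cur_area > t_fw and ri / int(region.sum()) > t_bw and ri > best_inter:
                best, best_inter = region, ri
        if best is None:
            break
        full = np.zeros_like(cur)
        full[win] = best
        full &= masks[u] == 0  # never overwrite detected cells
        if int(full.sum()) < min_area:
            break
        pending.append((u, full))
        cur = full
        cur_area = int(full.sum())
        ys, xs = np.nonzero(full)
        center = (float(xs.mean()), float(ys.mean()))
    if join_frag is None:
        return False
    # commit: insert locally detected regions as new labels
    for u, region in pending:
        new_label = int(masks[u].max()) + 1
        masks[u][region] = new_label
        rec = extract_features((masks[u] == new_label).astype(np.uint16) * new_label, images8[u], u)
        frag.labels.append(new_label)
        frag.records.append(rec[0])
    g = fragments.pop(join_frag)
    frag.labels.extend(g.labels)
    frag.records.extend(g.records)
    frag.diffs = [difference_vector(a, b) for a, b in zip(frag.records, frag.records[1:])]
    frag.flags.discard("lost-end")
    frag.flags.discard("cell-death")
    frag.flags.add("recovered")
    for fl in g.flags:
        if fl not in ("lost-begin", "border-begin", "begin"):
            frag.flags.add(fl)
    for i, e in enumerate(adjacency.edges):
        if e.frag_a == g.id or e.frag_b == g.id:
            adjacency.edges[i] = type(e)(
                frag.id if e.frag_a == g.id else e.frag_a,
                frag.id if e.frag_b == g.id else e.frag_b,
                e.boundary_frame,
                e.intersection,
            )
    return True


# ---------------------------------------------------------------------------
# decision tree


def classify_tracking_error(
    frag: PathFragment,
    side: str,
    debris_max_span: int = 2,
    debris_speed_min: float = 15.0,
) -> str:
    """Classify one fragment terminus, in fixed priority order.

    ``side`` is "begin" or "end".  Returns one of ``none`` (movie boundary
    or explained by a validated junction), ``border``, ``merged``,
    ``mitosis``, ``vanished-recovered``, ``debris``, ``unresolved``.
    """
    f = frag.flags
    if side == "begin":
        if "begin" in f:
            return "none"
        if "border-begin" in f:
            return "border"
        if "merged" in f:
            return "merged"
        if "mitosis-born" in f:
            return "mitosis"
        if "recovered" in f:
            return "vanished-recovered"
        if "lost-begin" in f:
            if frag.length <= debris_max_span:
                if frag.length == 1:
                    return "debris"
                speed = float(np.mean([d[0] for d in frag.diffs])) if frag.diffs else 0.0
                if speed > debris_speed_min:
                    return "debris"
            return "unresolved"
        return "unresolved"
    if side == "end":
        if "end" in f:
            return "none"
        if "border-end" in f:
            return "border"
        if "merged" in f or "merged-end" in f:
            return "merged"
        if "mitosis" in f:
            return "mitosis"
        if "lost-end" in f:
            return "unresolved"  # recovery was attempted and failed
        return "unresolved"
    raise ValueError("side must be 'begin' or 'end'")


# ---------------------------------------------------------------------------
# assembly


def validate_and_assemble(
    fragments: dict[int, PathFragment],
    mitoses: list[MitosisEvent],
    frame_interval_min: float = 15.0,
    debris_max_span: int = 2,
    debris_speed_min: float = 15.0,
) -> tuple[list[CompletePath], LineageForest, dict[int, list[str]]]:
    """Accept complete mitosis-to-mitosis paths; reject everything doubtful.

    A fragment becomes a :class:`CompletePath` iff its begin is a daughter
    of a surviving mitosis, its end is the parent of a surviving mitosis,
    and no border/lost/merged flag occurs anywhere on it.  Accepted paths
    are linked into the lineage forest; every rejected fragment receives
    machine-readable reasons.
    """
    birth: dict[int, MitosisEvent] = {}
    for ev in mitoses:
        if ev.parent in fragments:
            for d in ev.daughters:
                if d in fragments:
                    birth[d] = ev
    terminal = {ev.parent: ev for ev in mitoses if ev.parent in fragments}

    bad_flags = {"merged", "merged-end", "lost-begin", "lost-end", "border-begin", "border-end"}
    accepted: list[CompletePath] = []
    rejected: dict[int, list[str]] = {}
    for fid, frag in sorted(fragments.items()):
        reasons = []
        if frag.flags & bad_flags:
            for side in ("begin", "end"):
                cls = classify_tracking_error(frag, side, debris_max_span, debris_speed_min)
                if cls not in ("none", "mitosis", "vanished-recovered"):
                    reasons.append(f"{side}:{cls}")
            if not reasons:
                reasons.append("flagged:" + ",".join(sorted(frag.flags & bad_flags)))
        if fid not in birth:
            reasons.append("begin:no-birth-mitosis")
        if fid not in terminal:
            reasons.append("end:no-terminal-mitosis")
        if reasons:
            rejected[fid] = reasons
        else:
            accepted.append(
                CompletePath(
                    id=fid,
                    fragment_id=fid,
                    start_frame=frag.start_frame,
                    end_frame=frag.end_frame,
                    labels=list(frag.labels),
                    birth_mitosis=birth[fid],
                    terminal_mitosis=terminal[fid],
                    start_x=frag.records[0].x if frag.records else 0.0,
                    start_y=frag.records[0].y if frag.records else 0.0,
                )
            )

    forest = LineageForest()
    by_id = {p.id: p for p in accepted}
    for p in accepted:
        forest.add_path(p)
    for p in accepted:
        ev = p.terminal_mitosis
        for d in ev.daughters:
            if d in by_id:
                forest.add_mitosis_edge(p.id, d, ev)
    return accepted, forest, rejected
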