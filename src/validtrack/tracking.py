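"""Overlap-based frame-to-frame linking and path-fragment construction.

Cells are linked across consecutive frames through the intersection of their
mask regions.  For a cell with area A_t and a candidate with area A_{t+1},

    forward overlap  O_fw = |intersection| / A_t
    backward overlap O_bw = |intersection| / A_{t+1}.

A link is made only when it is *unique*: the pair exceeds both thresholds
T_fw, T_bw and neither cell has a competing candidate.  Maximal chains of
unique links are *path fragments*; every detected cell belongs to exactly
one fragment.  All remaining concurrent overlaps are kept in a symmetric
adjacency structure which serves as the starting hypothesis for the
validation stage (mitosis / merge junctions live there).

``naive_track`` is the unvalidated baseline: backward tracking that simply
assigns every cell the predecessor with the greatest overlap, no thresholds,
no validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PathFragment",
    "Adjacency",
    "pairwise_overlaps",
    "link_cells",
    "build_path_fragments",
    "naive_track",
    "NaiveResult",
]


def pairwise_overlaps(mask_t: np.ndarray, mask_t1: np.ndarray) -> pd.DataFrame:
    """Exact pixel intersections between every label pair of two frames.

    Returns a table with columns ``label_a, label_b, intersection, o_fw,
    o_bw``; zero-intersection pairs are not stored.
    """
    a = np.asarray(mask_t)
    b = np.asarray(mask_t1)
    if a.shape != b.shape:
        raise ValueError("mask dimensions differ")
    fa = a.ravel().astype(np.int64)
    fb = b.ravel().astype(np.int64)
    sel = (fa > 0) & (fb > 0)
    if not sel.any():
        return pd.DataFrame(columns=["label_a", "label_b", "intersection", "o_fw", "o_bw"])
    width = int(fb.max()) + 1
    pairs, counts = np.unique(fa[sel] * width + fb[sel], return_counts=True)
    la = pairs // width
    lb = pairs % width
    area_a = np.bincount(fa)
    area_b = np.bincount(fb)
    return pd.DataFrame(
        {
            "label_a": la.astype(int),
            "label_b": lb.astype(int),
            "intersection": counts.astype(int),
            "o_fw": counts / area_a[la],
            "o_bw": counts / area_b[lb],
        }
    )


def link_cells(
    table: pd.DataFrame, t_fw: float = 0.3, t_bw: float = 0.3
) -> tuple[dict[int, int], pd.DataFrame]:
    """Split overlap candidates into unique links and ambiguous pairs.

    A pair is a *candidate* when both overlaps strictly exceed the
    thresholds.  A candidate is a unique link iff its source has exactly one
    candidate successor and its target exactly one candidate predecessor.
    Returns ``(links {label_a: label_b}, ambiguous candidate rows)``.
    """
    if not 0 <= t_fw <= 1 or not 0 <= t_bw <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    if table.empty:
        return {}, table
    cand = table[(table.o_fw > t_fw) & (table.o_bw > t_bw)]
    if cand.empty:
        return {}, cand
    na = cand.label_a.value_counts()
    nb = cand.label_b.value_counts()
    uniq = cand[(cand.label_a.map(na) == 1) & (cand.label_b.map(nb) == 1)]
    links = dict(zip(uniq.label_a.astype(int), uniq.label_b.astype(int)))
    ambiguous = cand.drop(uniq.index)
    return links, ambiguous


@dataclass
class PathFragment:
    """Temporally contiguous single-cell track (one label per frame)."""

    id: int
    start_frame: int
    labels: list[int]
    flags: set[str] = field(default_factory=set)
    records: list = field(default_factory=list)  # CellRecord per frame
    diffs: list = field(default_factory=list)  # difference vector per step

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.labels) - 1

    @property
    def length(self) -> int:
        return len(self.labels)

    def cells(self):
        return [(self.start_frame + i, lab) for i, lab in enumerate(self.labels)]


@dataclass(frozen=True)
class AdjacencyEdge:
    frag_a: int  # fragment holding the cell in the earlier frame
    frag_b: int  # fragment holding the cell in the later frame
    boundary_frame: int  # earlier frame index
    intersection: int


class Adjacency:
    """Symmetric candidate relation between path fragments.

    Records every concurrent (non-unique) overlap between cells of adjacent
    frames as a candidate continuation between the two involved fragments.
    """

    def __init__(self):
        self.edges: list[AdjacencyEdge] = []

    def add(self, frag_a: int, frag_b: int, frame: int, intersection: int) -> None:
        if frag_a == frag_b:
            return
        self.edges.append(AdjacencyEdge(frag_a, frag_b, frame, intersection))

    def successors(self, fragments: dict[int, PathFragment], frag_id: int) -> list[int]:
        """Fragments that *start* right after ``frag_id`` ends and are linked."""
        f = fragments[frag_id]
        out = []
        for e in self.edges:
            if e.frag_a == frag_id and e.boundary_frame == f.end_frame:
                g = fragments[e.frag_b]
                if g.start_frame == f.end_frame + 1 and e.frag_b not in out:
                    out.append(e.frag_b)
        return out

    def predecessors(self, fragments: dict[int, PathFragment], frag_id: int) -> list[int]:
        """Fragments that *end* right before ``frag_id`` starts and are linked."""
        g = fragments[frag_id]
        out = []
        for e in self.edges:
            if e.frag_b == frag_id and e.boundary_frame == g.start_frame - 1:
                f = fragments[e.frag_a]
                if f.end_frame == g.start_frame - 1 and e.frag_a not in out:
                    out.append(e.frag_a)
        return out

    def contains(self, frag_a: int, frag_b: int) -> bool:
        return any(
            (e.frag_a == frag_a and e.frag_b == frag_b)
            or (e.frag_a == frag_b and e.frag_b == frag_a)
            for e in self.edges
        )


def build_path_fragments(
    masks: list[np.ndarray],
    t_fw: float = 0.3,
    t_bw: float = 0.3,
    candidate_floor: int = 1,
) -> tuple[dict[int, PathFragment], Adjacency]:
    """Build maximal unique-link chains and the candidate adjacency.

    Every cell of every frame ends up in exactly one fragment.  At each
    abort point, all overlap pairs that failed uniqueness (intersection >=
    ``candidate_floor`` pixels) are recorded in the adjacency — a permissive
    starting hypothesis for validation.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 frames")
    fragments: dict[int, PathFragment] = {}
    adjacency = Adjacency()
    owner: dict[tuple[int, int], int] = {}
    next_id = 0

    def new_fragment(t: int, label: int) -> int:
        nonlocal next_id
        fragments[next_id] = PathFragment(id=next_id, start_frame=t, labels=[label])
        owner[(t, label)] = next_id
        next_id += 1
        return next_id - 1

    for lab in np.unique(masks[0]):
        if lab > 0:
            new_fragment(0, int(lab))

    for t in range(len(masks) - 1):
        table = pairwise_overlaps(masks[t], masks[t + 1])
        links, _ = link_cells(table, t_fw, t_bw)
        linked_targets = set(links.values())
        for la, lb in links.items():
            fid = owner[(t, la)]
            fragments[fid].labels.append(lb)
            owner[(t + 1, lb)] = fid
        for lab in np.unique(masks[t + 1]):
            lab = int(lab)
            if lab > 0 and lab not in linked_targets:
                new_fragment(t + 1, lab)
        for row in table.itertuples():
            la, lb = int(row.label_a), int(row.label_b)
            if links.get(la) == lb or row.intersection < candidate_floor:
                continue
            adjacency.add(owner[(t, la)], owner[(t + 1, lb)], t, int(row.intersection))
    return fragments, adjacency


@dataclass
class NaiveResult:
    """Output of the unvalidated backward-overlap baseline tracker."""

    paths: dict[int, PathFragment]
    #: (frame of the parent cell, parent path id, (daughter path ids))
    mitoses: list[tuple[int, int, tuple[int, ...]]]
    #: path ids whose begin AND end lie at 2-successor junctions
    complete_ids: list[int]


def naive_track(masks: list[np.ndarray]) -> NaiveResult:
    """Backward tracking: each cell takes the predecessor with most overlap.

    No thresholds and no validation are applied; Y-junctions (a predecessor
    chosen by exactly two cells) are read as putative mitoses.  Output uses
    the same path types as the validated pipeline so both can be scored by
    the evaluation module.
    """
    T = len(masks)
    pred: dict[tuple[int, int], tuple[int, int] | None] = {}
    succs: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for t in range(T - 1, 0, -1):
        table = pairwise_overlaps(masks[t - 1], masks[t])
        by_b: dict[int, list] = {}
        for row in table.itertuples():
            by_b.setdefault(int(row.label_b), []).append(row)
        for lab in np.unique(masks[t]):
            lab = int(lab)
            if lab == 0:
                continue
            rows = by_b.get(lab)
            if not rows:
                pred[(t, lab)] = None
                continue
            # largest intersection; ties: larger backward overlap, lower label
            best = max(rows, key=lambda r: (r.intersection, r.o_bw, -r.label_a))
            p = (t - 1, int(best.label_a))
            pred[(t, lab)] = p
            succs.setdefault(p, []).append((t, lab))
    for lab in np.unique(masks[0]):
        if lab > 0:
            pred[(0, int(lab))] = None

    paths: dict[int, PathFragment] = {}
    owner: dict[tuple[int, int], int] = {}
    next_id = 0
    for t in range(T):
        for lab in np.unique(masks[t]):
            lab = int(lab)
            if lab == 0:
                continue
            cell = (t, lab)
            p = pred[cell]
            if p is not None and len(succs.get(p, [])) == 1:
                fid = owner[p]
                paths[fid].labels.append(lab)
                owner[cell] = fid
            else:
                paths[next_id] = PathFragment(id=next_id, start_frame=t, labels=[lab])
                owner[cell] = next_id
                next_id += 1

    mitoses = []
    for parent_cell, children in succs.items():
        if len(children) == 2:
            daughters = tuple(sorted(owner[c] for c in children))
            mitoses.append((parent_cell[0], owner[parent_cell], daughters))
    born_at_y = {d for _, _, ds in mitoses for d in ds}
    parents_of_y = {p for _, p, _ in mitoses}
    complete_ids = [
        pid for pid, path in paths.items() if pid in born_at_y and pid in parents_of_y
    ]
    return NaiveResult(paths=paths, mitoses=sorted(mitoses), complete_ids=sorted(complete_ids))
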