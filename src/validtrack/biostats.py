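"""Biological culture parameters from detection and validated tracking.

Because accepted paths are whole cell lives, population statistics follow
directly: proliferation curves and division probabilities, confluency and
cell-area statistics, life-time (cell-cycle time) distributions, the
symmetry of sibling divisions, and simple per-tree summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .validate import CompletePath, LineageForest

__all__ = [
    "proliferation_curve",
    "division_probability",
    "confluency_and_mean_area",
    "lifetime_distribution",
    "sibling_symmetry",
    "tree_summary",
]


def proliferation_curve(masks: list[np.ndarray]) -> np.ndarray:
    """Number of detected cells (labels) per frame."""
    return np.array([len(np.unique(m)) - (1 if (np.asarray(m) == 0).any() else 0) for m in masks])


def division_probability(
    counts: np.ndarray,
    mitosis_frames: list[int],
    window_min: float = 120.0,
    frame_interval_min: float = 15.0,
) -> pd.DataFrame:
    """Per-window probability (%) for a cell to divide within the window.

    Computed as 100 x (divisions in window) / (mean cell count in window);
    windows tile the movie from frame 0.  Probability is NaN where the mean
    count is zero.
    """
    if window_min < frame_interval_min:
        raise ValueError("window must be at least one frame interval")
    counts = np.asarray(counts, dtype=float)
    wframes = max(1, int(round(window_min / frame_interval_min)))
    rows = []
    for start in range(0, len(counts), wframes):
        stop = min(start + wframes, len(counts))
        mean_count = counts[start:stop].mean()
        n_mit = sum(1 for f in mitosis_frames if start <= f < stop)
        prob = 100.0 * n_mit / mean_count if mean_count > 0 else np.nan
        rows.append(
            {
                "window_start_min": start * frame_interval_min,
                "window_end_min": stop * frame_interval_min,
                "mitoses": n_mit,
                "mean_cell_count": mean_count,
                "division_probability_pct": prob,
            }
        )
    return pd.DataFrame(rows)


def confluency_and_mean_area(
    masks: list[np.ndarray], pixel_size_um: float = 1.6
) -> pd.DataFrame:
    """Per-frame confluency (%) and mean +/- sd cell area (px and um^2).

    Confluency is the fraction of image pixels covered by detected cells.
    """
    rows = []
    for t, mask in enumerate(masks):
        mask = np.asarray(mask)
        areas = np.bincount(mask.ravel())[1:]
        areas = areas[areas > 0]
        fg = int(areas.sum())
        rows.append(
            {
                "frame": t,
                "confluency_pct": 100.0 * fg / mask.size,
                "mean_area_px": float(areas.mean()) if areas.size else np.nan,
                "sd_area_px": float(areas.std(ddof=0)) if areas.size else np.nan,
                "mean_area_um2": float(areas.mean()) * pixel_size_um**2 if areas.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def lifetime_distribution(
    accepted: list[CompletePath], frame_interval_min: float = 15.0
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Life times of complete paths, stamped with their end time.

    The life time of a path born in frame b that divides in frame e is
    ``(e - b) * interval``.  Returns the tidy samples plus a histogram with
    Freedman-Diaconis bins (edges included so plots can be reproduced).
    """
    samples = pd.DataFrame(
        [
            {
                "path_id": p.id,
                "lifetime_min": p.lifetime_minutes(frame_interval_min),
                "end_time_min": p.end_frame * frame_interval_min,
            }
            for p in accepted
        ],
        columns=["path_id", "lifetime_min", "end_time_min"],
    )
    if samples.empty:
        return samples, np.array([]), np.array([0.0])
    hist, edges = np.histogram(samples.lifetime_min.to_numpy(), bins="fd")
    return samples, hist, edges


def sibling_symmetry(
    forest: LineageForest, frame_interval_min: float = 15.0
) -> pd.DataFrame:
    """Signed life-time difference of the two daughters of each division.

    Only divisions whose *both* daughters are accepted complete paths
    qualify.  Daughters are ordered by birth centroid (lower y, then lower
    x); the absolute difference is emitted alongside since the sign is
    purely conventional.  Values near zero mean symmetric divisions.
    """
    g = forest.graph
    rows = []
    for parent in sorted(g.nodes):
        children = sorted(g.successors(parent))
        if len(children) != 2:
            continue
        d1, d2 = (g.nodes[c]["path"] for c in children)
        if (d1.start_y, d1.start_x) > (d2.start_y, d2.start_x):
            d1, d2 = d2, d1
        diff = d1.lifetime_minutes(frame_interval_min) - d2.lifetime_minutes(frame_interval_min)
        rows.append(
            {
                "parent_path": parent,
                "daughter_1": d1.id,
                "daughter_2": d2.id,
                "signed_diff_min": diff,
                "abs_diff_min": abs(diff),
            }
        )
    return pd.DataFrame(
        rows, columns=["parent_path", "daughter_1", "daughter_2", "signed_diff_min", "abs_diff_min"]
    )


def tree_summary(forest: LineageForest) -> pd.DataFrame:
    """Per-tree generation depth and connected path count.

    Generations = longest root-to-leaf chain of paths; path count = number
    of accepted paths in the tree.
    """
    g = forest.graph
    rows = []
    for i, nodes in enumerate(sorted(forest.trees(), key=min)):
        sub = g.subgraph(nodes)
        roots = [n for n in sub.nodes if sub.in_degree(n) == 0]
        depth = 0
        for root in roots:
            lengths = nx_longest_depth(sub, root)
            depth = max(depth, lengths)
        rows.append({"tree_id": i, "generations": depth + 1, "n_paths": len(nodes)})
    return pd.DataFrame(rows, columns=["tree_id", "generations", "n_paths"])


def nx_longest_depth(g, root) -> int:
    depth = 0
    stack = [(root, 0)]
    while stack:
        node, d = stack.pop()
        depth = max(depth, d)
        for c in g.successors(node):
            stack.append((c, d + 1))
    return depth
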