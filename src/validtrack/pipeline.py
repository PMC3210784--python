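"""End-to-end orchestration: frames -> masks -> fragments -> validated lineage.

Also hosts the calibration of the mitosis similarity model: on a clean
calibration movie with known divisions, terminal difference-vector windows
of truth-matched dividing fragments are collected, a multivariate normal is
fitted to them, and the acceptance threshold is set at the 5th percentile
of the training scores (95% recall on the calibration divisions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .detect import detect_stack
from .evaluate import frame_correspondences
from .features import SimilarityModel, fit_similarity_model
from .simulate import GroundTruth, SimulationConfig, simulate_movie
from .tracking import Adjacency, NaiveResult, PathFragment, build_path_fragments, naive_track
from .validate import (
    CompletePath,
    LineageForest,
    MergeEvent,
    MitosisEvent,
    assign_path_flags,
    attach_features,
    detect_merges,
    detect_mitoses,
    mitosis_window,
    recover_undetected,
    split_at_interior_branches,
    validate_and_assemble,
)

__all__ = ["TrackingParams", "PipelineResult", "run_pipeline", "calibrate_mitosis_model"]


@dataclass(frozen=True)
class TrackingParams:
    """All stage parameters of the tracking pipeline (pixels / minutes)."""

    gauss_sigma: float = 25.0
    erosion_radius: int = 1
    dilation_radius: int = 1
    min_area: int = 20
    t_fw: float = 0.3
    t_bw: float = 0.3
    candidate_floor: int = 1
    border_margin: float = 30.0
    k_window: int = 2
    max_gap: int = 5
    search_half: int = 30
    debris_max_span: int = 2
    debris_speed_min: float = 15.0
    frame_interval_min: float = 15.0
    overlap_floor: float = 0.3

    def __post_init__(self):
        for name in ("t_fw", "t_bw", "overlap_floor"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")


@dataclass
class PipelineResult:
    """Everything the validated pipeline produces for one movie."""

    pre: list[np.ndarray]
    masks: list[np.ndarray]
    fragments: dict[int, PathFragment]
    adjacency: Adjacency
    merges: list[MergeEvent]
    mitoses: list[MitosisEvent]
    accepted: list[CompletePath]
    forest: LineageForest
    rejected: dict[int, list[str]]

    def mitosis_tuples(self) -> list[tuple[int, int]]:
        return [(ev.frame, ev.parent) for ev in self.mitoses]

    def complete_spans(self) -> dict[int, tuple[int, int]]:
        return {p.id: (p.start_frame, p.end_frame) for p in self.accepted}


def run_pipeline(
    frames: list[np.ndarray],
    params: TrackingParams,
    mitosis_model: SimilarityModel,
    t_mit: float,
) -> PipelineResult:
    """Detect, link, validate and assemble the lineage forest for a movie."""
    pre, masks = detect_stack(
        frames,
        gauss_sigma=params.gauss_sigma,
        erosion_radius=params.erosion_radius,
        dilation_radius=params.dilation_radius,
        min_area=params.min_area,
    )
    fragments, adjacency = build_path_fragments(
        masks, params.t_fw, params.t_bw, params.candidate_floor
    )
    attach_features(fragments, masks, pre)
    split_at_interior_branches(fragments, adjacency)
    h, w = masks[0].shape
    assign_path_flags(
        fragments,
        adjacency,
        width=w,
        height=h,
        border_margin=params.border_margin,
        n_frames=len(masks),
        min_area=params.min_area,
    )
    merges = detect_merges(fragments, adjacency)
    # local re-detection of vanished cells; joins may expose further gaps
    for _ in range(3):
        changed = False
        for fid in sorted(fragments):
            frag = fragments.get(fid)
            if frag is not None and "lost-end" in frag.flags:
                if recover_undetected(
                    frag,
                    fragments,
                    adjacency,
                    masks,
                    pre,
                    t_fw=params.t_fw,
                    t_bw=params.t_bw,
                    max_gap=params.max_gap,
                    search_half=params.search_half,
                    erosion_radius=params.erosion_radius,
                    dilation_radius=params.dilation_radius,
                    min_area=params.min_area,
                ):
                    changed = True
        if not changed:
            break
    mitoses = detect_mitoses(fragments, adjacency, mitosis_model, t_mit, k=params.k_window)
    accepted, forest, rejected = validate_and_assemble(
        fragments,
        mitoses,
        frame_interval_min=params.frame_interval_min,
        debris_max_span=params.debris_max_span,
        debris_speed_min=params.debris_speed_min,
    )
    return PipelineResult(
        pre=pre,
        masks=masks,
        fragments=fragments,
        adjacency=adjacency,
        merges=merges,
        mitoses=mitoses,
        accepted=accepted,
        forest=forest,
        rejected=rejected,
    )


# ---------------------------------------------------------------------------
# mitosis-model calibration


#: clean calibration movie: enough divisions for a stable 4-D Gaussian fit
CALIBRATION_CONFIG = SimulationConfig(
    width=420,
    height=420,
    n_frames=70,
    initial_cells=14,
    mean_lifetime_min=300.0,
    sd_lifetime_min=60.0,
    noise_sd=6.0,
    gradient_amplitude=12.0,
    seed=0,
)


def calibrate_mitosis_model(
    seed: int = 0,
    params: TrackingParams | None = None,
    config: SimulationConfig | None = None,
    recall: float = 0.95,
) -> tuple[SimilarityModel, float]:
    """Fit the mitosis similarity model on known divisions.

    Simulates a clean calibration movie, detects and links it, matches
    fragment ends to true divisions, and fits the multivariate normal on
    their terminal difference-vector windows.  The threshold ``t_mit`` is
    the (1 - recall) quantile of the training scores, so the detector
    accepts the configured fraction of reference divisions by construction.
    """
    params = params or TrackingParams()
    config = replace(config or CALIBRATION_CONFIG, seed=seed)
    frames, truth = simulate_movie(config)
    pre, masks = detect_stack(
        frames,
        gauss_sigma=params.gauss_sigma,
        erosion_radius=params.erosion_radius,
        dilation_radius=params.dilation_radius,
        min_area=params.min_area,
    )
    fragments, _ = build_path_fragments(masks, params.t_fw, params.t_bw, params.candidate_floor)
    attach_features(fragments, masks, pre)
    maps = frame_correspondences(masks, truth, params.overlap_floor)
    div_frames = {parent: frame for parent, _, frame in truth.lineage}
    by_end: dict[int, list[PathFragment]] = {}
    for frag in fragments.values():
        by_end.setdefault(frag.end_frame, []).append(frag)
    windows = []
    for parent, d in div_frames.items():
        for frag in by_end.get(d, []):
            if maps[d].get(frag.labels[-1]) == parent:
                w = mitosis_window(frag, params.k_window)
                if w is not None:
                    windows.append(w)
                break
    if len(windows) < 8:
        raise RuntimeError("calibration movie produced too few matched divisions")
    model = fit_similarity_model(np.array(windows))
    from .features import similarity_probability

    probs = sorted(similarity_probability(w, model) for w in windows)
    t_mit = float(np.quantile(probs, 1.0 - recall))
    return model, t_mit


def save_mitosis_model(model: SimilarityModel, t_mit: float, path) -> None:
    """Persist the calibrated mitosis model and its threshold as JSON."""
    import json
    from pathlib import Path

    doc = {"mu": model.mu.tolist(), "cov": model.cov.tolist(), "n": model.n, "t_mit": t_mit}
    Path(path).write_text(json.dumps(doc, indent=1))


def load_mitosis_model(path) -> tuple[SimilarityModel, float]:
    import json
    from pathlib import Path

    doc = json.loads(Path(path).read_text())
    return SimilarityModel(mu=np.array(doc["mu"]), cov=np.array(doc["cov"])), float(doc["t_mit"])


def naive_complete_spans(result: NaiveResult) -> dict[int, tuple[int, int]]:
    """Spans of the naive tracker's putatively complete paths."""
    return {
        pid: (result.paths[pid].start_frame, result.paths[pid].end_frame)
        for pid in result.complete_ids
    }
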