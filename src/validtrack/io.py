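"""Readers/writers for all on-disk artifacts plus the run configuration.

Conventions: frames are 8-bit PNG (or TIFF), label masks 16-bit PNG so more
than 255 cells per frame are representable, tables are CSV with header rows,
summaries JSON.  Every writer has a matching reader and round-trips
losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .features import difference_vector, extract_features
from .pipeline import TrackingParams
from .simulate import SimulationConfig
from .tracking import Adjacency, PathFragment
from .validate import CompletePath, LineageForest, MitosisEvent

__all__ = [
    "RunConfig",
    "read_image_stack",
    "write_frames",
    "write_masks",
    "read_masks",
    "write_fragments",
    "read_fragments",
    "write_adjacency",
    "write_paths",
    "write_lineage_json",
    "write_rejections",
    "write_manifest",
]

_NUM = re.compile(r"(\d+)")


def _natural_key(path: Path):
    return [int(tok) if tok.isdigit() else tok for tok in _NUM.split(path.name)]


def read_image_stack(path_spec: str | Path, pattern: str = "*.png") -> list[np.ndarray]:
    """Read an ordered frame stack.

    ``path_spec`` may be a directory (files matching ``pattern`` in natural
    filename order; TIFFs are picked up too if the pattern allows) or a
    single multi-page TIFF / image file.  All frames must share dimensions.
    """
    path = Path(path_spec)
    if path.is_dir():
        files = sorted(path.glob(pattern), key=_natural_key)
        if not files:
            raise FileNotFoundError(f"no frames matching {pattern!r} in {path}")
        frames = [np.asarray(iio.imread(f)) for f in files]
    elif path.suffix.lower() in (".tif", ".tiff"):
        frames = [np.asarray(page) for page in tifffile.imread(path)]
        if frames and frames[0].ndim == 0:  # single page
            frames = [np.asarray(tifffile.imread(path))]
    elif path.exists():
        frames = [np.asarray(iio.imread(path))]
    else:
        raise FileNotFoundError(str(path))
    dims = {f.shape for f in frames}
    if len(dims) != 1:
        raise ValueError(f"frames have mixed dimensions: {sorted(dims)}")
    return frames


def write_frames(frames: list[np.ndarray], dest: str | Path, prefix: str = "frame") -> None:
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    for t, frame in enumerate(frames):
        iio.imwrite(dest / f"{prefix}_{t:04d}.png", np.asarray(frame, dtype=np.uint8))


def write_masks(masks: list[np.ndarray], dest: str | Path, prefix: str = "mask") -> None:
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    for t, mask in enumerate(masks):
        iio.imwrite(dest / f"{prefix}_{t:04d}.png", np.asarray(mask, dtype=np.uint16))


def read_masks(src: str | Path, pattern: str = "mask_*.png") -> list[np.ndarray]:
    files = sorted(Path(src).glob(pattern), key=_natural_key)
    if not files:
        raise FileNotFoundError(f"no masks matching {pattern!r} in {src}")
    return [np.asarray(iio.imread(f), dtype=np.uint16) for f in files]


# ---------------------------------------------------------------------------
# fragments / adjacency / paths


def write_fragments(fragments: dict[int, PathFragment], path: str | Path) -> None:
    rows = []
    for fid, frag in sorted(fragments.items()):
        for (t, lab), rec in zip(frag.cells(), frag.records):
            rows.append(
                {
                    "fragment_id": fid,
                    "frame": t,
                    "label": lab,
                    "x": rec.x,
                    "y": rec.y,
                    "area": rec.area,
                    "compactness": rec.compactness,
                    "mean_grey": rec.mean_grey,
                    "flags": ";".join(sorted(frag.flags)),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "fragment_id",
            "frame",
            "label",
            "x",
            "y",
            "area",
            "compactness",
            "mean_grey",
            "flags",
        ],
    ).to_csv(path, index=False)


def read_fragments(path: str | Path) -> dict[int, PathFragment]:
    from .features import CellRecord

    df = pd.read_csv(path, keep_default_na=False)
    fragments: dict[int, PathFragment] = {}
    for fid, grp in df.groupby("fragment_id"):
        grp = grp.sort_values("frame")
        records = [
            CellRecord(
                frame=int(r.frame),
                label=int(r.label),
                x=float(r.x),
                y=float(r.y),
                area=float(r.area),
                compactness=float(r.compactness),
                mean_grey=float(r.mean_grey),
            )
            for r in grp.itertuples()
        ]
        flags = set(str(grp["flags"].iloc[0]).split(";")) - {""}
        frag = PathFragment(
            id=int(fid),
            start_frame=int(grp.frame.iloc[0]),
            labels=[int(v) for v in grp.label],
            flags=flags,
            records=records,
            diffs=[difference_vector(a, b) for a, b in zip(records, records[1:])],
        )
        fragments[frag.id] = frag
    return fragments


def write_adjacency(adjacency: Adjacency, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "fragment_a": e.frag_a,
                "fragment_b": e.frag_b,
                "boundary_frame": e.boundary_frame,
                "intersection_px": e.intersection,
            }
            for e in adjacency.edges
        ],
        columns=["fragment_a", "fragment_b", "boundary_frame", "intersection_px"],
    ).to_csv(path, index=False)


def write_paths(
    accepted: list[CompletePath],
    forest: LineageForest,
    frame_interval_min: float,
    path: str | Path,
) -> None:
    parent_of = {}
    for u, v in forest.graph.edges:
        parent_of[v] = u
    pd.DataFrame(
        [
            {
                "path_id": p.id,
                "fragment_ids": p.fragment_id,
                "birth_frame": p.start_frame,
                "death_frame": p.end_frame,
                "lifetime_min": p.lifetime_minutes(frame_interval_min),
                "parent_path_id": parent_of.get(p.id, -1),
            }
            for p in accepted
        ],
        columns=[
            "path_id",
            "fragment_ids",
            "birth_frame",
            "death_frame",
            "lifetime_min",
            "parent_path_id",
        ],
    ).to_csv(path, index=False)


def write_lineage_json(
    accepted: list[CompletePath], forest: LineageForest, mitoses: list[MitosisEvent], path: str | Path
) -> None:
    doc = {
        "paths": [
            {
                "path_id": p.id,
                "birth_frame": p.start_frame,
                "death_frame": p.end_frame,
                "birth_mitosis_frame": p.birth_mitosis.frame,
                "terminal_mitosis_frame": p.terminal_mitosis.frame,
            }
            for p in accepted
        ],
        "edges": [
            {"parent_path": u, "daughter_path": v, "frame": d["event"].frame}
            for u, v, d in forest.graph.edges(data=True)
        ],
        "mitoses": [
            {
                "parent_fragment": ev.parent,
                "daughters": list(ev.daughters),
                "frame": ev.frame,
                "probability": ev.probability,
            }
            for ev in mitoses
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def write_rejections(
    rejected: dict[int, list[str]], fragments: dict[int, PathFragment], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "fragment_id": fid,
                "reason": ";".join(reasons),
                "start_frame": fragments[fid].start_frame,
                "end_frame": fragments[fid].end_frame,
            }
            for fid, reasons in sorted(rejected.items())
            if fid in fragments
        ],
        columns=["fragment_id", "reason", "start_frame", "end_frame"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration and manifest


@dataclass
class RunConfig:
    """Structured configuration for a whole run (YAML-backed).

    Unknown keys in the file are rejected so typos cannot silently fall back
    to defaults.  CLI flags override file values.
    """

    input: str | None = None
    output: str = "validtrack_out"
    pattern: str = "*.png"
    frame_interval_min: float = 15.0
    pixel_size_um: float = 1.6
    seed: int = 0
    tracking: TrackingParams = field(default_factory=TrackingParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - top
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(doc)
        if "tracking" in kwargs:
            sub = kwargs["tracking"] or {}
            allowed = {f.name for f in dataclasses.fields(TrackingParams)}
            bad = set(sub) - allowed
            if bad:
                raise ValueError(f"unknown tracking keys: {sorted(bad)}")
            kwargs["tracking"] = TrackingParams(**sub)
        if "simulation" in kwargs:
            sub = kwargs["simulation"] or {}
            allowed = {f.name for f in dataclasses.fields(SimulationConfig)}
            bad = set(sub) - allowed
            if bad:
                raise ValueError(f"unknown simulation keys: {sorted(bad)}")
            if "drift" in sub:
                sub["drift"] = tuple(sub["drift"])
            kwargs["simulation"] = SimulationConfig(**sub)
        cfg = cls(**kwargs)
        if cfg.frame_interval_min <= 0 or cfg.pixel_size_um <= 0:
            raise ValueError("frame interval and pixel size must be positive")
        return cfg

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["simulation"]["drift"] = list(doc["simulation"]["drift"])
        return doc

    def config_hash(self) -> str:
        doc = self.to_dict()
        doc.pop("input", None)  # paths are run plumbing, not analysis config
        doc.pop("output", None)
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(config: RunConfig, path: str | Path, extra: dict | None = None) -> None:
    from . import __version__

    doc = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
    }
    if extra:
        doc.update(extra)
    tmp = Path(str(path) + ".tmp")
    tmp.write_text(json.dumps(doc, indent=1, sort_keys=True))
    tmp.replace(path)  # atomic on POSIX
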