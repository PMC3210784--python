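"""Synthetic time-lapse simulator with pixel-exact ground truth.

Emulates an adherent, label-free cell culture as seen by a low-magnification
grey-scale camera: bright convex (elliptical) cell bodies on a darker
background, Brownian-plus-drift motion, cell divisions with the
characteristic pre-mitotic pattern (the cell contracts, rounds up and
brightens over the last frames before splitting into two touching
daughters), plus the four classic tracking-error scenarios:

* optical merging of two touching cells into a single region,
* transient intensity dropouts (a cell falls below global detectability),
* border crossings (cells leaving / entering the observed area),
* fast, linearly drifting debris particles.

Every run is fully reproducible from ``(config, seed)`` and emits a
:class:`GroundTruth` with per-frame true label masks, a stable cell
registry, lineage edges and a typed event log, so that trackers and
validators can be scored against exact truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TrueCell",
    "Event",
    "simulate_movie",
    "render_frame",
    "Blob",
    "export_ground_truth",
    "import_ground_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic movie.

    Counts are event totals over the whole movie (deterministic given the
    seed); geometric quantities are in pixels, times in minutes.
    """

    width: int = 512
    height: int = 512
    n_frames: int = 60
    frame_interval_min: float = 15.0
    pixel_size_um: float = 1.6
    initial_cells: int = 15
    mean_radius: float = 6.0
    sd_radius: float = 0.5
    aspect_mean: float = 1.4
    aspect_jitter: float = 0.04
    motion_sd: float = 1.0
    drift: tuple[float, float] = (0.0, 0.0)
    divide: bool = True
    mean_lifetime_min: float = 300.0
    sd_lifetime_min: float = 60.0
    max_cells: int = 100_000
    area_drop: float = 0.45
    brightness_rise: float = 0.35
    premitotic_frames: int = 2
    background: float = 30.0
    cell_intensity: float = 120.0
    intensity_sd: float = 8.0
    noise_sd: float = 6.0
    gradient_amplitude: float = 0.0
    n_merges: int = 0
    merge_duration: int = 4
    n_dropouts: int = 0
    dropout_duration: int = 3
    dropout_contrast: float = 0.35
    #: dropouts are scheduled on interior cells only; a vanishing cell at the
    #: image edge is indistinguishable from a border exit
    dropout_border_margin: float = 50.0
    n_debris: int = 0
    debris_speed: float = 35.0
    debris_radius: float = 3.0
    border_mode: str = "reflect"  # "reflect" keeps cells inside; "open" lets them cross
    n_border_entries: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("frame count must be positive")
        if self.initial_cells <= 0:
            raise ValueError("initial cell count must be positive")
        if self.mean_radius <= 0 or self.sd_radius < 0:
            raise ValueError("radii must be positive")
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")
        for name in ("n_merges", "n_dropouts", "n_debris", "n_border_entries"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.border_mode not in ("reflect", "open"):
            raise ValueError("border_mode must be 'reflect' or 'open'")


@dataclass(frozen=True)
class TrueCell:
    """Registry entry: one cell life (stable id from birth to division/exit)."""

    id: int
    first_frame: int
    last_frame: int
    parent: int | None  # None for roots (present at movie start or border entry)


@dataclass(frozen=True)
class Event:
    type: str  # border-exit | border-entry | merge-interval | dropout-interval | debris
    start_frame: int
    end_frame: int
    ids: tuple[int, ...]


@dataclass
class GroundTruth:
    """Simulator-emitted truth: masks, registry, lineage and event log."""

    masks: list[np.ndarray]
    cells: dict[int, TrueCell]
    lineage: list[tuple[int, int, int]]  # (parent_id, daughter_id, division_frame)
    events: list[Event]
    frame_interval_min: float = 15.0

    def lifetime_minutes(self, cell_id: int) -> float:
        c = self.cells[cell_id]
        return (c.last_frame - c.first_frame) * self.frame_interval_min

    def complete_cells(self) -> list[int]:
        """Cells born by a division that themselves divide inside the movie."""
        parents = {p for p, _, _ in self.lineage}
        daughters = {d for _, d, _ in self.lineage}
        return sorted(parents & daughters)


@dataclass(frozen=True)
class Blob:
    """Renderable ellipse: one cell (or debris particle) at one time point."""

    x: float
    y: float
    a: float  # semi-major axis, px
    b: float  # semi-minor axis, px
    phi: float
    intensity: float
    dropout: bool = False


# ---------------------------------------------------------------------------
# rendering


def _ellipse_patch(blob: Blob, shape: tuple[int, int]):
    """Boolean inside-mask and normalized radial coordinate on a local patch.

    Returns (ys, xs, inside, rho) where rho < 1 inside the ellipse; or None
    if the patch misses the image.
    """
    h, w = shape
    r = max(blob.a, blob.b)
    x0, x1 = int(math.floor(blob.x - r - 1)), int(math.ceil(blob.x + r + 2))
    y0, y1 = int(math.floor(blob.y - r - 1)), int(math.ceil(blob.y + r + 2))
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - blob.x
    dy = yy - blob.y
    c, s = math.cos(blob.phi), math.sin(blob.phi)
    u = (dx * c + dy * s) / blob.a
    v = (-dx * s + dy * c) / blob.b
    rho = u * u + v * v
    inside = rho <= 1.0
    if not inside.any():
        return None
    return slice(y0, y1), slice(x0, x1), inside, rho


def render_frame(
    blobs: list[Blob], config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render one grey frame from a world state.

    Cells are painted brighter than background (except dropout-flagged
    blobs, whose contrast is scaled by ``config.dropout_contrast``); an
    optional linear illumination gradient and additive Gaussian noise are
    applied.  Deterministic given the state and the generator's stream.
    """
    for blob in blobs:
        if blob.a <= 0 or blob.b <= 0:
            raise ValueError("blob with non-positive area")
    img = np.full((config.height, config.width), config.background, dtype=np.float64)
    if config.gradient_amplitude:
        img += config.gradient_amplitude * (
            np.arange(config.width, dtype=np.float64) / max(config.width - 1, 1)
        )
    for blob in blobs:
        patch = _ellipse_patch(blob, img.shape)
        if patch is None:
            continue
        ys, xs, inside, _ = patch
        inten = blob.intensity
        if blob.dropout:
            inten = config.background + config.dropout_contrast * (inten - config.background)
        region = img[ys, xs]
        region[inside] = np.maximum(region[inside], inten)
        img[ys, xs] = region
    if rng is not None and config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, img.shape)
    return np.rint(img).clip(0, 255).astype(np.uint8)


def _paint_truth(blobs: dict[int, Blob], shape: tuple[int, int]) -> np.ndarray:
    """Label mask with overlapping pixels assigned to the nearer cell centre."""
    labels = np.zeros(shape, dtype=np.uint16)
    score = np.full(shape, np.inf, dtype=np.float32)
    for cid, blob in blobs.items():
        patch = _ellipse_patch(blob, shape)
        if patch is None:
            continue
        ys, xs, inside, rho = patch
        sc = score[ys, xs]
        lb = labels[ys, xs]
        win = inside & (rho < sc)
        sc[win] = rho[win]
        lb[win] = cid
        score[ys, xs] = sc
        labels[ys, xs] = lb
    return labels


# ---------------------------------------------------------------------------
# world state


@dataclass
class _Cell:
    id: int
    x: float
    y: float
    r_birth: float
    r_target: float
    aspect: float  # mature aspect ratio (jittered per frame)
    aspect_birth: float  # 1.0 for newborn daughters (post-mitotic balls)
    phi: float
    intensity: float
    birth_frame: int
    div_frame: int | None  # scheduled last frame (division); None = no division
    parent: int | None
    dropout_from: int = -1
    dropout_until: int = -2
    merge_until: int = -1

    GROW_FRAMES = 6  # post-mitotic respreading to target size/shape

    def _growth(self, t: int) -> float:
        age = t - self.birth_frame
        return 1.0 if age >= self.GROW_FRAMES else age / self.GROW_FRAMES

    def radius_at(self, t: int) -> float:
        f = self._growth(t)
        return self.r_birth + f * (self.r_target - self.r_birth)

    def aspect_at(self, t: int) -> float:
        f = self._growth(t)
        return self.aspect_birth + f * (self.aspect - self.aspect_birth)

    def blob_at(self, t: int, cfg: SimulationConfig) -> Blob:
        r = self.radius_at(t)
        aspect = self.aspect_at(t)
        inten = self.intensity
        if self.div_frame is not None and cfg.premitotic_frames > 0:
            start = self.div_frame - cfg.premitotic_frames + 1
            if t >= start:
                prog = (t - start + 1) / cfg.premitotic_frames
                r = r * math.sqrt(1.0 - cfg.area_drop * prog)
                aspect = aspect + prog * (1.0 - aspect)
                inten = inten * (1.0 + cfg.brightness_rise * prog)
        a = r * math.sqrt(aspect)
        b = r / math.sqrt(aspect)
        return Blob(
            x=self.x,
            y=self.y,
            a=a,
            b=b,
            phi=self.phi,
            intensity=inten,
            dropout=self.dropout_from <= t <= self.dropout_until,
        )


@dataclass
class _Debris:
    x: float
    y: float
    vx: float
    vy: float
    r: float
    intensity: float
    start: int
    last_seen: int = -1


class _World:
    def __init__(self, cfg: SimulationConfig):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.cells: dict[int, _Cell] = {}
        self.registry: dict[int, dict] = {}
        self.lineage: list[tuple[int, int, int]] = []
        self.events: list[Event] = []
        self.debris: list[_Debris] = []
        self.merges: list[dict] = []
        self._next_id = 1
        self._life_frames_mean = cfg.mean_lifetime_min / cfg.frame_interval_min
        self._life_frames_sd = cfg.sd_lifetime_min / cfg.frame_interval_min
        self._schedule_events()
        self._place_initial()

    # -- scheduling -------------------------------------------------------

    def _schedule_events(self):
        cfg, rng = self.cfg, self.rng
        span = max(cfg.n_frames - 12, 1)
        self._merge_starts = sorted(int(rng.integers(4, 4 + span)) for _ in range(cfg.n_merges))
        self._dropout_starts = sorted(
            int(rng.integers(4, 4 + span)) for _ in range(cfg.n_dropouts)
        )
        self._debris_starts = sorted(
            int(rng.integers(1, max(cfg.n_frames - 2, 2))) for _ in range(cfg.n_debris)
        )
        self._entry_starts = sorted(
            int(rng.integers(2, max(cfg.n_frames - 5, 3))) for _ in range(cfg.n_border_entries)
        )

    def _draw_life_frames(self) -> int:
        raw = self.rng.normal(self._life_frames_mean, self._life_frames_sd)
        return max(2, int(round(raw)))

    def _new_cell(
        self, x, y, birth, parent, r_birth=None, aspect_birth=None, residual_uniform=False
    ) -> _Cell:
        cfg, rng = self.cfg, self.rng
        r_target = max(2.0, rng.normal(cfg.mean_radius, cfg.sd_radius))
        aspect = max(1.0, rng.normal(cfg.aspect_mean, 0.1))
        inten = rng.normal(cfg.cell_intensity, cfg.intensity_sd)
        life = self._draw_life_frames()
        if cfg.divide:
            # division frame chosen so (div - birth) * interval matches the
            # configured mitosis-to-mitosis life time
            if residual_uniform:
                div = birth + int(rng.integers(2, life + 1))
            else:
                div = birth + life
        else:
            div = None
        cell = _Cell(
            id=self._next_id,
            x=float(x),
            y=float(y),
            r_birth=float(r_birth if r_birth is not None else r_target),
            r_target=float(r_target),
            aspect=float(aspect),
            aspect_birth=float(aspect_birth if aspect_birth is not None else aspect),
            phi=float(rng.uniform(0, math.pi)),
            intensity=float(inten),
            birth_frame=birth,
            div_frame=div,
            parent=parent,
        )
        self._next_id += 1
        self.cells[cell.id] = cell
        self.registry[cell.id] = {"first": birth, "last": birth, "parent": parent}
        return cell

    def _place_initial(self):
        cfg, rng = self.cfg, self.rng
        inset = cfg.mean_radius * math.sqrt(cfg.aspect_mean) + 4
        sep = 2 * cfg.mean_radius * math.sqrt(cfg.aspect_mean) + 4
        placed: list[tuple[float, float]] = []
        attempts = 0
        while len(placed) < cfg.initial_cells and attempts < 20000 * cfg.initial_cells:
            attempts += 1
            x = rng.uniform(inset, cfg.width - inset)
            y = rng.uniform(inset, cfg.height - inset)
            if all((x - px) ** 2 + (y - py) ** 2 >= sep * sep for px, py in placed):
                placed.append((x, y))
        if len(placed) < cfg.initial_cells:
            raise ValueError("could not place initial cells; image too small")
        for x, y in placed:
            self._new_cell(x, y, birth=0, parent=None, residual_uniform=True)

    # -- per-frame dynamics ----------------------------------------------

    def _postpone_division(self, cell: _Cell, until: int):
        if cell.div_frame is not None and cell.div_frame <= until:
            cell.div_frame = until + 1 + int(self.rng.integers(0, 3))

    def _start_merges(self, t: int):
        """Steer two neighbouring cells into contact, hold, then separate.

        The partner closes in over a few frames (small per-frame steps keep
        the overlap chain alive), the pair sits in deep contact — rendered as
        one connected region — for ``merge_duration`` frames, then departs.
        """
        cfg = self.cfg
        approach = 3
        while self._merge_starts and self._merge_starts[0] == t:
            self._merge_starts.pop(0)
            horizon = t + approach + cfg.merge_duration + 6
            free = [
                c
                for c in self.cells.values()
                if c.merge_until < t
                and (c.div_frame is None or c.div_frame > horizon)
                and c.dropout_until < t
                and c.birth_frame < t - 1
            ]
            if len(free) < 2:
                continue
            anchor = free[int(self.rng.integers(len(free)))]
            others = [c for c in free if c.id != anchor.id]
            partner = min(others, key=lambda c: (c.x - anchor.x) ** 2 + (c.y - anchor.y) ** 2)
            contact = t + approach
            end = contact + cfg.merge_duration - 1
            d0 = math.hypot(partner.x - anchor.x, partner.y - anchor.y)
            angle = math.atan2(partner.y - anchor.y, partner.x - anchor.x)
            self.merges.append(
                {
                    "a": anchor.id,
                    "b": partner.id,
                    "start": t,
                    "contact": contact,
                    "end": end,
                    "angle": angle,
                    "d0": d0,
                }
            )
            anchor.merge_until = end + 2
            partner.merge_until = end + 2
            self._postpone_division(anchor, end + 4)
            self._postpone_division(partner, end + 4)
            # logged span covers approach through full departure (the whole
            # interval in which the pair's tracks cannot be trusted)
            self.events.append(Event("merge-interval", t, end + 2, (anchor.id, partner.id)))

    def _start_dropouts(self, t: int):
        cfg = self.cfg
        while self._dropout_starts and self._dropout_starts[0] == t:
            self._dropout_starts.pop(0)
            end = t + cfg.dropout_duration - 1
            m = cfg.dropout_border_margin
            eligible = [
                c
                for c in self.cells.values()
                if c.dropout_until < t
                and c.merge_until < t
                and c.birth_frame < t
                and (c.div_frame is None or c.div_frame > end + 3)
                and m <= c.x <= cfg.width - m
                and m <= c.y <= cfg.height - m
            ]
            if not eligible:
                continue
            cell = eligible[int(self.rng.integers(len(eligible)))]
            cell.dropout_from = t
            cell.dropout_until = end
            self._postpone_division(cell, end + 3)
            self.events.append(Event("dropout-interval", t, end, (cell.id,)))

    def _start_debris(self, t: int):
        cfg = self.cfg
        while self._debris_starts and self._debris_starts[0] == t:
            self._debris_starts.pop(0)
            edge = int(self.rng.integers(4))
            if edge == 0:  # left -> right
                x, y = -cfg.debris_radius, self.rng.uniform(0, cfg.height)
                ang = self.rng.uniform(-0.3, 0.3)
            elif edge == 1:
                x, y = cfg.width + cfg.debris_radius, self.rng.uniform(0, cfg.height)
                ang = math.pi + self.rng.uniform(-0.3, 0.3)
            elif edge == 2:
                x, y = self.rng.uniform(0, cfg.width), -cfg.debris_radius
                ang = math.pi / 2 + self.rng.uniform(-0.3, 0.3)
            else:
                x, y = self.rng.uniform(0, cfg.width), cfg.height + cfg.debris_radius
                ang = -math.pi / 2 + self.rng.uniform(-0.3, 0.3)
            self.debris.append(
                _Debris(
                    x=float(x),
                    y=float(y),
                    vx=cfg.debris_speed * math.cos(ang),
                    vy=cfg.debris_speed * math.sin(ang),
                    r=cfg.debris_radius,
                    intensity=float(self.rng.normal(cfg.cell_intensity, cfg.intensity_sd)),
                    start=t,
                )
            )

    def _start_entries(self, t: int):
        cfg = self.cfg
        while self._entry_starts and self._entry_starts[0] == t:
            self._entry_starts.pop(0)
            edge = int(self.rng.integers(4))
            r = cfg.mean_radius
            if edge == 0:
                x, y = r + 1, self.rng.uniform(r, cfg.height - r)
            elif edge == 1:
                x, y = cfg.width - r - 1, self.rng.uniform(r, cfg.height - r)
            elif edge == 2:
                x, y = self.rng.uniform(r, cfg.width - r), r + 1
            else:
                x, y = self.rng.uniform(r, cfg.width - r), cfg.height - r - 1
            cell = self._new_cell(x, y, birth=t, parent=None)
            self.events.append(Event("border-entry", t, t, (cell.id,)))

    def _apply_merge_positions(self, t: int):
        for m in self.merges:
            if not (m["start"] <= t <= m["end"] + 2):
                continue
            a = self.cells.get(m["a"])
            b = self.cells.get(m["b"])
            if a is None or b is None:
                continue
            ra = a.radius_at(t) * math.sqrt(a.aspect_at(t))
            rb = b.radius_at(t) * math.sqrt(b.aspect_at(t))
            touch = 0.55 * (ra + rb)  # deep contact: rendered as one region
            if t < m["contact"]:
                f = (t - m["start"]) / (m["contact"] - m["start"])
                dist = m["d0"] + f * (touch - m["d0"])
            elif t <= m["end"]:
                dist = touch
            else:  # departure: separate over two frames
                k = t - m["end"]
                dist = (ra + rb) * (0.55 + 0.45 * k) + 1.5 * k
            b.x = a.x + dist * math.cos(m["angle"])
            b.y = a.y + dist * math.sin(m["angle"])

    def _move(self, t: int):
        cfg, rng = self.cfg, self.rng
        ids = sorted(self.cells)
        for cid in ids:
            c = self.cells[cid]
            if c.merge_until >= t:
                continue  # merge override controls this cell's position
            c.x += rng.normal(0, cfg.motion_sd) + cfg.drift[0]
            c.y += rng.normal(0, cfg.motion_sd) + cfg.drift[1]
            c.phi += rng.normal(0, cfg.aspect_jitter)
            c.aspect = max(1.0, c.aspect + rng.normal(0, cfg.aspect_jitter))
        self._relax(t)
        if cfg.border_mode == "reflect":
            for c in self.cells.values():
                r = c.radius_at(t) * math.sqrt(c.aspect_at(t)) + 2
                c.x = min(max(c.x, r), cfg.width - r)
                c.y = min(max(c.y, r), cfg.height - r)
        else:
            gone = [
                cid
                for cid, c in self.cells.items()
                if not (0 <= c.x < cfg.width and 0 <= c.y < cfg.height)
            ]
            for cid in gone:
                self.events.append(Event("border-exit", t + 1, t + 1, (cid,)))
                del self.cells[cid]

    def _relax(self, t: int, passes: int = 3, gap: float = 2.5):
        """Soft contact avoidance: push overlapping non-merging cells apart."""
        merging = {
            frozenset((m["a"], m["b"])) for m in self.merges if m["start"] <= t <= m["end"] + 2
        }
        ids = sorted(self.cells)
        if len(ids) < 2:
            return
        rad = {cid: self.cells[cid].radius_at(t) * math.sqrt(self.cells[cid].aspect_at(t)) for cid in ids}
        rmax = max(rad.values())
        for _ in range(passes):
            pts = np.array([[self.cells[cid].x, self.cells[cid].y] for cid in ids])
            tree = cKDTree(pts)
            pairs = sorted(tree.query_pairs(r=2 * rmax + gap))
            moved = False
            for i, j in pairs:
                ci, cj = self.cells[ids[i]], self.cells[ids[j]]
                if frozenset((ci.id, cj.id)) in merging:
                    continue
                req = rad[ci.id] + rad[cj.id] + gap
                dx, dy = cj.x - ci.x, cj.y - ci.y
                d = math.hypot(dx, dy)
                if d >= req:
                    continue
                if d < 1e-6:
                    ang = self.rng.uniform(0, 2 * math.pi)
                    dx, dy, d = math.cos(ang), math.sin(ang), 1.0
                push = (req - d) / 2
                ux, uy = dx / d, dy / d
                locked_i = ci.merge_until >= t
                locked_j = cj.merge_until >= t
                if not locked_i:
                    ci.x -= push * ux * (2 if locked_j else 1)
                    ci.y -= push * uy * (2 if locked_j else 1)
                if not locked_j:
                    cj.x += push * ux * (2 if locked_i else 1)
                    cj.y += push * uy * (2 if locked_i else 1)
                moved = True
            if not moved:
                break

    def _divide(self, t: int):
        cfg, rng = self.cfg, self.rng
        for cid in sorted(self.cells):
            c = self.cells[cid]
            if c.div_frame != t:
                continue
            if len(self.cells) >= cfg.max_cells:
                self._postpone_division(c, t + 2)
                continue
            # daughters emerge as small round balls splitting the contracted
            # mitotic cell in place, then respread to full size
            r_d = c.r_target * math.sqrt((1.0 - cfg.area_drop) / 2.0)
            ang = rng.uniform(0, math.pi)
            off = r_d + 1.2
            del self.cells[cid]
            for sgn in (+1, -1):
                d = self._new_cell(
                    c.x + sgn * off * math.cos(ang),
                    c.y + sgn * off * math.sin(ang),
                    birth=t + 1,
                    parent=cid,
                    r_birth=r_d,
                    aspect_birth=1.0,
                )
                self.lineage.append((cid, d.id, t))

    def step(self, t: int):
        """Advance the world from the state rendered at t to frame t+1."""
        self._divide(t)
        self._move(t)

    def frame_state(self, t: int) -> tuple[dict[int, Blob], list[Blob]]:
        self._start_entries(t)
        self._start_merges(t)
        self._start_dropouts(t)
        self._start_debris(t)
        self._apply_merge_positions(t)
        cfg = self.cfg
        blobs = {}
        for cid in sorted(self.cells):
            c = self.cells[cid]
            blobs[cid] = c.blob_at(t, cfg)
            self.registry[cid]["last"] = t
        debris_blobs = []
        for d in self.debris:
            if d.start > t:
                continue
            age = t - d.start
            x, y = d.x + age * d.vx, d.y + age * d.vy
            if -d.r <= x < cfg.width + d.r and -d.r <= y < cfg.height + d.r:
                debris_blobs.append(Blob(x=x, y=y, a=d.r, b=d.r, phi=0.0, intensity=d.intensity))
                d.last_seen = t
        return blobs, debris_blobs


def simulate_movie(config: SimulationConfig) -> tuple[list[np.ndarray], GroundTruth]:
    """Run the simulator: returns grey frames and pixel-exact ground truth."""
    world = _World(config)
    frames: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for t in range(config.n_frames):
        blobs, debris = world.frame_state(t)
        shape = (config.height, config.width)
        masks.append(_paint_truth(blobs, shape))
        frames.append(render_frame(list(blobs.values()) + debris, config, world.rng))
        if t < config.n_frames - 1:
            world.step(t)
    for i, d in enumerate(world.debris):
        if d.last_seen >= d.start:
            world.events.append(Event("debris", d.start, d.last_seen, (-(i + 1),)))
    cells = {
        cid: TrueCell(cid, reg["first"], reg["last"], reg["parent"])
        for cid, reg in world.registry.items()
    }
    truth = GroundTruth(
        masks=masks,
        cells=cells,
        lineage=sorted(world.lineage),
        events=sorted(world.events, key=lambda e: (e.start_frame, e.type, e.ids)),
        frame_interval_min=config.frame_interval_min,
    )
    return frames, truth


# ---------------------------------------------------------------------------
# on-disk ground truth


def export_ground_truth(truth: GroundTruth, destination: str | Path) -> None:
    """Write truth masks (16-bit PNG) and lineage/event/cell tables (CSV)."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    for t, mask in enumerate(truth.masks):
        iio.imwrite(dest / f"truth_{t:04d}.png", mask.astype(np.uint16))
    pd.DataFrame(truth.lineage, columns=["parent_id", "daughter_id", "frame"]).to_csv(
        dest / "lineage.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "event_type": e.type,
                "start_frame": e.start_frame,
                "end_frame": e.end_frame,
                "ids": ";".join(str(i) for i in e.ids),
            }
            for e in truth.events
        ],
        columns=["event_type", "start_frame", "end_frame", "ids"],
    ).to_csv(dest / "events.csv", index=False)
    pd.DataFrame(
        [
            {
                "cell_id": c.id,
                "first_frame": c.first_frame,
                "last_frame": c.last_frame,
                "parent_id": -1 if c.parent is None else c.parent,
            }
            for c in sorted(truth.cells.values(), key=lambda c: c.id)
        ],
        columns=["cell_id", "first_frame", "last_frame", "parent_id"],
    ).to_csv(dest / "cells.csv", index=False)
    (dest / "meta.csv").write_text(
        f"frame_interval_min,n_frames\n{truth.frame_interval_min},{len(truth.masks)}\n"
    )


def import_ground_truth(source: str | Path) -> GroundTruth:
    """Read back a :func:`export_ground_truth` directory (lossless)."""
    src = Path(source)
    meta = pd.read_csv(src / "meta.csv")
    n = int(meta.n_frames[0])
    masks = [np.asarray(iio.imread(src / f"truth_{t:04d}.png"), dtype=np.uint16) for t in range(n)]
    lin = pd.read_csv(src / "lineage.csv")
    lineage = [tuple(int(v) for v in row) for row in lin.itertuples(index=False)]
    ev = pd.read_csv(src / "events.csv")
    events = [
        Event(
            r.event_type,
            int(r.start_frame),
            int(r.end_frame),
            tuple(int(x) for x in str(r.ids).split(";")),
        )
        for r in ev.itertuples()
    ]
    cdf = pd.read_csv(src / "cells.csv")
    cells = {
        int(r.cell_id): TrueCell(
            int(r.cell_id),
            int(r.first_frame),
            int(r.last_frame),
            None if int(r.parent_id) < 0 else int(r.parent_id),
        )
        for r in cdf.itertuples()
    }
    return GroundTruth(
        masks=masks,
        cells=cells,
        lineage=sorted(lineage),
        events=sorted(events, key=lambda e: (e.start_frame, e.type, e.ids)),
        frame_interval_min=float(meta.frame_interval_min[0]),
    )
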