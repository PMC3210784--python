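"""Per-cell features and the multivariate-normal similarity measure.

Each detected cell gets a feature vector f = (x̄, ȳ, A, C, ḡ): centroid,
area in pixels, compactness C = 4·pi·A / P² (1 for a perfect circle, smaller
for elongated shapes) and mean grey value.  Along a cell path, consecutive
features are reduced to a difference vector d = (Δs, ΔA, Δḡ, ΔC) — speed,
size change, brightness change, compactness change.  The similarity of a
cell with itself across one frame step is scored as the density of a
multivariate normal fitted to reference difference vectors:

    Prob(d) = (2 pi)^(-n/2) |Σ|^(-1/2) exp(-0.5 (d-µ)ᵀ Σ⁻¹ (d-µ)),  n = 4.

A mitosis shows the opposite usage: the *same* density, fitted on the
characteristic pre-division pattern (area drop, rounding, brightening), must
*exceed* a threshold for a division to be accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg
from skimage.measure import regionprops

__all__ = [
    "CellRecord",
    "SimilarityModel",
    "extract_features",
    "difference_vector",
    "fit_similarity_model",
    "similarity_probability",
]


@dataclass(frozen=True)
class CellRecord:
    """Feature vector of one detected cell in one frame."""

    frame: int
    label: int
    x: float
    y: float
    area: float
    compactness: float
    mean_grey: float


def extract_features(mask: np.ndarray, image: np.ndarray, frame_index: int = 0) -> list[CellRecord]:
    """One :class:`CellRecord` per label of a cell mask.

    Centroid is the mean pixel coordinate, area the pixel count, mean grey
    the average image intensity over the region, and compactness
    ``4*pi*A/P**2`` with P the region's outer boundary length.
    """
    if mask.shape != image.shape:
        raise ValueError("mask and frame dimensions differ")
    out = []
    for rp in regionprops(np.asarray(mask), intensity_image=np.asarray(image)):
        # Crofton estimate: unbiased for smooth boundaries, where the
        # chain-code perimeter overestimates by ~5% and would push the
        # compactness of a circle visibly below 1
        perim = rp.perimeter_crofton
        comp = 4.0 * np.pi * rp.area / (perim * perim) if perim > 0 else 1.0
        cy, cx = rp.centroid
        out.append(
            CellRecord(
                frame=frame_index,
                label=int(rp.label),
                x=float(cx),
                y=float(cy),
                area=float(rp.area),
                compactness=float(comp),
                mean_grey=float(rp.intensity_mean),
            )
        )
    return out


def difference_vector(a: CellRecord, b: CellRecord) -> np.ndarray:
    """Difference vector d = (Δs, ΔA, Δḡ, ΔC) between consecutive records.

    Δs is the Euclidean centroid displacement (non-negative); the remaining
    components are signed changes ``b - a``.
    """
    if b.frame != a.frame + 1:
        raise ValueError("records must come from consecutive frames")
    ds = float(np.hypot(b.x - a.x, b.y - a.y))
    return np.array(
        [ds, b.area - a.area, b.mean_grey - a.mean_grey, b.compactness - a.compactness]
    )


@dataclass
class SimilarityModel:
    """Mean vector and covariance of the 4-D difference-vector distribution."""

    mu: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        n = self.mu.shape[0]
        if self.cov.shape != (n, n):
            raise ValueError("covariance shape does not match mean")

    @property
    def n(self) -> int:
        return self.mu.shape[0]

    def to_json(self, path: str | Path) -> None:
        doc = {"mu": self.mu.tolist(), "cov": self.cov.tolist(), "n": self.n}
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimilarityModel":
        doc = json.loads(Path(path).read_text())
        return cls(mu=np.array(doc["mu"]), cov=np.array(doc["cov"]))


def fit_similarity_model(samples: np.ndarray | list, ridge_scale: float = 1e-6) -> SimilarityModel:
    """Fit µ and Σ by sample mean / covariance with a ridge safeguard.

    If the sample covariance is near-singular (e.g. a constant coordinate), a
    ridge ``eps = ridge_scale * trace(Σ)/n`` (floor: ridge_scale) is added to
    the diagonal so that Σ stays positive-definite.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be a 2-D array (m, n)")
    m, n = samples.shape
    if m < n + 1:
        raise ValueError(f"need at least {n + 1} samples, got {m}")
    mu = samples.mean(axis=0)
    cov = np.cov(samples, rowvar=False, bias=False)
    cov = np.atleast_2d(cov)
    eps = ridge_scale * max(np.trace(cov) / n, 1.0)
    try:
        # positive-definite check; eigenvalue floor guards rank deficiency
        if np.linalg.eigvalsh(cov).min() <= eps:
            cov = cov + eps * np.eye(n)
    except np.linalg.LinAlgError:
        cov = cov + eps * np.eye(n)
    return SimilarityModel(mu=mu, cov=cov)


def similarity_probability(d: np.ndarray, model: SimilarityModel) -> float:
    """Multivariate normal density of a difference vector under the model.

    Evaluated directly from the closed form via a Cholesky factorization of
    Σ; raises on a singular covariance.
    """
    d = np.asarray(d, dtype=float)
    n = model.n
    if d.shape != (n,):
        raise ValueError(f"difference vector must have length {n}")
    try:
        chol, low = linalg.cho_factor(model.cov, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("singular covariance matrix") from exc
    diff = d - model.mu
    sol = linalg.cho_solve((chol, low), diff)
    maha = float(diff @ sol)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return float(np.exp(-0.5 * (n * np.log(2.0 * np.pi) + logdet + maha)))
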