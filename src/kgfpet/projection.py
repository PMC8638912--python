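"""Forward projection and Poisson count simulation.

The projector is a pixel-driven parallel-beam operator: for each projection
angle the pixel centers are projected onto the detector axis and each pixel's
value is split linearly between its two nearest radial bins.  It is stored as
a sparse matrix, so the adjoint is exactly the transpose — a matched pair,
which the multiplicative EM reconstructions rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse

from .containers import DynamicImageSet, DynamicSinogramSet

__all__ = [
    "ProjectionGeometry",
    "SystemModel",
    "make_system_model",
    "forward_project",
    "scale_to_counts",
    "add_randoms_and_noise",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam sampling: radial bins x angles uniform over 180 degrees."""

    n_bins: int
    n_angles: int
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.n_bins < 8 or self.n_angles < 8:
            raise ValueError("need at least 8 bins and 8 angles")

    @property
    def M(self) -> int:
        return self.n_bins * self.n_angles

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles


class SystemModel:
    """Linear forward operator H (image -> sinogram) with exact adjoint.

    ``S`` is the additive expectation of random/scattered events, initialised
    to zero and set by the noise simulator.  Optional per-bin attenuation
    factors are folded multiplicatively into H.
    """

    def __init__(
        self,
        geometry: ProjectionGeometry,
        matrix: sparse.csr_matrix,
        attenuation: Optional[np.ndarray] = None,
    ):
        self.geometry = geometry
        if attenuation is not None:
            attenuation = np.asarray(attenuation, dtype=float)
            if attenuation.shape != (geometry.M,):
                raise ValueError("attenuation must be one factor per sinogram bin")
            if np.any(attenuation < 0):
                raise ValueError("attenuation factors must be nonnegative")
            matrix = sparse.diags(attenuation) @ matrix
        self._H = matrix.tocsr()
        self._HT = self._H.T.tocsr()
        self.attenuation = attenuation
        self.S = np.zeros((geometry.M, 1))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """H x for a flat image vector or an (n_pixels, N) matrix."""
        return self._H @ x

    def adjoint(self, p: np.ndarray) -> np.ndarray:
        """H^T p for a flat sinogram vector or an (M, N) matrix."""
        return self._HT @ p

    def sensitivity(self) -> np.ndarray:
        """Per-pixel sensitivity H^T 1 (back projection of a unit sinogram)."""
        return self.adjoint(np.ones(self.geometry.M))

    def dense(self) -> np.ndarray:
        return self._H.toarray()


def make_system_model(
    geometry: ProjectionGeometry, attenuation: Optional[np.ndarray] = None
) -> SystemModel:
    """Build the sparse pixel-driven projection matrix for ``geometry``."""
    H, W = geometry.grid_shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    yc, xc = (yy - cy).ravel(), (xx - cx).ravel()
    n_pix = H * W
    center = (geometry.n_bins - 1) / 2.0

    rows, cols, vals = [], [], []
    pix_idx = np.arange(n_pix)
    for a, theta in enumerate(geometry.angles):
        s = xc * np.cos(theta) + yc * np.sin(theta) + center
        lo = np.floor(s).astype(int)
        frac = s - lo
        for bin_idx, weight in ((lo, 1.0 - frac), (lo + 1, frac)):
            ok = (bin_idx >= 0) & (bin_idx < geometry.n_bins) & (weight > 0)
            rows.append(bin_idx[ok] + a * geometry.n_bins)
            cols.append(pix_idx[ok])
            vals.append(weight[ok])

    matrix = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geometry.M, n_pix),
    )
    return SystemModel(geometry, matrix, attenuation=attenuation)


def forward_project(images: DynamicImageSet, model: SystemModel) -> DynamicSinogramSet:
    """Noiseless sinograms: column i = H (x_i * frame_duration_i).

    Multiplying by the frame duration converts the activity-rate images into
    accumulated counts, so long late frames carry more signal.
    """
    if images.grid_shape != model.geometry.grid_shape:
        raise ValueError("image grid does not match the projector geometry")
    P = model.forward(images.X * images.schedule.frame_duration[None, :])
    return DynamicSinogramSet(
        P=P,
        n_bins=model.geometry.n_bins,
        n_angles=model.geometry.n_angles,
        schedule=images.schedule,
        provenance="noiseless",
    )


def scale_to_counts(
    noiseless: DynamicSinogramSet, total_events: float
) -> DynamicSinogramSet:
    """Apply one global factor so the grand total equals ``total_events``."""
    total = noiseless.P.sum()
    if total <= 0:
        raise ValueError("cannot scale an all-zero sinogram set")
    factor = total_events / total
    out = noiseless.with_P(noiseless.P * factor)
    out.meta["scale_factor"] = factor
    return out


def add_randoms_and_noise(
    scaled: DynamicSinogramSet, randoms_fraction: float = 0.2, seed: int = 0
) -> tuple[DynamicSinogramSet, np.ndarray]:
    """Simulate randoms plus Poisson counting noise.

    The randoms background S is spatially uniform within each frame and sized
    so that randoms make up ``randoms_fraction`` of the total acquired events
    (true events are scaled down to the complement, so the grand-total
    expectation is unchanged).  Returns the noisy set and S, which the
    reconstruction treats as a known additive expectation.
    """
    if not 0.0 <= randoms_fraction < 1.0:
        raise ValueError("randoms_fraction must be in [0, 1)")
    trues = (1.0 - randoms_fraction) * scaled.P
    frame_trues = trues.sum(axis=0)
    # per-frame randoms expectation: f/(1-f) x that frame's true events
    randoms_per_frame = randoms_fraction / (1.0 - randoms_fraction) * frame_trues
    S = np.broadcast_to(randoms_per_frame / scaled.M, scaled.P.shape).copy()

    rng = np.random.default_rng(seed)
    noisy_P = rng.poisson(trues + S).astype(float)
    noisy = scaled.with_P(noisy_P, provenance="noisy")
    noisy.seed = seed
    noisy.meta["randoms_fraction"] = randoms_fraction
    noisy.meta["trues_total"] = float(frame_trues.sum())
    return noisy, S
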