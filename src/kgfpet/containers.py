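"""In-memory containers for dynamic PET data.

Both containers store the dynamic data as a single 2-D matrix whose columns
are time frames, the layout every algorithm in this package operates on:

* ``DynamicImageSet`` — X, (n_pixels x N) column-stacked activity images;
* ``DynamicSinogramSet`` — P, (M x N) projection counts, M = n_bins * n_angles.

Columns are ordered by acquisition time (column i covers an earlier interval
than column i+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .schedule import FrameSchedule

__all__ = ["DynamicImageSet", "DynamicSinogramSet"]


@dataclass
class DynamicImageSet:
    """N frames of activity images on a fixed 2-D pixel grid."""

    X: np.ndarray                      # (n_pixels, N), nonnegative
    grid_shape: tuple[int, int]
    schedule: FrameSchedule
    label_map: Optional[np.ndarray] = None   # integer grid, same shape as the image

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        n_pix = int(np.prod(self.grid_shape))
        if self.X.ndim != 2 or self.X.shape[0] != n_pix:
            raise ValueError(
                f"X must be (n_pixels, N) with n_pixels={n_pix}, got {self.X.shape}"
            )
        if self.X.shape[1] != self.schedule.n_frames:
            raise ValueError("number of image columns must match the schedule")
        if np.any(self.X < 0):
            raise ValueError("activity images must be nonnegative")
        if self.label_map is not None:
            self.label_map = np.asarray(self.label_map)
            if self.label_map.shape != self.grid_shape:
                raise ValueError("label_map shape must match grid_shape")

    @property
    def n_frames(self) -> int:
        return self.X.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.X.shape[0]

    def frame_image(self, i: int) -> np.ndarray:
        """Frame i as a 2-D array."""
        return self.X[:, i].reshape(self.grid_shape)


@dataclass
class DynamicSinogramSet:
    """N frames of sinograms (radial bin x angle, flattened per column)."""

    P: np.ndarray                      # (M, N), nonnegative
    n_bins: int
    n_angles: int
    schedule: FrameSchedule
    provenance: str = "unknown"        # noiseless | noisy | denoised | ...
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.n_bins = int(self.n_bins)
        self.n_angles = int(self.n_angles)
        M = self.n_bins * self.n_angles
        if self.P.ndim != 2 or self.P.shape[0] != M:
            raise ValueError(f"P must be (M, N) with M={M}, got {self.P.shape}")
        if self.P.shape[1] != self.schedule.n_frames:
            raise ValueError("number of sinogram columns must match the schedule")
        if np.any(self.P < 0):
            raise ValueError("sinograms must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.P.shape[1]

    @property
    def M(self) -> int:
        return self.P.shape[0]

    @property
    def frame_totals(self) -> np.ndarray:
        """Per-frame count totals, i.e. the frame 1-norms ||p_i||_1."""
        return self.P.sum(axis=0)

    def frame_sinogram(self, i: int) -> np.ndarray:
        """Frame i as a (n_bins, n_angles) array."""
        return self.P[:, i].reshape(self.n_bins, self.n_angles)

    def with_P(self, P: np.ndarray, provenance: Optional[str] = None) -> "DynamicSinogramSet":
        """Copy of this set with a new data matrix (same geometry/schedule)."""
        return DynamicSinogramSet(
            P=P,
            n_bins=self.n_bins,
            n_angles=self.n_angles,
            schedule=self.schedule,
            provenance=self.provenance if provenance is None else provenance,
            seed=self.seed,
            meta=dict(self.meta),
        )
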