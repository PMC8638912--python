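"""Procedural brain-like label phantom and dynamic ground-truth images.

The phantom is a 2-D integer label map built from nested ellipses — an outer
CSF rim, a gray-matter shell, a white-matter core with CSF ventricles, and an
optional lesion disk embedded in the gray shell.  It provides the region
structure (gray/white/lesion) that the regional metrics need, without any
external anatomical dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import DynamicImageSet
from .kinetics import KineticParams, frame_averaged_tac
from .schedule import FrameSchedule

__all__ = ["LABELS", "LabelPhantom", "generate_phantom", "build_dynamic_images"]

LABELS = {"background": 0, "csf": 1, "gray": 2, "white": 3, "lesion": 4}
_LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass
class LabelPhantom:
    """Integer label map over a pixel grid; labels from :data:`LABELS`."""

    label_map: np.ndarray
    pixel_size: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=int)
        if self.label_map.ndim != 2:
            raise ValueError("label_map must be 2-D")
        extra = set(np.unique(self.label_map)) - set(LABELS.values())
        if extra:
            raise ValueError(f"unknown labels present: {sorted(extra)}")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def labels_present(self) -> list[str]:
        return [_LABEL_NAMES[v] for v in np.unique(self.label_map)]

    def region_mask(self, name: str) -> np.ndarray:
        """Boolean mask of one region."""
        return self.label_map == LABELS[name]


def _ellipse(yy, xx, cy, cx, sy, sx):
    return ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2 <= 1.0


def generate_phantom(
    grid_shape: tuple[int, int] = (128, 128),
    include_lesion: bool = True,
    seed: int = 0,
) -> LabelPhantom:
    """Build the ellipse phantom; deterministic for a fixed seed.

    The seed jitters the head center and picks the lesion bearing, so
    different seeds give slightly different but structurally identical
    anatomies.
    """
    H, W = (int(s) for s in grid_shape)
    if H < 32 or W < 32:
        raise ValueError("grid must be at least 32x32 to place all regions")
    rng = np.random.default_rng(seed)

    sy, sx = H / 2.0, W / 2.0
    cy = sy + rng.uniform(-0.02, 0.02) * H
    cx = sx + rng.uniform(-0.02, 0.02) * W
    yy, xx = np.mgrid[0:H, 0:W].astype(float)

    labels = np.zeros((H, W), dtype=int)
    labels[_ellipse(yy, xx, cy, cx, 0.92 * sy, 0.92 * sx)] = LABELS["csf"]
    labels[_ellipse(yy, xx, cy, cx, 0.84 * sy, 0.84 * sx)] = LABELS["gray"]
    labels[_ellipse(yy, xx, cy, cx, 0.58 * sy, 0.58 * sx)] = LABELS["white"]
    # lateral-ventricle-like CSF pockets inside white matter
    for side in (-1.0, 1.0):
        labels[
            _ellipse(yy, xx, cy - 0.05 * sy, cx + side * 0.18 * sx, 0.22 * sy, 0.08 * sx)
        ] = LABELS["csf"]

    if include_lesion:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        # mid-depth of the gray shell (between the 0.58 and 0.84 ellipses)
        f = 0.71
        ly = cy + f * sy * np.sin(theta)
        lx = cx + f * sx * np.cos(theta)
        radius = max(2.0, 0.055 * min(sy, sx))
        while radius >= 1.0:
            disk = (yy - ly) ** 2 + (xx - lx) ** 2 <= radius**2
            if disk.any() and np.all(labels[disk] == LABELS["gray"]):
                labels[disk] = LABELS["lesion"]
                break
            radius -= 0.5
        else:
            raise ValueError("grid too small to embed a lesion inside gray matter")

    return LabelPhantom(label_map=labels, seed=seed)


def build_dynamic_images(
    phantom: LabelPhantom,
    params_by_label: dict[str, KineticParams],
    input_fn,
    schedule: FrameSchedule,
) -> DynamicImageSet:
    """Paint frame-averaged tissue TACs into the phantom regions.

    Background and CSF carry zero activity; every other label present in the
    phantom must have kinetic parameters.  Each frame holds the time-average
    of C_T over its interval.
    """
    H, W = phantom.grid_shape
    N = schedule.n_frames
    X = np.zeros((H * W, N))
    flat = phantom.label_map.ravel()

    for value in np.unique(flat):
        name = _LABEL_NAMES[int(value)]
        if name in ("background", "csf"):
            continue
        if name not in params_by_label:
            raise KeyError(f"no kinetic parameters supplied for label '{name}'")
        tac = frame_averaged_tac(params_by_label[name], input_fn, schedule)
        X[flat == value, :] = tac[None, :]

    totals = X.sum(axis=0) * schedule.frame_duration
    if np.any(np.diff(totals) < -1e-9 * max(totals.max(), 1.0)):
        warnings.warn(
            "per-frame total activity (activity x duration) is not nondecreasing; "
            "the energy-ordering assumption of the graph filter may not hold",
            stacklevel=2,
        )

    return DynamicImageSet(
        X=X, grid_shape=(H, W), schedule=schedule, label_map=phantom.label_map
    )
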