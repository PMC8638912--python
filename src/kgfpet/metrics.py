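"""Evaluation metrics for denoised sinograms and reconstructed images.

``mse_db`` is a *normalised* squared error expressed in decibels,
10 log10( sum (xhat - x)^2 / sum x^2 ); the conventional name MSE is kept.
RTA is the mean absolute activity over a region of one frame; the regional
MAE averages the absolute RTA error over all frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RegionMask", "mse_db", "rta", "mae_rta", "average_over_realizations",
           "framewise_mse_db"]


@dataclass(frozen=True)
class RegionMask:
    """Named set of pixel indices on a flattened grid."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int).ravel()
        object.__setattr__(self, "indices", idx)
        if idx.size < 1:
            raise ValueError("a region must contain at least one pixel")

    @classmethod
    def from_labels(cls, label_map: np.ndarray, value: int, name: str) -> "RegionMask":
        idx = np.flatnonzero(np.asarray(label_map).ravel() == value)
        return cls(name=name, indices=idx)

    @property
    def D(self) -> int:
        return int(self.indices.size)


def mse_db(x_hat: np.ndarray, x: np.ndarray) -> float:
    """Normalised squared error in dB between one frame and its reference.

    Returns -inf when the two frames coincide exactly.
    """
    x_hat = np.asarray(x_hat, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if x_hat.shape != x.shape:
        raise ValueError("frames must have equal length")
    denom = np.sum(x**2)
    if denom <= 0:
        raise ValueError("reference frame has zero energy")
    num = np.sum((x_hat - x) ** 2)
    if num == 0:
        return -np.inf
    return float(10.0 * np.log10(num / denom))


def framewise_mse_db(X_hat: np.ndarray, X: np.ndarray) -> np.ndarray:
    """mse_db of each column (frame) of X_hat against X."""
    X_hat, X = np.asarray(X_hat, float), np.asarray(X, float)
    if X_hat.shape != X.shape:
        raise ValueError("matrices must have equal shapes")
    return np.array([mse_db(X_hat[:, j], X[:, j]) for j in range(X.shape[1])])


def rta(x_frame: np.ndarray, mask: RegionMask) -> float:
    """Regional time activity: mean absolute value over the region."""
    x = np.asarray(x_frame, dtype=float).ravel()
    if mask.indices.max() >= x.size:
        raise ValueError("region indices fall outside the frame")
    return float(np.mean(np.abs(x[mask.indices])))


def mae_rta(X_hat: np.ndarray, X: np.ndarray, mask: RegionMask) -> float:
    """Mean absolute RTA error over frames: (1/N) sum_j |RTA(xhat_j) - RTA(x_j)|."""
    X_hat, X = np.asarray(X_hat, float), np.asarray(X, float)
    if X_hat.shape != X.shape:
        raise ValueError("matrices must have equal shapes")
    errs = [
        abs(rta(X_hat[:, j], mask) - rta(X[:, j], mask)) for j in range(X.shape[1])
    ]
    return float(np.mean(errs))


def average_over_realizations(runs) -> np.ndarray:
    """Elementwise mean over noise realizations.

    ``runs`` is a sequence of equally shaped arrays (e.g. per-frame MSE(dB)
    curves, one per seed); returns their arithmetic mean — the AMSE protocol.
    """
    runs = [np.asarray(r, dtype=float) for r in runs]
    if not runs:
        raise ValueError("need at least one run")
    shape = runs[0].shape
    if any(r.shape != shape for r in runs):
        raise ValueError("all runs must have the same shape")
    return np.mean(np.stack(runs, axis=0), axis=0)


def tabulate_framewise(curves: dict[str, np.ndarray]) -> pd.DataFrame:
    """Frame-indexed table of per-method metric curves."""
    df = pd.DataFrame(curves)
    df.index = np.arange(1, len(df) + 1)
    df.index.name = "frame"
    return df
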