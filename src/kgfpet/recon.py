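"""Tomographic image reconstruction: MLEM and kernelized EM (KEM).

MLEM iterates the multiplicative Poisson EM update

    X^{n+1} = X^n * ( H^T ( P / (H X^n + S) ) ) / ( H^T 1 ),

all operations elementwise, starting from a uniform image.  KEM runs the same
update on coefficient images under a voxel-similarity kernel, X = K Lambda,
where K is built from prior (composite) images; with K = I it reduces exactly
to MLEM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .containers import DynamicImageSet, DynamicSinogramSet
from .projection import SystemModel

__all__ = [
    "ReconConfig",
    "KemKernel",
    "mlem",
    "kem",
    "kem_kernel_matrix",
    "composite_prior_images",
    "poisson_loglik",
]

_FLOOR = 1e-12


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction settings."""

    n_iter: int = 100
    method: str = "mlem"            # "mlem" | "kem"
    kem_neighbors: int = 50
    kem_sigma: float = 1.0
    floor: float = _FLOOR           # denominator guard for Hadamard division

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.floor <= 0:
            raise ValueError("floor must be positive")


@dataclass
class KemKernel:
    """Sparse voxel-similarity kernel K (row-stochastic) and its features."""

    K: sparse.csr_matrix
    features: np.ndarray            # (n_pixels, n_priors), std-normalised
    n_neighbors: int
    sigma: float


def _as_array(P_in: Union[np.ndarray, DynamicSinogramSet]) -> np.ndarray:
    arr = P_in.P if isinstance(P_in, DynamicSinogramSet) else np.asarray(P_in, float)
    if np.any(arr < 0):
        raise ValueError("input sinograms must be nonnegative")
    return arr


def _safe_div(num: np.ndarray, den: np.ndarray, floor: float) -> np.ndarray:
    out = num / np.maximum(den, floor)
    out[(num == 0) & (den < floor)] = 0.0       # 0/0 := 0
    return out


def mlem(
    P_in: Union[np.ndarray, DynamicSinogramSet],
    model: SystemModel,
    config: ReconConfig = ReconConfig(),
    S: Optional[np.ndarray] = None,
    schedule=None,
) -> tuple[Union[np.ndarray, DynamicImageSet], np.ndarray]:
    """MLEM reconstruction of all frames jointly.

    Returns the reconstructed images and the per-iteration Poisson
    log-likelihood.  Pixels with zero sensitivity are frozen at zero.
    """
    P = _as_array(P_in)
    S_arr = np.zeros_like(P) if S is None else np.broadcast_to(S, P.shape)
    sens = model.sensitivity()
    alive = sens > 0
    X = np.ones((model.geometry.n_pixels, P.shape[1]))
    X[~alive, :] = 0.0
    loglik = np.empty(config.n_iter)
    for n in range(config.n_iter):
        expect = model.forward(X) + S_arr
        loglik[n] = _loglik_from_expectation(P, expect)
        ratio = _safe_div(P, expect, config.floor)
        back = model.adjoint(ratio)
        X = X * _safe_div(back, sens[:, None], config.floor)
        X[~alive, :] = 0.0
    if isinstance(P_in, DynamicSinogramSet):
        sched = schedule if schedule is not None else P_in.schedule
        return (
            DynamicImageSet(X=X, grid_shape=model.geometry.grid_shape, schedule=sched),
            loglik,
        )
    return X, loglik


def composite_prior_images(
    P_in: Union[np.ndarray, DynamicSinogramSet],
    model: SystemModel,
    n_groups: int = 3,
    n_iter: int = 20,
    S: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Composite MLEM images from temporally rebinned sinograms.

    The frames are grouped into ``n_groups`` contiguous blocks of roughly
    equal total counts, each block is summed into one composite sinogram and
    reconstructed with a short MLEM run; the composites serve as the prior
    features for the KEM kernel.  Returns (n_pixels, n_groups).
    """
    P = _as_array(P_in)
    N = P.shape[1]
    n_groups = int(min(n_groups, N))
    totals = P.sum(axis=0)
    cum = np.cumsum(totals) / totals.sum()
    raw = np.searchsorted(cum, np.arange(1, n_groups) / n_groups, side="left") + 1
    # enforce strictly increasing edges so every group keeps >= 1 frame
    bounds = [0]
    for g, e in enumerate(raw, start=1):
        e = max(int(e), bounds[-1] + 1)
        bounds.append(min(e, N - (n_groups - g)))
    bounds.append(N)
    S_arr = np.zeros_like(P) if S is None else np.broadcast_to(S, P.shape)
    priors = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        comp = P[:, a:b].sum(axis=1, keepdims=True)
        comp_S = S_arr[:, a:b].sum(axis=1, keepdims=True)
        img, _ = mlem(comp, model, ReconConfig(n_iter=n_iter), S=comp_S)
        priors.append(img[:, 0])
    return np.column_stack(priors)


def kem_kernel_matrix(
    prior_images: np.ndarray, kem_neighbors: int = 50, kem_sigma: float = 1.0
) -> KemKernel:
    """Row-stochastic voxel-similarity kernel from composite prior images.

    Each voxel's feature vector is its value across the prior images,
    normalised by the per-image standard deviation; similarities are Gaussian
    in feature space, restricted to each voxel's ``kem_neighbors`` nearest
    voxels, and rows are normalised to sum one so K Lambda stays on the
    activity scale.  Degenerate (constant) priors fall back to K = I.
    """
    prior = np.atleast_2d(np.asarray(prior_images, dtype=float))
    if prior.ndim != 2:
        raise ValueError("prior_images must be (n_pixels, n_priors)")
    n_pix = prior.shape[0]
    stds = prior.std(axis=0)
    if np.all(stds == 0):
        warnings.warn("constant prior images; falling back to K = I", stacklevel=2)
        return KemKernel(
            K=sparse.identity(n_pix, format="csr"),
            features=np.zeros_like(prior),
            n_neighbors=1,
            sigma=kem_sigma,
        )
    feats = prior[:, stds > 0] / stds[stds > 0][None, :]
    k = int(min(kem_neighbors, n_pix))
    nn = NearestNeighbors(n_neighbors=k).fit(feats)
    dist, idx = nn.kneighbors(feats)
    w = np.exp(-(dist**2) / (2.0 * kem_sigma**2))
    w /= w.sum(axis=1, keepdims=True)
    rows = np.repeat(np.arange(n_pix), k)
    K = sparse.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n_pix, n_pix))
    return KemKernel(K=K, features=feats, n_neighbors=k, sigma=kem_sigma)


def kem(
    P_in: Union[np.ndarray, DynamicSinogramSet],
    model: SystemModel,
    kernel: KemKernel,
    config: ReconConfig = ReconConfig(),
    S: Optional[np.ndarray] = None,
    schedule=None,
) -> tuple[Union[np.ndarray, DynamicImageSet], np.ndarray]:
    """Kernelized EM: MLEM on coefficients Lambda with X = K Lambda.

    Returns X = K Lambda at the final iteration, plus the per-iteration
    Poisson log-likelihood of X.
    """
    P = _as_array(P_in)
    S_arr = np.zeros_like(P) if S is None else np.broadcast_to(S, P.shape)
    K = kernel.K
    KT = K.T.tocsr()
    sens = KT @ model.sensitivity()
    alive = sens > 0
    Lam = np.ones((model.geometry.n_pixels, P.shape[1]))
    Lam[~alive, :] = 0.0
    loglik = np.empty(config.n_iter)
    for n in range(config.n_iter):
        X = K @ Lam
        expect = model.forward(X) + S_arr
        loglik[n] = _loglik_from_expectation(P, expect)
        ratio = _safe_div(P, expect, config.floor)
        back = KT @ model.adjoint(ratio)
        Lam = Lam * _safe_div(back, sens[:, None], config.floor)
        Lam[~alive, :] = 0.0
    X = K @ Lam
    if isinstance(P_in, DynamicSinogramSet):
        sched = schedule if schedule is not None else P_in.schedule
        return (
            DynamicImageSet(X=X, grid_shape=model.geometry.grid_shape, schedule=sched),
            loglik,
        )
    return X, loglik


def _loglik_from_expectation(P: np.ndarray, expect: np.ndarray) -> float:
    if np.any((P > 0) & (expect <= 0)):
        raise ValueError("zero expectation at a bin with observed counts")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(P > 0, P * np.log(np.maximum(expect, _FLOOR)), 0.0)
    return float(np.sum(term - expect))


def poisson_loglik(
    P_in: Union[np.ndarray, DynamicSinogramSet],
    model: SystemModel,
    X: np.ndarray,
    S: Optional[np.ndarray] = None,
) -> float:
    """Poisson log-likelihood sum[P log(HX+S) - (HX+S)], dropping log(P!).

    Bins with P = 0 contribute -(HX+S); a bin with P > 0 but zero expectation
    makes the data impossible and raises.
    """
    P = _as_array(P_in)
    S_arr = np.zeros_like(P) if S is None else np.broadcast_to(S, P.shape)
    expect = model.forward(X) + S_arr
    return _loglik_from_expectation(P, expect)
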