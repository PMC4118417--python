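"""Density-invariant diffusion-map embeddings of feature clouds.

The pipeline implemented here builds a Gaussian-kernel graph over a point
cloud, removes sampling-density effects with the anisotropic (Laplace-
Beltrami) re-weighting, row-normalizes into a Markov transition matrix,
eigendecomposes it, and exposes diffusion coordinates in which plain
Euclidean distance equals the diffusion distance of the random walk.

The scale parameter t of the walk is aggregated over all scales: each
coordinate k is weighted by lam_tilde_k = sqrt(lam_k^2 / (1 - lam_k^2)),
the closed form of the geometric series sum_{t>=1} lam_k^{2t}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg
from scipy.spatial.distance import pdist, squareform


class DegenerateCloudError(ValueError):
    """All points coincide: the pairwise-distance median vanishes."""


class DisconnectedGraphError(RuntimeError):
    """A non-trivial eigenvalue is numerically 1: the kernel graph has
    (at least) two components. A larger bandwidth reconnects it."""


@dataclass(frozen=True)
class FeatureCloud:
    """n points x_i in R^d, one row per point.

    For image-derived clouds the rows are (beta*row, beta*col, channels),
    i.e. d = spatial dims + channel count.
    """

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2:
            raise ValueError("points must be a 2-D (n, d) array")
        if pts.shape[0] < 1:
            raise ValueError("a feature cloud needs at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("feature cloud contains non-finite entries")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]


@dataclass(frozen=True)
class KernelMatrix:
    """Symmetric Gaussian affinity matrix with unit diagonal."""

    W: np.ndarray
    sigma2: float


@dataclass
class DiffusionOperator:
    """Markov diffusion operator and (optionally) its eigenpairs.

    P is row-stochastic and similar to the symmetric matrix
    D^{-1/2} W_tilde D^{-1/2} (D = diag of W_tilde row sums), so its
    spectrum is real and lies in [-1, 1].

    Eigenvector normalization: psi_0 is the constant ones vector and
    phi_0 is the stationary distribution (sums to 1); with this choice
    phi_j . psi_k = delta_jk and the probability-cloud diffusion distance
    equals the spectral form exactly.
    """

    P: np.ndarray
    W_tilde: np.ndarray
    row_sums: np.ndarray  # row sums of W_tilde
    eigenvalues: Optional[np.ndarray] = None
    psi: Optional[np.ndarray] = None  # right eigenvectors, columns
    phi: Optional[np.ndarray] = None  # left eigenvectors, columns

    @property
    def n(self) -> int:
        return self.P.shape[0]

    @property
    def stationary(self) -> np.ndarray:
        """Stationary distribution phi_0 of the chain."""
        return self.row_sums / self.row_sums.sum()


@dataclass(frozen=True)
class DiffusionEmbedding:
    """All-scales diffusion coordinates: column k-1 is lam_tilde_k * psi_k.

    The trivial constant eigenvector psi_0 is excluded. `eigenvalues`
    holds lam_1..lam_l, needed for Nystrom out-of-sample extension.
    """

    coords: np.ndarray  # (n, l)
    lam_tilde: np.ndarray  # (l,)
    eigenvalues: np.ndarray  # (l,) lam_1..lam_l
    source_n: int

    @property
    def l(self) -> int:
        return self.coords.shape[1]


def median_bandwidth(cloud: FeatureCloud) -> float:
    """Median of all n(n-1)/2 squared pairwise Euclidean distances.

    The even-count median is the mean of the two middle values (numpy
    convention). Raises DegenerateCloudError when all points coincide.
    """
    if cloud.n < 2:
        raise ValueError("median bandwidth needs at least two points")
    d2 = pdist(cloud.points, metric="sqeuclidean")
    sigma2 = float(np.median(d2))
    if sigma2 <= 0.0:
        raise DegenerateCloudError(
            "all points in the cloud are identical; the kernel bandwidth "
            "is undefined"
        )
    return sigma2


def gaussian_kernel(cloud: FeatureCloud, sigma2: float) -> KernelMatrix:
    """W_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)), unit diagonal."""
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    d2 = squareform(pdist(cloud.points, metric="sqeuclidean"))
    W = np.exp(-d2 / (2.0 * sigma2))
    np.fill_diagonal(W, 1.0)
    return KernelMatrix(W=W, sigma2=float(sigma2))


def density_normalize(K: KernelMatrix) -> np.ndarray:
    """Anisotropic re-weighting w_tilde_ij = W_ij / (r_i r_j).

    r are the row sums of W. Removes the sampling-density dependence so
    the subsequent Markov chain approximates the Laplace-Beltrami
    operator of the underlying manifold.
    """
    W = K.W
    r = W.sum(axis=1)
    if np.any(r <= 0):
        raise ValueError("kernel matrix has a non-positive row sum")
    return W / np.outer(r, r)


def markov_normalize(w_tilde: np.ndarray) -> DiffusionOperator:
    """Row-normalize the re-weighted kernel into a transition matrix."""
    w_tilde = np.asarray(w_tilde, dtype=float)
    r = w_tilde.sum(axis=1)
    if np.any(r <= 0):
        raise ValueError("re-weighted kernel has a non-positive row sum")
    P = w_tilde / r[:, None]
    return DiffusionOperator(P=P, W_tilde=w_tilde, row_sums=r)


def eigendecompose(op: DiffusionOperator, n_eig: int) -> DiffusionOperator:
    """Eigenpairs of P via its symmetric conjugate.

    Works on S = D^{-1/2} W_tilde D^{-1/2}, which is symmetric and shares
    P's spectrum, then converts the orthonormal eigenvectors back to the
    biorthogonal right/left pairs of P. Eigenvalues are sorted in
    decreasing order; each psi_k's sign is fixed by making its entry of
    largest magnitude positive.
    """
    n = op.n
    if not 2 <= n_eig <= n:
        raise ValueError("n_eig must lie in [2, n]")
    d = op.row_sums
    sqrt_d = np.sqrt(d)
    S = op.W_tilde / np.outer(sqrt_d, sqrt_d)
    S = 0.5 * (S + S.T)  # enforce exact symmetry against roundoff
    try:
        if n_eig == n:
            vals, vecs = linalg.eigh(S)
        else:
            vals, vecs = linalg.eigh(S, subset_by_index=[n - n_eig, n - 1])
    except linalg.LinAlgError as exc:  # pragma: no cover - solver failure
        raise RuntimeError(f"eigendecomposition failed to converge: {exc}")
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], -1.0, 1.0)
    vecs = vecs[:, order]

    total = d.sum()
    psi = vecs / sqrt_d[:, None] * np.sqrt(total)
    phi = vecs * sqrt_d[:, None] / np.sqrt(total)
    # deterministic sign: largest-magnitude entry of each psi_k positive
    for k in range(psi.shape[1]):
        i = int(np.argmax(np.abs(psi[:, k])))
        if psi[i, k] < 0:
            psi[:, k] = -psi[:, k]
            phi[:, k] = -phi[:, k]
    op.eigenvalues = vals
    op.psi = psi
    op.phi = phi
    return op


def build_embedding(op: DiffusionOperator, l: int) -> DiffusionEmbedding:
    """All-scales diffusion coordinates from the leading eigenpairs.

    Column k-1 is lam_tilde_k psi_k with lam_tilde_k^2 =
    lam_k^2 / (1 - lam_k^2) (the sum of Dt^2 over every scale t >= 1).
    psi_0 is excluded; any |lam_k| numerically at 1 for k >= 1 signals a
    disconnected graph and is rejected rather than clipped.
    """
    if op.eigenvalues is None or op.psi is None:
        raise ValueError("operator has no eigenpairs; call eigendecompose")
    n_eig = op.eigenvalues.shape[0]
    if not 1 <= l <= n_eig - 1:
        raise ValueError("l must lie in [1, n_eig - 1]")
    lam = op.eigenvalues[1 : l + 1]
    if np.any(np.abs(lam) >= 1.0 - 1e-12):
        raise DisconnectedGraphError(
            "a non-trivial eigenvalue is numerically 1: the kernel graph "
            "is disconnected; increase the bandwidth sigma"
        )
    lam_tilde = np.abs(lam) / np.sqrt(1.0 - lam**2)
    coords = op.psi[:, 1 : l + 1] * lam_tilde[None, :]
    return DiffusionEmbedding(
        coords=coords,
        lam_tilde=lam_tilde,
        eigenvalues=lam.copy(),
        source_n=op.n,
    )


def diffusion_distance(emb: DiffusionEmbedding, i: int, j: int) -> float:
    """Euclidean distance between diffusion coordinates of points i, j."""
    return float(np.linalg.norm(emb.coords[i] - emb.coords[j]))


def build_operator_pipeline(
    cloud: FeatureCloud,
    sigma2: Optional[float] = None,
    density_invariant: bool = True,
    n_eig: Optional[int] = None,
) -> DiffusionOperator:
    """Kernel -> (density normalize) -> Markov -> eigendecompose."""
    if sigma2 is None:
        sigma2 = median_bandwidth(cloud)
    K = gaussian_kernel(cloud, sigma2)
    w = density_normalize(K) if density_invariant else K.W
    op = markov_normalize(w)
    if n_eig is None:
        n_eig = cloud.n
    return eigendecompose(op, n_eig)


def embed_cloud(
    cloud: FeatureCloud,
    l: int,
    sigma2: Optional[float] = None,
    density_invariant: bool = True,
    n_eig: Optional[int] = None,
) -> DiffusionEmbedding:
    """Convenience: full pipeline from cloud to diffusion embedding."""
    if n_eig is None:
        n_eig = min(cloud.n, l + 1)
    op = build_operator_pipeline(
        cloud, sigma2=sigma2, density_invariant=density_invariant, n_eig=n_eig
    )
    return build_embedding(op, l)
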