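"""From images to diffusion-map images.

An image is turned into a feature cloud of rows (beta*row, beta*col,
intensities), with each channel min-max rescaled to the span of the
pixel coordinates so that geometry and intensity carry comparable
weight. The diffusion embedding is computed at the coarsest level of a
Gaussian pyramid (dense eigenproblem kept desk-scale), extended to full
resolution by Nystrom kernel interpolation, optionally mapped into a
common reference space, and reshaped into an image whose pixels hold
the first l diffusion coordinates — the diffusion-map image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from . import alignment
from .spectral import (
    DiffusionEmbedding,
    FeatureCloud,
    build_embedding,
    build_operator_pipeline,
    gaussian_kernel,
    median_bandwidth,
)


@dataclass(frozen=True)
class ImageGrid:
    """H x W x m intensity grid (m >= 1 channels), spacing in mm/pixel."""

    data: np.ndarray
    spacing: float = 1.0

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValueError("image data must be H x W or H x W x m")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("image must be at least 2 x 2")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite intensities")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Knobs of the diffusion-map image construction.

    beta: spatial-locality weight on pixel coordinates (default 1, i.e.
      raw pixel coordinates next to range-matched intensities).
    l: number of retained diffusion coordinates (default 1; the leading
      coordinate captures the coarse intrinsic geometry).
    max_coarse_points: pyramid decimation stops once the pixel count is
      at or below this cap, keeping the dense eigenproblem tractable.
    pyramid_sigma: Gaussian smoothing applied before each 2x decimation.
    bandwidth_scale: factor on the median-pairwise-distance bandwidth.
      The raw median over a full image grid is dominated by the spatial
      spread of the frame and yields a nearly global kernel, in which
      the embedding degenerates toward linear (PCA-like) modes; a
      fraction of the median keeps the walk local enough to resolve the
      intensity-gap bottlenecks that carry the structure.
    """

    beta: float = 1.0
    l: int = 1
    max_coarse_points: int = 3000
    pyramid_sigma: float = 1.0
    bandwidth_scale: float = 1.0 / 64.0
    n_eig: Optional[int] = None
    #: modes of the source eigenbasis used by the change-of-basis
    #: operator. Leading eigenvalues of image graphs can be nearly
    #: degenerate, so a single mode can rotate within its eigenspace
    #: across modalities; a few extra source modes let the operator
    #: undo that rotation. Kept small: a large basis would reconstruct
    #: the reference pattern at the reference pose, erasing the very
    #: misalignment being estimated.
    n_align: int = 3

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if self.l < 1:
            raise ValueError("l must be at least 1")


@dataclass(frozen=True)
class DiffusionMapImage:
    """H x W x l image of per-pixel diffusion coordinates."""

    coords: np.ndarray
    ref_id: Optional[str] = None
    spacing: float = 1.0

    def __post_init__(self):
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValueError("coords must be H x W x l")
        object.__setattr__(self, "coords", arr)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.coords.shape[0], self.coords.shape[1]

    @property
    def l(self) -> int:
        return self.coords.shape[2]


@dataclass
class CoarseEmbeddingResult:
    """Coarse-level embedding plus everything needed downstream.

    psi holds the raw non-trivial eigenvector columns psi_1..psi_l
    (used to build change-of-basis operators); cloud/sigma2/row-sums
    feed the Nystrom extension.
    """

    embedding: DiffusionEmbedding
    psi: np.ndarray  # (n_coarse, n_modes) orthonormalized basis
    psi_norms: np.ndarray  # Euclidean norms of the raw psi columns
    cloud: FeatureCloud
    sigma2: float
    shape: Tuple[int, int]  # coarse grid shape
    levels: int  # number of 2x decimations applied


def image_to_features(img: ImageGrid, cfg: EmbeddingConfig) -> FeatureCloud:
    """One row per pixel: (beta*row, beta*col, rescaled channels).

    Each channel is linearly min-max rescaled to [0, max(H, W) - 1] so
    intensity spans match the coordinate span. A constant channel maps
    to zeros (with a warning): the graph is then driven by geometry.
    """
    H, W = img.shape
    span = float(max(H, W) - 1)
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    feats = [cfg.beta * rows.ravel(), cfg.beta * cols.ravel()]
    for ch in range(img.n_channels):
        c = img.data[:, :, ch]
        lo, hi = float(c.min()), float(c.max())
        if hi == lo:
            warnings.warn(
                f"channel {ch} is constant; rescaled to 0 (graph driven "
                "by geometry alone)",
                stacklevel=2,
            )
            feats.append(np.zeros(H * W))
        else:
            feats.append(((c - lo) / (hi - lo) * span).ravel())
    return FeatureCloud(points=np.column_stack(feats))


def _pyramid_reduce(data: np.ndarray, sigma: float) -> np.ndarray:
    sm = gaussian_filter(data, sigma=(sigma, sigma, 0.0), mode="nearest")
    return sm[::2, ::2, :]


def coarse_embedding(
    img: ImageGrid, cfg: EmbeddingConfig
) -> CoarseEmbeddingResult:
    """Diffusion embedding at the coarsest Gaussian-pyramid level.

    The image is blurred and decimated by 2 until its pixel count is at
    or below cfg.max_coarse_points, then the full spectral pipeline runs
    on the coarse feature cloud.
    """
    data = img.data
    levels = 0
    while data.shape[0] * data.shape[1] > cfg.max_coarse_points:
        nh, nw = -(-data.shape[0] // 2), -(-data.shape[1] // 2)
        if nh < 8 or nw < 8:
            raise ValueError(
                "coarse pyramid level would fall below 8 x 8; raise "
                "max_coarse_points"
            )
        data = _pyramid_reduce(data, cfg.pyramid_sigma)
        levels += 1
    coarse_img = ImageGrid(data, spacing=img.spacing * 2**levels)
    cloud = image_to_features(coarse_img, cfg)
    sigma2 = cfg.bandwidth_scale * median_bandwidth(cloud)
    n = cloud.n
    n_modes = min(max(cfg.l, cfg.n_align), n - 1)
    n_eig = cfg.n_eig if cfg.n_eig is not None else min(n, n_modes + 1)
    op = build_operator_pipeline(cloud, sigma2=sigma2, n_eig=n_eig)
    emb = build_embedding(op, min(n_modes, n_eig - 1))
    # Eigenvectors are orthogonal under the stationary-weighted inner
    # product, only approximately under the Euclidean one; the closest
    # Euclidean-orthonormal basis (Lowdin/Procrustes) makes the
    # change-of-basis operator of self-alignment exactly the identity.
    psi_cols = op.psi[:, 1 : emb.l + 1]
    norms = np.linalg.norm(psi_cols, axis=0)
    U, _, Vt = np.linalg.svd(psi_cols / norms[None, :], full_matrices=False)
    return CoarseEmbeddingResult(
        embedding=emb,
        psi=U @ Vt,
        psi_norms=norms,
        cloud=cloud,
        sigma2=sigma2,
        shape=coarse_img.shape,
        levels=levels,
    )


def extend_embedding(
    coarse: DiffusionEmbedding,
    coarse_cloud: FeatureCloud,
    fine_cloud: FeatureCloud,
    sigma2: float,
) -> np.ndarray:
    """Nystrom out-of-sample extension of diffusion coordinates.

    Builds the same density-normalized, row-stochastic kernel rows for
    the fine points against the coarse samples and applies the Nystrom
    rule psi_k(y) = (1/lam_k) sum_i p(y, x_i) psi_k(x_i), which makes
    the extension exact at points coinciding with coarse samples. Fine
    points whose total kernel weight underflows inherit the coordinates
    of their nearest coarse sample (with a warning).
    """
    if coarse_cloud.n != coarse.source_n:
        raise ValueError("coarse cloud does not match the embedding")
    if coarse_cloud.n == 1:
        return np.tile(coarse.coords[0], (fine_cloud.n, 1))
    d2 = cdist(fine_cloud.points, coarse_cloud.points, metric="sqeuclidean")
    Wfc = np.exp(-d2 / (2.0 * sigma2))
    r_coarse = gaussian_kernel(coarse_cloud, sigma2).W.sum(axis=1)
    r_fine = Wfc.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        wt = Wfc / (r_fine[:, None] * r_coarse[None, :])
        row_tot = wt.sum(axis=1)
        P = wt / row_tot[:, None]
    lam = coarse.eigenvalues
    lam_safe = np.where(np.abs(lam) > 1e-300, lam, 1.0)
    out = (P @ coarse.coords) / lam_safe[None, :]
    bad = ~np.all(np.isfinite(out), axis=1) | (r_fine <= 0) | (row_tot <= 0)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} fine points had vanishing kernel weight; "
            "assigned nearest coarse sample's coordinates",
            stacklevel=2,
        )
        nn = np.argmin(d2[bad], axis=1)
        out[bad] = coarse.coords[nn]
    return out


def _fine_cloud_in_coarse_frame(
    img: ImageGrid, cfg: EmbeddingConfig, coarse_shape: Tuple[int, int], levels: int
) -> FeatureCloud:
    """Full-resolution feature cloud expressed in coarse-grid units.

    Fine pixel (r, c) sits at coarse position (r, c) / 2^levels (the
    decimation keeps even-index samples), and intensities are rescaled
    to the coarse coordinate span so fine and coarse features live on
    the same scale.
    """
    H, W = img.shape
    scale = float(2**levels)
    span = float(max(coarse_shape) - 1)
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    feats = [cfg.beta * rows.ravel() / scale, cfg.beta * cols.ravel() / scale]
    for ch in range(img.n_channels):
        c = img.data[:, :, ch]
        lo, hi = float(c.min()), float(c.max())
        if hi == lo:
            feats.append(np.zeros(H * W))
        else:
            feats.append(((c - lo) / (hi - lo) * span).ravel())
    return FeatureCloud(points=np.column_stack(feats))


def build_diffusion_map_image(
    img: ImageGrid,
    cfg: EmbeddingConfig,
    ref: Optional[CoarseEmbeddingResult] = None,
    coarse: Optional[CoarseEmbeddingResult] = None,
    ref_id: Optional[str] = None,
) -> DiffusionMapImage:
    """Assemble the H x W x l diffusion-map image of `img`.

    Pipeline: coarse embedding -> Nystrom extension to full resolution
    -> (if `ref` is given) change-of-basis mapping into the reference
    embedding's Euclidean space. The basis-change operator is built at
    the coarse level, where both embeddings share the same pixel grid.
    """
    if coarse is None:
        coarse = coarse_embedding(img, cfg)
    if ref is not None and ref.shape != coarse.shape:
        raise ValueError(
            f"reference coarse grid {ref.shape} does not match this "
            f"image's coarse grid {coarse.shape}"
        )
    fine_cloud = _fine_cloud_in_coarse_frame(img, cfg, coarse.shape, coarse.levels)
    ext = extend_embedding(coarse.embedding, coarse.cloud, fine_cloud, coarse.sigma2)
    if ref is not None:
        # Reconstruct the reference's first l coordinate patterns in the
        # source eigenbasis: channel k is
        # lam_tilde_k^ref * sum_j <psi_k^ref, psi_j^src> psi_j^src(u),
        # with unit-normalized basis functions, so both sides of a
        # registration carry the reference's spectral amplitudes.
        op = alignment.build_operator(ref.psi[:, : cfg.l], coarse.psi)
        src_scale = coarse.embedding.lam_tilde * coarse.psi_norms
        src_scale = np.where(src_scale > 1e-300, src_scale, 1.0)
        unit_basis_ext = ext / src_scale[None, :]
        ext = alignment.apply_operator(op, unit_basis_ext) * (
            ref.embedding.lam_tilde[: cfg.l] * ref.psi_norms[: cfg.l]
        )[None, :]
    else:
        ext = ext[:, : cfg.l]
    H, W = img.shape
    return DiffusionMapImage(
        coords=ext.reshape(H, W, -1), ref_id=ref_id, spacing=img.spacing
    )
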