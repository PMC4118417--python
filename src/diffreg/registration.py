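"""Rigid and B-spline FFD registration with SSD and MI dissimilarities.

The registration itself is modality-agnostic plumbing: it minimizes a
dissimilarity between a fixed and a warped moving image over transform
parameters. The method of this package consists of feeding it
diffusion-map images (where plain squared-Euclidean distance is, up to
extension accuracy, the diffusion distance between the underlying
feature clouds); mutual information and raw-intensity L2 act as
baselines.

Optimization is quasi-Newton (L-BFGS-B) with analytic gradients over a
multi-resolution pyramid. For MI the optimizer minimizes a linear-kernel
(partial-volume) soft-histogram estimate, the differentiable counterpart
of the hard-binned `mi_cost`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import minimize

from .embedding import DiffusionMapImage, ImageGrid

ImageLike = Union[np.ndarray, ImageGrid, DiffusionMapImage]


# ---------------------------------------------------------------------------
# transforms


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees, about `center`) plus translation, in pixels.

    Maps a point u (row, col) to R(u - center) + center + t. Composable
    and exactly invertible.
    """

    theta: float
    t: Tuple[float, float] = (0.0, 0.0)
    center: Tuple[float, float] = (0.0, 0.0)

    def _matrix(self) -> np.ndarray:
        a = np.deg2rad(self.theta)
        return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        c = np.asarray(self.center)
        return (pts - c) @ self._matrix().T + c + np.asarray(self.t)

    def inverse(self) -> "RigidTransform":
        Rinv = RigidTransform(-self.theta, (0, 0), self.center)._matrix()
        t = -Rinv @ np.asarray(self.t)
        return RigidTransform(-self.theta, (float(t[0]), float(t[1])), self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: first apply `other`, then `self` (same center)."""
        R1 = self._matrix()
        t = R1 @ np.asarray(other.t) + np.asarray(self.t)
        return RigidTransform(
            self.theta + other.theta, (float(t[0]), float(t[1])), self.center
        )

    @property
    def is_identity(self) -> bool:
        return self.theta == 0.0 and self.t[0] == 0.0 and self.t[1] == 0.0


def _bspline_basis(u: np.ndarray) -> np.ndarray:
    """The four uniform cubic B-spline basis values at fraction u."""
    u2, u3 = u * u, u * u * u
    return np.stack(
        [
            (1 - u) ** 3 / 6.0,
            (3 * u3 - 6 * u2 + 4) / 6.0,
            (-3 * u3 + 3 * u2 + 3 * u + 1) / 6.0,
            u3 / 6.0,
        ],
        axis=-1,
    )


def _n_ctrl(extent: int, spacing: float) -> int:
    """Control points covering [0, extent-1] with one-knot margins."""
    return int(np.floor((extent - 1) / spacing)) + 4


def _bspline_weights(positions: np.ndarray, spacing: float, n_ctrl: int) -> np.ndarray:
    """Dense (len(positions), n_ctrl) cubic B-spline weight matrix.

    Control point with array index a sits at position (a - 1) * spacing;
    each position is supported by 4 consecutive control points.
    """
    t = np.asarray(positions, dtype=float) / spacing
    i0 = np.floor(t).astype(int)
    i0 = np.clip(i0, 0, n_ctrl - 4)
    B = _bspline_basis(t - i0)
    W = np.zeros((len(t), n_ctrl))
    rows = np.repeat(np.arange(len(t)), 4)
    cols = (i0[:, None] + np.arange(4)[None, :]).ravel()
    np.add.at(W, (rows, cols), B.ravel())
    return W


@dataclass(frozen=True)
class FFDTransform:
    """Cubic B-spline free-form deformation on a control-point lattice.

    `ctrl` has shape (Nr, Nc, 2): per-control-point displacement in
    pixels (row, col), with `spacing` pixels between control points on
    an image of shape `shape`. A zero lattice is the identity map.
    """

    ctrl: np.ndarray
    spacing: float
    shape: Tuple[int, int]

    def __post_init__(self):
        arr = np.asarray(self.ctrl, dtype=float)
        H, W = self.shape
        nr, nc = _n_ctrl(H, self.spacing), _n_ctrl(W, self.spacing)
        if arr.shape != (nr, nc, 2):
            raise ValueError(
                f"control grid shape {arr.shape} does not match the "
                f"expected ({nr}, {nc}, 2) for shape {self.shape} and "
                f"spacing {self.spacing}"
            )
        object.__setattr__(self, "ctrl", arr)

    def dense_field(self) -> np.ndarray:
        """H x W x 2 displacement field interpolated from the lattice."""
        H, W = self.shape
        Wr = _bspline_weights(np.arange(H), self.spacing, self.ctrl.shape[0])
        Wc = _bspline_weights(np.arange(W), self.spacing, self.ctrl.shape[1])
        dr = Wr @ self.ctrl[:, :, 0] @ Wc.T
        dc = Wr @ self.ctrl[:, :, 1] @ Wc.T
        return np.stack([dr, dc], axis=-1)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        Wr = _bspline_weights(pts[:, 0], self.spacing, self.ctrl.shape[0])
        Wc = _bspline_weights(pts[:, 1], self.spacing, self.ctrl.shape[1])
        dr = np.einsum("pi,ij,pj->p", Wr, self.ctrl[:, :, 0], Wc)
        dc = np.einsum("pi,ij,pj->p", Wr, self.ctrl[:, :, 1], Wc)
        return pts + np.stack([dr, dc], axis=-1)

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.ctrl == 0.0))


Transform = Union[RigidTransform, FFDTransform]


@dataclass
class RegistrationResult:
    transform: Transform
    final_cost: float
    cost_trace: List[float]
    converged: bool
    error_vs_truth: Optional[dict] = None


# ---------------------------------------------------------------------------
# warping and costs


def _as_array(img: ImageLike) -> np.ndarray:
    if isinstance(img, ImageGrid):
        arr = img.data
    elif isinstance(img, DiffusionMapImage):
        arr = img.coords
    else:
        arr = np.asarray(img, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
    return arr


def _rebuild_like(img: ImageLike, arr: np.ndarray) -> ImageLike:
    if isinstance(img, ImageGrid):
        return ImageGrid(arr, spacing=img.spacing)
    if isinstance(img, DiffusionMapImage):
        return DiffusionMapImage(arr, ref_id=img.ref_id, spacing=img.spacing)
    out = arr
    if np.asarray(img).ndim == 2:
        out = arr[:, :, 0]
    return out


def _sample_channels(arr: np.ndarray, xr: np.ndarray, xc: np.ndarray,
                     cval: float = 0.0, mode: str = "constant") -> np.ndarray:
    out = np.empty(xr.shape + (arr.shape[2],))
    for ch in range(arr.shape[2]):
        out[..., ch] = map_coordinates(
            arr[:, :, ch], [xr, xc], order=1, mode=mode, cval=cval
        )
    return out


def warp(
    img: ImageLike,
    transform: Union[Transform, np.ndarray],
    cval: float = 0.0,
) -> Tuple[ImageLike, np.ndarray]:
    """Resample `img` through `transform`: output(u) = img(T(u)).

    `transform` may also be a dense H x W x 2 displacement field D, in
    which case T(u) = u + D(u). Returns (warped, validity_mask) where
    the mask flags pixels whose source location fell inside the domain.
    An identity transform returns the input unchanged.
    """
    arr = _as_array(img)
    H, W = arr.shape[:2]
    if isinstance(transform, (RigidTransform, FFDTransform)) and transform.is_identity:
        return img, np.ones((H, W), dtype=bool)
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    if isinstance(transform, np.ndarray):
        D = np.asarray(transform, dtype=float)
        if D.shape != (H, W, 2):
            raise ValueError("dense displacement field must be H x W x 2")
        xr, xc = rows + D[:, :, 0], cols + D[:, :, 1]
    elif isinstance(transform, FFDTransform):
        D = transform.dense_field()
        xr, xc = rows + D[:, :, 0], cols + D[:, :, 1]
    else:
        pts = transform.apply(np.column_stack([rows.ravel(), cols.ravel()]))
        xr = pts[:, 0].reshape(H, W)
        xc = pts[:, 1].reshape(H, W)
    mask = (xr >= 0) & (xr <= H - 1) & (xc >= 0) & (xc <= W - 1)
    warped = _sample_channels(arr, xr, xc, cval=cval)
    return _rebuild_like(img, warped), mask


def l2_cost(A: ImageLike, B: ImageLike, mask: Optional[np.ndarray] = None) -> float:
    """Mean (over valid pixels) squared Euclidean per-pixel difference."""
    a, b = _as_array(A), _as_array(B)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if mask is None:
        mask = np.ones(a.shape[:2], dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: no valid pixels to compare")
    diff2 = ((a - b) ** 2).sum(axis=2)
    return float(diff2[mask].sum() / n)


def mi_cost(
    A: ImageLike, B: ImageLike, bins: int = 32, mask: Optional[np.ndarray] = None
) -> float:
    """Negated mutual information from the joint intensity histogram.

    Hard-binned `bins` x `bins` histogram; MI in nats. Negated so that
    minimization points the same way as `l2_cost`.
    """
    a, b = _as_array(A), _as_array(B)
    if a.shape[2] != 1 or b.shape[2] != 1:
        raise ValueError("mi_cost expects single-channel images")
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if bins < 2:
        raise ValueError("bins must be at least 2")
    if mask is None:
        mask = np.ones(a.shape[:2], dtype=bool)
    if int(mask.sum()) == 0:
        raise ValueError("empty mask: no valid pixels to compare")
    av, bv = a[:, :, 0][mask], b[:, :, 0][mask]
    H, _, _ = np.histogram2d(av, bv, bins=bins)
    p = H / H.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float((p[nz] * np.log(p[nz] / (pa @ pb)[nz])).sum())
    return -mi


# ---------------------------------------------------------------------------
# differentiable objectives


def _ssd_pixelgrad(
    fixed: np.ndarray, warped: np.ndarray, w: np.ndarray
) -> Tuple[float, np.ndarray]:
    # normalized by the fixed image's variance so the objective is O(1)
    # regardless of the intensity scale (diffusion coordinates are small)
    n = float(w.sum())
    var = float(fixed.var(axis=(0, 1)).sum())
    scale = 1.0 / max(var, 1e-300)
    diff = (warped - fixed) * w[:, :, None]
    cost = float(((warped - fixed) * diff).sum() / n) * scale
    return cost, 2.0 * scale * diff / n


def _parzen_mi_pixelgrad(
    fixed: np.ndarray,
    warped: np.ndarray,
    w: np.ndarray,
    bins: int,
    frange: Tuple[float, float],
    mrange: Tuple[float, float],
) -> Tuple[float, np.ndarray]:
    """Negated soft-histogram MI and its derivative w.r.t. warped values.

    Linear (triangle) kernels on both axes; each sample spreads its
    overlap weight over a 2 x 2 block of the joint histogram, making
    the estimate piecewise differentiable in the warped intensities.
    """
    sel = w > 0
    f = fixed[:, :, 0][sel]
    m = warped[:, :, 0][sel]
    ws = w[sel]
    flo, fhi = frange
    mlo, mhi = mrange
    fs = (bins - 1) / max(fhi - flo, 1e-12)
    ms = (bins - 1) / max(mhi - mlo, 1e-12)
    eps = 1e-9
    a = np.clip((f - flo) * fs, 0.0, bins - 1 - eps)
    b_raw = (m - mlo) * ms
    b = np.clip(b_raw, 0.0, bins - 1 - eps)
    a0 = np.floor(a).astype(int)
    b0 = np.floor(b).astype(int)
    wa, wb = a - a0, b - b0
    N = float(ws.sum())
    H = np.zeros((bins, bins))
    np.add.at(H, (a0, b0), ws * (1 - wa) * (1 - wb))
    np.add.at(H, (a0, b0 + 1), ws * (1 - wa) * wb)
    np.add.at(H, (a0 + 1, b0), ws * wa * (1 - wb))
    np.add.at(H, (a0 + 1, b0 + 1), ws * wa * wb)
    p = H / N
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.log(p / (pa * pb))
    L[~np.isfinite(L)] = 0.0
    mi = float((p * L).sum())
    # d(mi)/d(b-coordinate of sample)
    dmi_db = ws * (
        (1 - wa) * (L[a0, b0 + 1] - L[a0, b0])
        + wa * (L[a0 + 1, b0 + 1] - L[a0 + 1, b0])
    ) / N
    dmi_db[(b_raw <= 0.0) | (b_raw >= bins - 1 - eps)] = 0.0
    grad = np.zeros_like(warped)
    gflat = np.zeros(w.shape)
    gflat[sel] = -dmi_db * ms  # cost = -MI
    grad[:, :, 0] = gflat
    return -mi, grad


@dataclass
class RegistrationOptions:
    """Optimizer settings shared by rigid and FFD registration."""

    n_levels: int = 3
    maxiter: int = 200
    bins: int = 32
    multistart: bool = True
    multistart_step: float = 8.0
    ffd_spacing: float = 4.0
    ffd_refine: int = 4  # control-grid levels: spacing * 2**(k) coarsening
    #: light bending-energy penalty on the control lattice; without it
    #: the lattice can fold wildly in texture-poor regions where the
    #: dissimilarity is flat
    bending_weight: float = 3e-4
    init: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: rigid capture-range bounds boxing the search
    max_rotation: float = 30.0
    max_translation: Optional[float] = None  # default: 25% of image extent


def _pyramid(arr: np.ndarray, n_levels: int) -> List[np.ndarray]:
    """Level 0 = full resolution; each level blurred and decimated 2x."""
    out = [arr]
    for _ in range(n_levels - 1):
        prev = out[-1]
        if min(prev.shape[0], prev.shape[1]) < 16:
            break
        sm = gaussian_filter(prev, sigma=(1.0, 1.0, 0.0), mode="nearest")
        out.append(sm[::2, ::2, :])
    return out


def _pixel_cost(
    kind: str,
    fixed: np.ndarray,
    warped: np.ndarray,
    w: np.ndarray,
    bins: int,
    frange: Tuple[float, float],
    mrange: Tuple[float, float],
) -> Tuple[float, np.ndarray]:
    if kind == "mi":
        return _parzen_mi_pixelgrad(fixed, warped, w, bins, frange, mrange)
    return _ssd_pixelgrad(fixed, warped, w)


def _grad_images(arr: np.ndarray) -> np.ndarray:
    """Per-channel spatial gradients, shape (H, W, m, 2)."""
    g = np.empty(arr.shape + (2,))
    for ch in range(arr.shape[2]):
        g[:, :, ch, 0], g[:, :, ch, 1] = np.gradient(arr[:, :, ch])
    return g


def _check_cost_inputs(kind: str, fixed: np.ndarray, moving: np.ndarray) -> None:
    if kind not in ("diffusion", "l2", "mi"):
        raise ValueError(f"unknown cost '{kind}'")
    if kind == "mi" and (fixed.shape[2] != 1 or moving.shape[2] != 1):
        raise ValueError("MI registration expects single-channel images")


def register_rigid(
    fixed: ImageLike,
    moving: ImageLike,
    cost: str = "diffusion",
    opts: Optional[RegistrationOptions] = None,
) -> RegistrationResult:
    """Recover the rigid transform minimizing cost(fixed, moving o T).

    Multi-resolution L-BFGS-B over (theta, t_row, t_col) with analytic
    gradients; at the coarsest level a small deterministic grid of
    starting points widens the capture range. For cost='diffusion' the
    inputs are expected to be diffusion-map images sharing a reference
    space; the objective is then SSD, i.e. squared diffusion distance.
    """
    opts = opts or RegistrationOptions()
    farr, marr = _as_array(fixed), _as_array(moving)
    _check_cost_inputs(cost, farr, marr)
    fpyr, mpyr = _pyramid(farr, opts.n_levels), _pyramid(marr, opts.n_levels)
    n_levels = min(len(fpyr), len(mpyr))
    Hf, Wf = farr.shape[:2]
    center = np.array([(Hf - 1) / 2.0, (Wf - 1) / 2.0])
    theta = float(opts.init[0])
    t = np.array(opts.init[1:], dtype=float)
    trace: List[float] = []
    converged = True
    final_cost = np.inf

    for L in reversed(range(n_levels)):
        fl, ml = fpyr[L], mpyr[L]
        f = 2.0**L
        ctr = center / f
        mg = _grad_images(ml)
        frange = (float(fl.min()), float(fl.max()))
        mrange = (float(ml.min()), float(ml.max()))
        Hl, Wl = fl.shape[:2]
        rows, cols = np.mgrid[0:Hl, 0:Wl].astype(float)
        pr, pc = rows - ctr[0], cols - ctr[1]

        def obj(p: np.ndarray) -> Tuple[float, np.ndarray]:
            th, tr, tc = p
            rad = np.deg2rad(th)
            cth, sth = np.cos(rad), np.sin(rad)
            xr = cth * pr - sth * pc + ctr[0] + tr
            xc = sth * pr + cth * pc + ctr[1] + tc
            # clamped sampling: out-of-domain locations take the border
            # (background) value, keeping the objective smooth in the
            # parameters with no artificial boundary mismatch
            w = np.ones((Hl, Wl))
            warped = _sample_channels(ml, xr, xc, mode="nearest")
            c, dCdW = _pixel_cost(cost, fl, warped, w, opts.bins, frange, mrange)
            gr = np.zeros((Hl, Wl))
            gc = np.zeros((Hl, Wl))
            for ch in range(ml.shape[2]):
                ggr = map_coordinates(mg[:, :, ch, 0], [xr, xc], order=1, mode="nearest")
                ggc = map_coordinates(mg[:, :, ch, 1], [xr, xc], order=1, mode="nearest")
                gr += dCdW[:, :, ch] * ggr
                gc += dCdW[:, :, ch] * ggc
            dxr_dth = (-sth * pr - cth * pc) * np.pi / 180.0
            dxc_dth = (cth * pr - sth * pc) * np.pi / 180.0
            g = np.array(
                [(gr * dxr_dth + gc * dxc_dth).sum(), gr.sum(), gc.sum()]
            )
            return c, g

        t_max = opts.max_translation
        if t_max is None:
            t_max = 0.25 * max(Hf, Wf)
        bounds = [
            (-opts.max_rotation, opts.max_rotation),
            (-t_max / f, t_max / f),
            (-t_max / f, t_max / f),
        ]
        clip = lambda p: np.clip(p, [b[0] for b in bounds], [b[1] for b in bounds])
        p0 = clip(np.array([theta, t[0] / f, t[1] / f]))
        if L == n_levels - 1 and opts.multistart:
            s = opts.multistart_step
            best, best_c = p0, obj(p0)[0]
            for dth in (-s, 0.0, s):
                for dr in (-s, 0.0, s):
                    for dc in (-s, 0.0, s):
                        cand = clip(p0 + np.array([dth, dr / f, dc / f]))
                        cc = obj(cand)[0]
                        if cc < best_c:
                            best, best_c = cand, cc
            p0 = best
        if opts.multistart:
            # rotation landscapes of near-isotropic structures are long
            # flat valleys; a 1-D sweep seeds the quasi-Newton step in
            # the right basin
            best, best_c = p0, obj(p0)[0]
            for th in np.arange(-12.0, 12.5, 1.0):
                cand = clip(np.array([p0[0] + th, p0[1], p0[2]]))
                cc = obj(cand)[0]
                if cc < best_c:
                    best, best_c = cand, cc
            p0 = best

        level_trace: List[float] = []

        def cb(xk: np.ndarray) -> None:
            level_trace.append(obj(xk)[0])

        res = minimize(
            obj,
            p0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            callback=cb,
            options={"maxiter": opts.maxiter, "ftol": 1e-14, "gtol": 1e-10},
        )
        theta = float(res.x[0])
        t = res.x[1:] * f
        final_cost = float(res.fun)
        converged = bool(res.success) or res.status == 1
        if L == 0:
            trace = list(np.minimum.accumulate([obj(p0)[0]] + level_trace))

    transform = RigidTransform(theta, (float(t[0]), float(t[1])),
                               (float(center[0]), float(center[1])))
    return RegistrationResult(
        transform=transform,
        final_cost=final_cost,
        cost_trace=trace,
        converged=converged,
    )


def register_ffd(
    fixed: ImageLike,
    moving: ImageLike,
    cost: str = "diffusion",
    opts: Optional[RegistrationOptions] = None,
) -> RegistrationResult:
    """B-spline FFD registration by coarse-to-fine lattice refinement.

    The control-point spacing halves at each refinement down to
    opts.ffd_spacing (default 4 px) while the image resolution rises
    through the pyramid; the coarse lattice propagates smooth large-
    scale displacement into texture-poor regions before the fine
    lattice sharpens boundaries. Gradients of the SSD / soft-MI cost
    with respect to control displacements are analytic (adjoint of the
    separable B-spline interpolation).
    """
    opts = opts or RegistrationOptions()
    farr, marr = _as_array(fixed), _as_array(moving)
    _check_cost_inputs(cost, farr, marr)
    H, W = farr.shape[:2]
    n_ref = opts.ffd_refine
    fpyr, mpyr = _pyramid(farr, n_ref), _pyramid(marr, n_ref)
    n_levels = min(len(fpyr), len(mpyr), n_ref)
    # schedule coarsest -> finest: (pyramid level, spacing in fine px)
    schedule = [
        (min(k, n_levels - 1), opts.ffd_spacing * 2**k)
        for k in reversed(range(n_ref))
    ]

    ctrl: Optional[np.ndarray] = None
    prev_transform: Optional[FFDTransform] = None
    trace: List[float] = []
    converged = True
    final_cost = np.inf

    for L, sp in schedule:
        fl, ml = fpyr[L], mpyr[L]
        f = 2.0**L
        nr, nc = _n_ctrl(H, sp), _n_ctrl(W, sp)
        if prev_transform is None:
            ctrl = np.zeros((nr, nc, 2))
        else:
            # initialize the refined lattice from the previous field
            kr = np.clip((np.arange(nr) - 1) * sp, 0, H - 1)
            kc = np.clip((np.arange(nc) - 1) * sp, 0, W - 1)
            KR, KC = np.meshgrid(kr, kc, indexing="ij")
            pts = np.column_stack([KR.ravel(), KC.ravel()])
            disp = prev_transform.apply(pts) - pts
            ctrl = disp.reshape(nr, nc, 2)
        mg = _grad_images(ml)
        frange = (float(fl.min()), float(fl.max()))
        mrange = (float(ml.min()), float(ml.max()))
        Hl, Wl = fl.shape[:2]
        rows, cols = np.mgrid[0:Hl, 0:Wl].astype(float)
        Wr = _bspline_weights(np.arange(Hl) * f, sp, nr)
        Wc = _bspline_weights(np.arange(Wl) * f, sp, nc)

        def obj(cflat: np.ndarray) -> Tuple[float, np.ndarray]:
            C = cflat.reshape(nr, nc, 2)
            dr = (Wr @ C[:, :, 0] @ Wc.T) / f
            dc = (Wr @ C[:, :, 1] @ Wc.T) / f
            xr, xc = rows + dr, cols + dc
            w = np.ones((Hl, Wl))
            warped = _sample_channels(ml, xr, xc, mode="nearest")
            c, dCdW = _pixel_cost(cost, fl, warped, w, opts.bins, frange, mrange)
            Gr = np.zeros((Hl, Wl))
            Gc = np.zeros((Hl, Wl))
            for ch in range(ml.shape[2]):
                Gr += dCdW[:, :, ch] * map_coordinates(
                    mg[:, :, ch, 0], [xr, xc], order=1, mode="nearest"
                )
                Gc += dCdW[:, :, ch] * map_coordinates(
                    mg[:, :, ch, 1], [xr, xc], order=1, mode="nearest"
                )
            g = np.empty_like(C)
            g[:, :, 0] = Wr.T @ Gr @ Wc / f
            g[:, :, 1] = Wr.T @ Gc @ Wc / f
            if opts.bending_weight > 0.0:
                for d in range(2):
                    lap = np.zeros((nr, nc))
                    lap[1:-1, :] += np.diff(C[:, :, d], 2, axis=0)
                    lap[:, 1:-1] += np.diff(C[:, :, d], 2, axis=1)
                    c += opts.bending_weight * float((lap**2).sum())
                    g[:, :, d] += opts.bending_weight * 2.0 * _bilap(lap)
            return c, g.ravel()

        level_trace: List[float] = []

        def cb(xk: np.ndarray) -> None:
            level_trace.append(obj(xk)[0])

        res = minimize(
            obj,
            ctrl.ravel(),
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": opts.maxiter, "ftol": 1e-14, "gtol": 1e-10},
        )
        ctrl = res.x.reshape(nr, nc, 2)
        prev_transform = FFDTransform(ctrl, sp, (H, W))
        final_cost = float(res.fun)
        converged = bool(res.success) or res.status == 1
        if sp == opts.ffd_spacing:
            trace = list(
                np.minimum.accumulate([obj(res.x)[0] if not level_trace else
                                       level_trace[0]] + level_trace)
            )

    return RegistrationResult(
        transform=prev_transform,
        final_cost=final_cost,
        cost_trace=trace,
        converged=converged,
    )


def _bilap(lap: np.ndarray) -> np.ndarray:
    """Adjoint of the discrete Laplacian used by the bending penalty."""
    out = np.zeros_like(lap)
    out[:-2, :] += lap[1:-1, :]
    out[1:-1, :] += -2.0 * lap[1:-1, :]
    out[2:, :] += lap[1:-1, :]
    out[:, :-2] += lap[:, 1:-1]
    out[:, 1:-1] += -2.0 * lap[:, 1:-1]
    out[:, 2:] += lap[:, 1:-1]
    return out


# ---------------------------------------------------------------------------
# error metrics


def rigid_error(
    est: RigidTransform, truth: RigidTransform, spacing: float = 1.0
) -> Tuple[float, float, float]:
    """(rotation error deg, translation error mm, combined).

    The combined value treats a 1-mm translation error as equal to a
    1-degree rotation error: sqrt(r^2 + t^2) in those units.
    """
    r = abs(est.theta - truth.theta)
    t = float(np.linalg.norm(np.asarray(est.t) - np.asarray(truth.t))) * spacing
    return r, t, float(np.hypot(r, t))


def field_error(
    est: Union[FFDTransform, np.ndarray],
    truth: np.ndarray,
    spacing: float = 1.0,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Mean Euclidean norm of the displacement difference, in mm."""
    est_field = est.dense_field() if isinstance(est, FFDTransform) else np.asarray(est)
    truth = np.asarray(truth, dtype=float)
    if est_field.shape != truth.shape:
        raise ValueError("displacement fields must share a shape")
    norms = np.linalg.norm(est_field - truth, axis=-1)
    if mask is not None:
        norms = norms[mask]
    return float(norms.mean() * spacing)
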