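"""Co-registered multimodal phantoms with ground-truth deformations.

The generator emulates the evaluation regime of simulated multimodal MR
acquisitions: one shared piecewise-constant "anatomy" of smooth blob
regions, rendered through per-modality intensity transfer functions
(monotone or non-monotone), corrupted by a smooth multiplicative bias
field (~20% intensity non-uniformity) and additive Gaussian noise (~3%
of the intensity range). Ground-truth misalignments are random rigid
transforms and smooth random deformations built from Gaussian radial
basis functions with a bounded maximum displacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .embedding import ImageGrid
from .registration import RigidTransform

# Tissue base values live in [TISSUE_LO, TISSUE_HI]; the background is
# 0. The background-tissue gap dominates every internal contrast so the
# leading diffusion mode (the slowest bottleneck of the random walk) is
# the anatomy-vs-background structure in every modality — as in MR,
# where air is far darker than any tissue in every weighting.
TISSUE_LO, TISSUE_HI = 0.55, 0.95
_BAND = TISSUE_HI - TISSUE_LO


def _tissue_frac(v):
    """Map tissue base values onto [0, 1]; background maps to 0."""
    return np.clip((np.asarray(v, dtype=float) - TISSUE_LO) / _BAND, 0.0, 1.0)


def _t2_like(v):
    # fold the tissue intensity ordering (asymmetric parabola) into a
    # compressed, dimmer band, the way T2 folds and rescales tissue
    # contrast relative to T1 while air stays dark. The fold maps some
    # tissue classes onto nearly the same intensity (class merging, as
    # T2 does to gray/white matter) — the regime in which raw-intensity
    # L2 registration breaks down.
    # the 1.8x gain emulates the unrelated raw intensity scales of
    # different acquisitions; the embedding and MI are scale-invariant,
    # raw L2 is not
    v = np.asarray(v, dtype=float)
    f = 1.0 - ((_tissue_frac(v) - 0.35) / 0.65) ** 2
    return 1.8 * np.where(v > 0.3, 0.40 + 0.30 * f, v)


def _pd_like(v):
    # non-monotone permutation of the tissue ordering (sawtooth) into a
    # compressed band, keeping every pair of tissue classes separated
    # by at least a third of the band — contrast is scrambled but no
    # classes merge, as in proton-density weighting
    v = np.asarray(v, dtype=float)
    return np.where(
        v > 0.3, 0.40 + 0.30 * np.mod(2.0 * _tissue_frac(v), 1.0 + 1e-9), v
    )


def _inverse(v):
    # reverse the tissue ordering inside the band; background stays dark
    v = np.asarray(v, dtype=float)
    return np.where(v > 0.3, TISSUE_LO + _BAND * (1.0 - _tissue_frac(v)), v)


# Per-modality transfer functions on the base value scale [0, 1]. All of
# them keep the dominant foreground/background contrast (air is dark in
# every MR weighting) but reorder the tissue intensities — monotonically
# ("identity", "gamma"), by reversal ("inverse") or non-monotonically
# ("t2_like", "pd_like"). "nonmonotone" is an alias of the class-merging
# T2-like fold.
MODALITY_MAPS: dict = {
    "identity": lambda v: np.asarray(v, dtype=float),
    "inverse": _inverse,
    "gamma": lambda v: np.asarray(v, dtype=float) ** 0.4,
    "t2_like": _t2_like,
    "pd_like": _pd_like,
    "nonmonotone": _t2_like,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of the synthetic multimodal phantom."""

    shape: Tuple[int, int] = (128, 128)
    n_regions: int = 5
    modality_maps: Sequence[Union[str, Callable]] = ("identity", "t2_like")
    noise_level: float = 0.03
    bias_amplitude: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("a phantom needs at least two regions")
        if self.noise_level < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_level and bias_amplitude must be >= 0")
        if len(set(map(str, self.modality_maps))) != len(self.modality_maps):
            raise ValueError("modality maps must be pairwise distinct")


@dataclass(frozen=True)
class DeformationSpec:
    """Ground-truth deformation regime: rigid box or RBF field."""

    kind: str = "rigid"
    t_max: float = 10.0
    theta_max: float = 10.0
    n_centers: int = 4
    width: Optional[float] = None  # RBF width in px; default shape[0] / 5
    max_displacement: float = 7.2
    #: RBF centers are drawn from this central fractional box, so the
    #: deformation acts on the anatomy rather than on blank margins
    center_box: Tuple[float, float] = (0.3, 0.7)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("rigid", "rbf"):
            raise ValueError("kind must be 'rigid' or 'rbf'")


def _resolve_map(m: Union[str, Callable]) -> Callable:
    if callable(m):
        return m
    try:
        return MODALITY_MAPS[m]
    except KeyError:
        raise ValueError(
            f"unknown modality map '{m}'; known: {sorted(MODALITY_MAPS)}"
        )


def _region_base_values(n_regions: int) -> np.ndarray:
    """Background 0 plus tissue values spread over the tissue band.

    The band keeps every tissue far brighter than the background, the
    dominant contrast that stays stable across modalities while the
    transfer functions scramble (and, for t2_like, partially merge) the
    tissue ordering.
    """
    k = n_regions - 1
    if k == 1:
        vals = np.array([TISSUE_HI])
    else:
        vals = TISSUE_LO + _BAND * (np.arange(k) / (k - 1))
    return np.concatenate([[0.0], vals])


def _label_map(shape: Tuple[int, int], n_regions: int, rng: np.random.Generator) -> np.ndarray:
    """Head-like geometry: a large ellipse with internal tissue blobs.

    Label 0 is the dark background (air), label 1 the outer tissue
    ellipse, labels >= 2 smooth blobs inside it — mimicking the
    anatomy-on-black-background structure of brain slices, whose
    dominant foreground/background mode is stable across modalities.
    """
    H, W = shape
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    cr = rng.uniform(0.48, 0.52) * H
    cc = rng.uniform(0.48, 0.52) * W
    # guaranteed eccentricity: like a head, the outline itself carries
    # orientation information
    ar = rng.uniform(0.27, 0.32) * H
    ac = ar * rng.uniform(1.25, 1.45)
    ang = rng.uniform(0, np.pi)
    dr, dc = rows - cr, cols - cc
    u = np.cos(ang) * dr + np.sin(ang) * dc
    v = -np.sin(ang) * dr + np.cos(ang) * dc
    inside = (u / ar) ** 2 + (v / ac) ** 2 <= 1.0
    labels = np.zeros(shape, dtype=int)
    labels[inside] = 1
    for k in range(2, n_regions):
        br = cr + rng.uniform(-0.45, 0.45) * ar
        bc = cc + rng.uniform(-0.45, 0.45) * ac
        s = rng.uniform(0.14, 0.22) * min(H, W)
        g = np.exp(-((rows - br) ** 2 + (cols - bc) ** 2) / (2 * s**2))
        labels[(g > 0.55) & inside] = k
    return labels


def _bias_field(
    shape: Tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative field: exponentiated low-order polynomial,
    scaled so the multiplier deviates from 1 by at most `amplitude`."""
    if amplitude == 0.0:
        return np.ones(shape)
    H, W = shape
    r = np.linspace(-1, 1, H)[:, None]
    c = np.linspace(-1, 1, W)[None, :]
    coef = rng.normal(size=6)
    g = (
        coef[0] * r
        + coef[1] * c
        + coef[2] * r * c
        + coef[3] * r**2
        + coef[4] * c**2
        + coef[5] * (r**2 - c**2)
    )
    peak = np.max(np.abs(g))
    if peak == 0:
        return np.ones(shape)
    g = g / peak * np.log1p(amplitude)
    return np.exp(g)


def make_phantom(spec: PhantomSpec) -> Tuple[List[ImageGrid], np.ndarray]:
    """Render one phantom per modality plus the shared region label map.

    Per modality: intensity = map(region base value) * bias + noise,
    with an independent bias field and noise draw per modality (shared
    geometry). Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _label_map(spec.shape, spec.n_regions, rng)
    base = _region_base_values(spec.n_regions)
    images = []
    for m in spec.modality_maps:
        fn = _resolve_map(m)
        clean = np.asarray(fn(base), dtype=float)[labels]
        bias = _bias_field(spec.shape, spec.bias_amplitude, rng)
        img = clean * bias
        rng_noise = rng  # same stream; draws stay ordered and seeded
        span = float(clean.max() - clean.min())
        if spec.noise_level > 0 and span > 0:
            img = img + rng_noise.normal(
                0.0, spec.noise_level * span, size=spec.shape
            )
        images.append(ImageGrid(img))
    return images, labels


def sample_rigid(
    spec: DeformationSpec, rng: Optional[np.random.Generator] = None
) -> RigidTransform:
    """Uniform draw within +/- t_max per axis and +/- theta_max degrees."""
    if spec.kind != "rigid":
        raise ValueError("sample_rigid needs a rigid DeformationSpec")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    theta = float(rng.uniform(-spec.theta_max, spec.theta_max))
    t = rng.uniform(-spec.t_max, spec.t_max, size=2)
    return RigidTransform(theta, (float(t[0]), float(t[1])))


def sample_rbf_deformation(
    spec: DeformationSpec,
    shape: Tuple[int, int],
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Smooth random H x W x 2 displacement field.

    Field = sum over centers of a_c * exp(-||u - u_c||^2 / (2 w^2)),
    rescaled so its maximum displacement norm is min(realized,
    max_displacement). Zero centers give the zero field.
    """
    if spec.kind != "rbf":
        raise ValueError("sample_rbf_deformation needs an rbf DeformationSpec")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    H, W = shape
    field = np.zeros((H, W, 2))
    if spec.n_centers == 0:
        return field
    width = spec.width if spec.width is not None else H / 5.0
    lo, hi = spec.center_box
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    for _ in range(spec.n_centers):
        cr = rng.uniform(lo * H, hi * H)
        cc = rng.uniform(lo * W, hi * W)
        a = rng.normal(0.0, spec.max_displacement, size=2)
        g = np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * width**2))
        field[:, :, 0] += a[0] * g
        field[:, :, 1] += a[1] * g
    peak = float(np.linalg.norm(field, axis=-1).max())
    if peak > spec.max_displacement:
        field *= spec.max_displacement / peak
    return field
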