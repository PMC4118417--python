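# diffreg

Multimodal image registration via diffusion-map structural
representations.

Registering images of the same scene acquired with different
modalities (T1 vs T2 MR, for instance) is hard because corresponding
structures carry unrelated intensities. `diffreg` sidesteps the
intensity mismatch by transforming each image into a *diffusion-map
image*: a per-pixel embedding that reflects the intrinsic geometry of
the image's (position, intensity) point cloud rather than the raw gray
values. Embeddings of the different modalities are mapped into one
common Euclidean space with a change-of-basis operator, after which
plain Euclidean (L2) distance is a valid cross-modality similarity and
ordinary monomodal registration machinery applies. Mutual information
(MI) and raw-intensity L2 are provided as baselines, together with a
synthetic multimodal phantom generator and an evaluation harness, so
the whole pipeline is testable without any external data.

It is aimed at researchers in medical image analysis and manifold
learning who want a transparent, NumPy/SciPy-level implementation of
spectral structural representations for registration.

## The method

For an image `I: Ω → R^m`, every pixel `u` contributes a feature point
`x = (βu, I(u))`. A Gaussian kernel `w(x_i, x_j) = exp(−‖x_i − x_j‖² / 2σ²)`
defines a graph over these points; the density-invariant re-weighting

    w̃(x_i, x_j) = w(x_i, x_j) / (Σ_j w(x_i, x_j) · Σ_i w(x_i, x_j))

followed by row normalization yields a Markov matrix `P` whose random
walk approximates the Laplace–Beltrami diffusion on the underlying
manifold, independently of how densely it was sampled. With
eigenpairs `{λ_k, ψ_k}` of `P`, the diffusion distance between pixels
aggregated over every scale `t` is

    D̃²(x_i, x_j) = Σ_{k≥1} λ̃_k² (ψ_k(x_i) − ψ_k(x_j))²,
    λ̃_k² = λ_k² / (1 − λ_k²),

so `Ψ(x_i) = (λ̃_k ψ_k(x_i))_{k=1..l}` embeds the image into `R^l`
where Euclidean distance *is* the all-scales diffusion distance. A
change-of-basis operator `O^{α→γ}` of inner products between the
eigenbases of two images (over the same coarse grid) brings both
embeddings into a shared space `Ψ^γ`. Registration then minimizes

    D^Ψ(Ψ^{γ,α}, Ψ^{γ,α'} ∘ φ)

over rigid transforms or cubic B-spline free-form deformations
(4-pixel control spacing), with a quasi-Newton optimizer and analytic
gradients on a multi-resolution pyramid. The embedding is computed at
the coarsest level of a Gaussian pyramid and extended to full
resolution by Nyström kernel interpolation.

## Worked example

```python
import numpy as np
from diffreg import (PhantomSpec, make_phantom, EmbeddingConfig,
                     coarse_embedding, build_diffusion_map_image,
                     RigidTransform, register_rigid, rigid_error, warp)

spec = PhantomSpec(seed=0)                       # two modalities, 128 x 128
images, labels = make_phantom(spec)
truth = RigidTransform(6.5, (4.0, -7.0), (63.5, 63.5))
fixed, _ = warp(images[1], truth, cval=0.0)      # misaligned second modality

cfg = EmbeddingConfig(l=1, max_coarse_points=1024)
ref = coarse_embedding(images[0], cfg)           # reference spectral basis
moving_dmap = build_diffusion_map_image(images[0], cfg, coarse=ref)
fixed_dmap = build_diffusion_map_image(fixed, cfg, ref=ref)

result = register_rigid(fixed_dmap, moving_dmap, cost="diffusion")
r, t, combined = rigid_error(result.transform, truth)
print(f"errors: rotation {r:.3f} deg, translation {t:.3f} px, combined {combined:.3f}")
```

prints

```
errors: rotation 0.146 deg, translation 0.168 px, combined 0.222
```

i.e. a 6.5-degree, ~8-pixel misalignment between two modalities whose
tissue intensities are related by a *non-monotone* transfer function is
recovered to a fifth of a pixel by minimizing plain L2 distance between
the two diffusion-map images — a regime in which L2 on the raw
intensities is unreliable.

The same flow is available from the shell:

```
diffreg simulate --out phantom/ --seed 0
diffreg embed --image phantom/modality_0.tif --out dmap.tif
diffreg register --fixed fixed.tif --moving moving.tif \
    --cost diffusion --model rigid --out transform.json
diffreg evaluate --protocol rigid --trials 20 --seed 0 --out results.tsv
```

Transforms are serialized as JSON (`model`, `theta`/`t`/`center` for
rigid; `spacing`, `grid_shape`, `ctrl` for FFD); diffusion-map images
are written as float32 TIFF or NIfTI without requantization.

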