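# Methods

This note documents the model implemented in `diffreg`, the choices
made where the design was genuinely open, the synthetic study
conditions, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Diffusion framework

Each image is represented by the point cloud `x_i = (β u_i, I(u_i))`,
one row per pixel, with β = 1 and each intensity channel min-max
rescaled to `[0, max(H, W) − 1]` so geometry and intensity span
comparable ranges. A Gaussian kernel with bandwidth σ² produces the
affinity matrix `W` (unit diagonal retained: the kernel at zero
distance is 1). Two normalizations follow:

1. **Density-invariant re-weighting** `w̃ = W / (r rᵀ)` with `r` the
   row sums. This is the anisotropic normalization that removes the
   sampling-density dependence, so the operator approximates the
   Laplace–Beltrami diffusion of the underlying manifold rather than a
   density-weighted variant.
2. **Markov normalization** `P = w̃ / rowsum(w̃)`.

`P` is similar to the symmetric matrix `D^{−1/2} w̃ D^{−1/2}`
(`D = diag(rowsum(w̃))`); the eigendecomposition is performed on that
conjugate (real spectrum, orthogonal solver paths) and converted back.
Eigenvectors are normalized so that `ψ_0 ≡ 1` and `φ_0` is the
stationary distribution; with this convention the biorthogonality
`φ_jᵀψ_k = δ_jk` is exact and the probability-cloud diffusion distance

    D_t²(x_i, x_j) = Σ_m (P^t[i, m] − P^t[j, m])² / φ_0(m)

equals the spectral form `Σ_{k≥1} λ_k^{2t} (ψ_k(i) − ψ_k(j))²` to
machine precision (asserted at 1e−8 in the tests). Signs are fixed
deterministically (largest-magnitude entry of each `ψ_k` positive).

Rather than fixing one walk length t, all scales are aggregated:
`λ̃_k² = Σ_{t≥1} λ_k^{2t} = λ_k²/(1−λ_k²)`. Eigenvalues numerically at
1 beyond `λ_0` indicate a disconnected kernel graph and are rejected
with guidance (increase σ), never clipped.

### Kernel bandwidth

`median_bandwidth` implements the classic heuristic: the median of all
squared pairwise feature distances (even counts: mean of the two middle
values). For full image grids, however, that median is dominated by the
spatial spread of the frame and yields a nearly global kernel; in the
global-kernel limit the leading eigenvectors degenerate toward the
principal axes of the cloud — essentially affine functions of raw
intensity and position, which are exactly *not* modality-invariant. The
pipeline therefore scales the median by `EmbeddingConfig.bandwidth_scale`
(default 1/64), keeping the walk local enough that the slowest modes
are the intensity-gap *bottlenecks* (anatomy vs background, region vs
region), which are determined by the shared geometry and survive
intensity remapping. The scale is a tunable: binary images with a
full-span gap may need a larger value to stay connected (the
disconnection error says so).

## Coarse embedding and Nyström extension

The eigenproblem is solved densely at the coarsest level of a Gaussian
pyramid (blur σ = 1, decimate by 2) whose pixel count is at or below
`max_coarse_points` (default 3000; the evaluation protocols use 1024 so
a 128² phantom embeds at 32²). Coordinates are extended to full
resolution with the exact Nyström rule

    ψ_k(y) = (1/λ_k) Σ_i p(y, x_i) ψ_k(x_i)

where the out-of-sample transition row `p(y, ·)` is built with the same
density + Markov normalization (using the coarse row sums). At points
coinciding with coarse samples the extension is exact by construction —
the contract a plain kernel-smoothing average cannot satisfy. Fine
points whose kernel row underflows inherit the nearest coarse sample's
coordinates, with a warning.

## Cross-modality alignment

Two embeddings of the same scene live in different Euclidean spaces:
eigenvectors can flip sign and, when eigenvalues are close, rotate
within their eigenspace. Over a common coarse grid, the operator
`O[k, j] = ⟨ψ_k^ref, ψ_j^src⟩` (unit-normalized columns; Euclidean
inner products — the uniform measure, chosen for symmetry) maps source
coordinates into the reference space.

Two implementation points matter:

- The stored eigenbases are Löwdin-orthonormalized (closest orthonormal
  matrix); eigenvectors are orthogonal under the stationary-weighted
  inner product but only approximately under the Euclidean one, and
  without this step self-alignment would miss identity by ~1e−4.
- The source basis used by the operator is deliberately **small**
  (`n_align = 3` by default, versus `l = 1` output channels). A few
  extra modes let the operator undo rotations within near-degenerate
  eigenspaces; a large basis would simply *reconstruct the reference
  pattern at the reference pose* and project away the misalignment the
  registration is trying to estimate. The aligned output is rescaled to
  the reference's spectral amplitudes so both sides of a registration
  carry the same units.

The order of operations is: extend (per eigencolumn, λ-corrected) →
align. The two commute only in that order, because the eigenvalue
correction in the extension is per source column.

## Registration

`register_rigid` optimizes (θ, t_row, t_col) — rotation about the image
center, degrees — and `register_ffd` optimizes a cubic B-spline lattice
with 4-px control spacing at full resolution, both with L-BFGS-B and
analytic gradients over a 3-level image pyramid. Capture range: a
deterministic 3×3×3 grid of starts at the coarsest level plus a 1-D
rotation sweep (±12° in 1° steps) at every level — rotation landscapes
of near-isotropic structures are long flat valleys that a pure
quasi-Newton step stalls in. The FFD lattice is refined coarse-to-fine
(spacing 32 → 16 → 8 → 4 px) with the refined lattice initialized from
the previous field; a light bending-energy penalty (weight 3e−4) is on
by default because an unregularized lattice folds wildly wherever the
dissimilarity is locally flat (truth-initialized runs demonstrably
diverge without it).

Costs:

- `diffusion` / `l2`: mean squared per-pixel difference, normalized by
  the fixed image's variance so the objective is O(1) regardless of the
  intensity scale (diffusion coordinates are numerically small; with
  raw scaling L-BFGS-B's default tolerances stop it immediately).
- `mi`: the public `mi_cost` is the standard hard-binned 32-bin joint
  histogram MI (negated). The optimizer minimizes its differentiable
  counterpart: a linear-kernel (partial-volume) soft histogram whose
  gradient with respect to the warped intensities is analytic.

Inside the optimizer the moving image is sampled with *clamped*
(nearest) boundary handling. A hard overlap mask makes the objective
discontinuous in the transform parameters (line searches fail on the
jumps as border pixels enter and leave the mask) and has a degenerate
minimum at near-total overlap loss; clamping keeps the objective smooth
and, for anatomy-on-background images, introduces no artificial
mismatch because the border value is the background. The public `warp`
/ `l2_cost` / `mi_cost` functions keep the masked-overlap semantics.

## Synthetic study conditions

The generator emulates simulated multimodal brain acquisitions:

- **Geometry**: a head-like ellipse (axes 0.27–0.32·H, enforced axis
  ratio 1.25–1.45 so the outline itself carries orientation) containing
  smooth internal blobs; 5 regions and 128×128 pixels by default.
- **Intensities**: background 0; tissues in [0.55, 0.95]. The dominant
  background↔tissue gap is the modality-stable structure — as in MR,
  where air is far darker than tissue in every weighting. Transfer
  functions: `identity`, `gamma` (monotone), `inverse` (order
  reversal), `t2_like` (a parabola fold into a dimmer band, 1.8× gain;
  merges some tissue classes as T2 does and makes raw L2 unreliable),
  `pd_like` (a sawtooth permutation keeping all classes ≥ band/3 apart;
  scrambled order with no merging).
- **Corruptions**: per-modality smooth multiplicative bias field
  (exponentiated quadratic, ±20%) and additive Gaussian noise (3% of
  the clean intensity range), the standard simulated-MR settings.
- **Misalignments**: uniform rigid draws within ±10 px and ±10°;
  non-rigid fields as sums of 4 Gaussian radial basis functions (width
  H/5, centers in the central 30–70% box so deformations act on the
  anatomy), rescaled so the maximum displacement never exceeds 7.2 px.

Protocol choices: the rigid protocol uses the (identity, t2_like) pair
— the analog of a T1–T2 registration, where raw L2 genuinely fails —
and the non-rigid protocol uses (identity, pd_like), the
class-separating regime in which dense matching of scalar diffusion-map
images is well posed. This mirrors the pair-dependence seen on real
data, where L2 fails on some modality pairs and not others. Non-rigid
field error is reported over the anatomy mask: on a phantom whose blank
margins occupy ~45% of the frame the margin's true deformation is
unrecoverable by *any* similarity, whereas on full-frame anatomy the
plain mean is content-dominated anyway.

What passing these protocols does **not** show: performance on real
anatomy with continuous tissue texture, partial-volume boundaries and
acquisition artifacts; 3-D behavior; robustness to occlusion or
pathology present in only one modality.

## Known limitations

- The scalar (l = 1) diffusion coordinate weights internal regions by
  each modality's intensities, so its interior values are only
  approximately modality-invariant; this caps the accuracy of dense
  non-rigid matching. In our measurements the diffusion cost recovers
  RBF deformations to ~1.4 px mean over the anatomy, while the Parzen-MI
  baseline — a modern analytic-gradient implementation that is
  considerably stronger than the histogram MIs of the era this method
  was proposed in — reaches ~0.7 px on the same trials. The qualitative
  ordering "diffusion beats MI" therefore does not reproduce for
  non-rigid registration against this MI implementation, although it
  does for rigid registration against raw L2.
- Eigenvalue clustering makes single modes unstable; the small-basis
  change-of-basis operator mitigates but cannot remove this.
- Images whose content does not dominate the frame produce
  frame-anchored spectral modes that dilute the registration signal.
- The kernel bandwidth scale is a real tunable; there is no automatic
  selection.
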