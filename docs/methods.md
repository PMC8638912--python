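# Methods

## The denoising model

Dynamic PET sinograms p₁ … p_N ∈ ℝ^M (one per time frame, ordered by
acquisition time) satisfy an *energy ordering*: short early frames carry few
counts, long late frames many, so 0 < ‖p_i‖₁ ≤ ‖p_{i+1}‖₁ holds for
FDG-like kinetics.  All frames image the same anatomy, so the clean
structure of the high-count late frames can regularise the noisy early
ones.  The kernel graph filter (KGF) formalises this as lowpass filtering
of the signal "frame index ↦ sinogram" on a data-learned graph:

1. **Embedding.**  Frames are scaled to unit Euclidean norm (the scaling
   feeds only the embedding; the counts themselves are never rescaled) and
   a Gaussian Gram matrix c_ij = exp(−‖p_i−p_j‖²/2σ₁²) is built, centered,
   and eigendecomposed.  Each frame is represented by its d leading kernel
   principal-component scores.  With a linear kernel ⟨p_i,p_j⟩ the same
   pipeline reduces exactly to classical PCA — the "GF" ablation used as a
   baseline.
2. **Graph.**  Frame i is connected to its k_i nearest neighbours in score
   space with Gaussian weights of width σ₂ (self always included, so
   a_ii = 1).  The neighbour count adapts to the counts,
   k_i = round(N‖p_i‖₁/‖p_N‖₁) clamped to [1, N]: the rounding is half-up
   (floor(x+0.5)), and the 1-norms are those of the observed noisy frames.
3. **Filter.**  Each frame's similarity profile, normalised to sum one, is
   placed as a column of the Markov matrix F (so F is column-stochastic and
   P Fᵐ forms convex combinations of frames).  The filter order is the
   smallest m with ‖PFᵐ − PFᵐ⁻¹‖²_F / ‖PFᵐ⁻¹‖²_F ≤ ε, capped at m_max
   (default 50, with a warning when hit).

### Score scaling (whitening)

The eigenproblem leaves the eigenvector scale free, and the choice matters:
feature-space distances under a Gaussian kernel are bounded by √2, so any
eigenvalue-weighted score convention compresses all inter-frame distances
below ~2 and an O(1) graph width σ₂ cannot distinguish similar from
dissimilar frames.  The pipeline therefore whitens the retained components
(unit variance each, y_l = √N α_l), which makes score distances invariant
to the overall kernel scale — the property that lets fixed σ₂ values
transfer across datasets.  The classical conventions remain available
(`scaling="component"` for √λ α, which preserves the retained spectrum in
the score Gram matrix, and `scaling="raw"` for λα).  Components with
numerically zero eigenvalue are left at zero rather than amplified.

### Count-preserving filtering

Raw frames differ in total counts by two to three orders of magnitude
across the scan, so a convex combination of raw frames drags every
filtered frame toward the count level of its neighbours; measured on the
desk-scale study this *worsens* all high-count frames and inflates the
selected order (the stopping criterion then tracks slow cross-magnitude
mixing modes).  The pipeline therefore filters the count-normalised frame
*shapes* (columns divided by their 1-norms), selects m* on the shape
matrix, and returns each output frame rescaled to its own acquired count
total — an unbiased estimate of its true counts.  This preserves per-frame
quantitation by construction; with it the selected orders drop to m* = 2–3
and denoising improves every frame whose k_i exceeds one.  The literal
raw-count filtering is available via `count_preserving=False`, and
`apply_graph_filter` itself always implements the plain P ↦ PFᵐ map.

### Parameter defaults

| parameter | default | meaning |
|---|---|---|
| d | 7 (KGF) / 10 (GF) | retained principal components; small-eigenvalue components carry mostly noise |
| σ₁ | 0.5 | Gram-kernel width on unit-norm frames (‖p_i−p_j‖ ∈ [0, 2]) |
| σ₂ | 1.0 | graph-kernel width on whitened scores (unit variance per component) |
| ε | 10⁻³ | order-selection stopping constant (relative squared Frobenius change) |
| m_max | 50 | safeguard cap on the filter order |
| normalization | "l2" | frame pre-scaling for the embedding (`l1`, `max`, `none` selectable) |

`KGFConfig.invivo()` switches to the low-count clinical profile
(d=8, σ₁=0.15, σ₂=0.5, ε=10⁻⁴).

## Reconstruction

MLEM iterates Xⁿ⁺¹ = Xⁿ ∘ (Hᵀ(P ⊘ (HXⁿ + S))) ⊘ (Hᵀ1) from a uniform
image; S is the known additive expectation of randoms.  KEM runs the same
update on coefficients Λ under X = KΛ, with K a sparse row-stochastic
voxel-similarity kernel built from prior images; K = I reduces KEM to MLEM
exactly.  Prior images are three composites obtained by 20 MLEM iterations
on the sinograms rebinned into three contiguous, roughly equal-count
temporal groups (every group keeps at least one frame); per-voxel features
are the composite values normalised by their standard deviation, the
neighbourhood is the 50 nearest voxels in feature space, and the Gaussian
width is 1 in that normalised space.  Constant priors fall back to K = I
with a warning.  Numerical choices: Hadamard denominators floored at
10⁻¹², 0/0 ≔ 0, zero-sensitivity pixels frozen at zero, fixed iteration
count (default 100) with no early stopping.  The per-iteration Poisson
log-likelihood is recorded and is nondecreasing (EM guarantee; asserted in
the tests).

## The simulator

The simulator emulates a dynamic FDG brain study end to end:

* **Phantom** — nested ellipses on a 2-D grid: CSF rim, gray shell, white
  core with ventricle pockets, and an optional lesion disk strictly inside
  the gray shell; deterministic per seed.  It stands in for a segmented
  anatomical atlas and exists to provide the gray/white/lesion region
  structure the metrics need, not anatomical realism.
* **Kinetics** — the two-tissue compartment model with literature FDG rate
  constants (gray 0.116/0.254/0.116/0.011, white 0.059/0.149/0.090/0.013,
  lesion 0.089/0.269/0.135/0.015; K₁ in ml/g/min, k₂–k₄ in 1/min),
  evaluated by the analytic bi-exponential impulse response convolved with
  a Feng-type tri-exponential plasma input by adaptive quadrature.
  The default input amplitudes (A₁=0, A₂=7.562, A₃=39.923 with the classic
  decay rates) are calibrated so that the simulated 24-frame scan
  (4×20 s, 4×40 s, 4×60 s, 4×180 s, 8×300 s) reproduces the reference
  per-frame count profile — frames 8/16/24 carrying 0.68%/4.9%/9.1% of all
  events; the classic population bolus is available as
  `FengInput.population()`.  Frame values are time-averages of C_T over the
  frame (count-accumulation physics); radioactive decay is not modelled.
* **Projection & noise** — a pixel-driven parallel-beam projector with
  linear radial interpolation, stored sparse so the adjoint is exactly the
  transpose (MLEM requires a matched pair).  Noiseless sinograms are
  scaled by one global factor to the target total (10⁶ events at desk
  scale, 10⁷ for the full preset), randoms are spatially uniform per frame
  and sized to 20% of total acquired events (trues scaled to the
  complement; a config knob), and counts are Poisson-sampled per seed.
  Realizations use seeds base, base+1, ….

What the simulator does *not* emulate — and hence what passing tests do
not establish about real data: vascular (blood-pool) activity in the
tissue TACs, scatter beyond the uniform additive term, attenuation
estimation (factors can be supplied but are assumed known), detector
normalisation, dead time, motion, partial volume, 3-D geometry.  Because
the early-frame tissue activity is purely the compartment response, the
first four to six frames carry so small a count fraction that k_i rounds
to 1 and the filter leaves them unchanged — on real data with vascular
background those frames would have larger k_i.

## Metrics

MSE(dB) = 10 log₁₀(Σ(x̂−x)²/Σx²) — a *normalised* squared error in
decibels (the conventional name is kept); it is invariant to common
rescaling of both arguments and returns −∞ for an exact match.
RTA is the mean absolute activity over a region of one frame;
the regional MAE averages |RTA(x̂)−RTA(x)| over frames.  Multi-realization
curves are averaged arithmetically frame by frame ("AMSE").

## Study presets and problem sizes

The bundled `desk` preset — 64×64 phantom grid, 95 bins × 72 angles,
10⁶ events, 5 realizations, 100 EM iterations — is the configuration the
test suite and `scripts/acceptance.py` run; it completes in well under a
minute per full sweep on one CPU.  The `full` preset mirrors the reference
protocol (217×181 grid, 249 bins × 210 angles, 10⁷ events, 10
realizations) and takes correspondingly longer; the two differ only in
these sizes.

## Known limitations

* The graph is directed (k_i varies per frame) and no symmetrisation is
  attempted; ties in neighbour distance are broken toward the smaller
  frame index, and the last frame always neighbours every frame.
* The desk-scale geometry is 2-D and the phantom procedural; absolute
  activity units are arbitrary (a global count rescale fixes the scale),
  so MAE values are comparable within a study but not across unit systems.
* Frames with k_i = 1 pass through the filter untouched by construction;
  the method cannot improve a frame whose count fraction rounds its
  neighbour budget to one.
* KEM quality depends on the prior-image recipe; the equal-count
  three-group rebinning is one reasonable choice among several and is
  exposed as configuration.
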