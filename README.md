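# kgfpet — kernel graph filtering for dynamic PET sinogram denoising

Dynamic PET scans split the acquisition into short early frames and long
late frames to follow the tracer kinetics.  The early frames collect very
few coincidence events, so their sinograms are dominated by Poisson noise
and the reconstructed images are correspondingly poor.  `kgfpet` denoises
the sinograms *before* reconstruction by filtering along the temporal
direction: the N time frames are treated as signals on the vertices of a
graph learned from the data itself, and a lowpass graph filter mixes each
frame with its most similar frames.

The method, for a sinogram matrix **P** = [p₁ … p_N] (one column per frame):

1. **Kernel-PCA embedding.**  Build the Gram matrix
   c_ij = exp(−‖p_i − p_j‖² / 2σ₁²) on unit-norm frame vectors, center it
   (Ĉ = C − 1_N C − C 1_N + 1_N C 1_N), and represent each frame by its d
   leading kernel principal-component scores y_i (whitened to unit variance
   per component).  A linear kernel ⟨p_i, p_j⟩ gives the non-kernel "GF"
   ablation, equivalent to classical PCA.
2. **Adaptive kNN graph.**  Frame i keeps
   k_i = round(N‖p_i‖₁ / ‖p_N‖₁) nearest neighbours in score space
   (clamped to ≥ 1, self included), with Gaussian edge weights
   a_ij = exp(−‖y_i − y_j‖² / 2σ₂²): low-count early frames mix with few,
   similar frames; high-count late frames with many.
3. **Markov lowpass filtering.**  Each frame's similarity profile,
   normalised to sum one, forms a column of the transition matrix F, and
   the sinograms are filtered as P ↦ P Fᵐ*, where m* is the smallest order
   at which ‖P Fᵐ − P Fᵐ⁻¹‖²_F / ‖P Fᵐ⁻¹‖²_F ≤ ε.  Filtering acts on
   count-normalised frame shapes and each output frame keeps its acquired
   count total, so every denoised frame is a count-preserving convex
   combination of the originals.

Around the denoiser the package provides everything needed for a
self-contained study: a procedural brain-like label phantom, two-tissue
compartment (three-compartment) TAC simulation with a Feng-type plasma
input, a matched-adjoint parallel-beam projector with count scaling,
uniform randoms and Poisson noise, MLEM and kernelized-EM (KEM)
reconstruction, and the evaluation metrics (normalised MSE in dB, regional
time activity, regional MAE) with multi-realization averaging.

## Worked example

```python
import kgfpet as kp
from kgfpet.metrics import framewise_mse_db

cfg = kp.preset("desk")                      # 64x64 phantom, 95x72 sinograms, 1M events
sim = kp.simulate_dataset(cfg)
noisy, S = kp.add_randoms_and_noise(sim["scaled"], cfg.randoms_fraction, seed=1)

result = kp.KernelGraphDenoiser(noisy).fit() # d=7, sigma1=0.5, sigma2=1, eps=1e-3
print(result.summary())

before = framewise_mse_db(noisy.P, sim["trues"].P)
after = framewise_mse_db(result.denoised.P, sim["trues"].P)
for f in (8, 16, 24):
    print(f"frame {f:2d}: noisy {before[f-1]:6.2f} dB -> denoised {after[f-1]:6.2f} dB")
```

prints

```
Kernel graph filter fit
=======================
kernel:          gaussian (sigma1=0.5)
normalization:   l2
components d:    7
graph sigma2:    1.0
epsilon:         0.001
selected m*:     2
neighbour counts k_i: [1, 1, 1, 1, 1, 1, 2, 2, 3, 3, 3, 4, 11, 12, 13, 13, 22, 22, 23, 23, 23, 24, 24, 24]
retained eigenvalues: 3.104e+00, 9.809e-01, 9.679e-01, 9.615e-01, 9.099e-01, 8.633e-01, 8.343e-01
frame  8: noisy  -0.45 dB -> denoised  -5.45 dB
frame 16: noisy  -8.25 dB -> denoised -13.74 dB
frame 24: noisy -10.04 dB -> denoised -13.01 dB
```

The neighbour counts k_i grow with the per-frame counts — the filter
touches the earliest frames barely (k_i = 1 leaves a frame unchanged) and
averages the high-count late frames broadly.  The selected order m* = 2
keeps the frames from becoming over-correlated.  Negative MSE(dB) is
better; the denoised mid- and high-count frames gain 3–6 dB here.

A command-line interface mirrors the library
(`kgfpet simulate | denoise | reconstruct | evaluate | run`), e.g.

```sh
kgfpet run --preset desk --seed 0 --out scratch/desk_run
```

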