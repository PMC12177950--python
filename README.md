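# trapdiff

Analysis tools for single-molecule diffusion on atomically flat 2D
surfaces (e.g. fluorophore-labeled ssDNA sliding on hexagonal boron
nitride), where free sliding is interrupted by transient trapping at
atomic defects. The package is aimed at single-particle-tracking
practitioners who want to go from fluorescence movies (or simulated
ground truth) to apparent diffusion coefficients, mobility states and
defect-trapping parameters in one reproducible pipeline.

## What it computes

**MSD analysis.** For a trajectory r(k) = [x(k), y(k)] of length l with
frame time Δt, the time-averaged mean squared displacement at lag
τ = nΔt is

    ⟨r²(τ)⟩ = (1/(l−n)) Σᵢ |r(i+n) − r(i)|²,

averaged across molecules and fitted by the anomalous-diffusion law
⟨r²(τ)⟩ = 4·D_A·τ^α (ordinary least squares in log–log space). α < 1
indicates subdiffusion. Trajectories must be longer than 20 frames to
enter the ensemble.

**Mobility segmentation.** A windowed, variance-weighted temporal
diffusion coefficient

    D_A,temp = Σⱼ ŵ(j) · ⟨r²ₜₑₘₚ(jΔt)⟩ / (4 jΔt),   w(j)⁻¹ = j(2j²+1)/(T−j+1),

with weights normalized to sum to one, classifies each frame as mobile
or stationary against a 0.031 μm²/s threshold. Stationary dwell times
are fitted with a log-normal ψ(τ_t | μ, σ); jump-distance histograms are
decomposed into a stationary (localization-noise) and a mobile Rayleigh
component.

**Trap-diffusion Monte Carlo.** Molecules diffuse freely (coefficient
D₀, from molecular-dynamics estimates: 749/228/111/65 μm²/s depending on
strand length — these are inputs, never recomputed here) on a square
terrace of side L_d with mirror boundaries, and trap with probability
P_tr per 1 ns step into log-normal-distributed immobile dwells. The
simulator is event-driven (geometric free-run lengths, Gaussian
displacements, direct trap-time draws), validated against a literal
per-nanosecond stepper, and resampled at arbitrary observation frame
times via Brownian-bridge interpolation. Closed-form defect estimates
follow: τ_d = step/P_tr, l_d = √(4 D₀ τ_d), defect density (1 cm/l_d)².

**Synthetic movies and tracking.** A renderer turns trajectory sets into
EMCCD movies (integrated Gaussian PSF, Poisson photons at 400–450 /s,
motion blur, ~20 background counts/pixel, EM gain 200, CCD sensitivity
9.41, geometric photobleaching), and a tracker recovers them
(difference-of-Gaussians detection, subpixel refinement, intensity and
mask filters, gated linear-assignment linking with a 0.88 μm / 5 px
gate), so the whole analysis chain can be exercised and error-quantified
without experimental data.

## Worked example

```python
import numpy as np
from trapdiff import mc
from trapdiff.msd import LogNormalTrapFit, ensemble_msd, fit_anomalous

cfg = mc.MCConfig(D0=749.0, p_tr=0.0012, L_d=2.0,
                  trap=LogNormalTrapFit(mu=-8.0, sigma=2.25),
                  n_molecules=100, total_time=2.0, seed=0)
events = mc.simulate(cfg)
tracks = mc.resample_set(events, frame_time=0.1, cfg=cfg)
fit = fit_anomalous(ensemble_msd(tracks, max_lag=10), (0, 5))
print(f"D_A = {fit.D_A:.3f} um^2/s, alpha = {fit.alpha:.2f}")

est = mc.analytic_estimates(p_tr=0.0012, D0=749.0)
print(f"tau_d = {est.tau_d*1e6:.2f} us, l_d = {est.l_d*1e3:.1f} nm, "
      f"defect density = {est.defect_density:.2g} cm^-2, "
      f"median trap time = {est.tau_t_med*1e6:.0f} us")
```

prints

```
D_A = 0.111 um^2/s, alpha = 0.90
tau_d = 0.83 us, l_d = 50.0 nm, defect density = 4e+10 cm^-2, median trap time = 335 us
```

A molecule that would slide at 749 μm²/s on a defect-free terrace shows
an apparent coefficient of ~0.1 μm²/s at a 100 ms frame time once 0.12%
per-step trapping is on — a ~10⁴-fold reduction — with mild subdiffusion
(α = 0.90). The analytic chain converts the same trapping probability
into a mean free time of 0.83 μs between traps, a 50 nm free path, and a
defect density of 4 × 10¹⁰ cm⁻²; the median trap dwell implied by
μ = −8.0 is 335 μs.

The same stages are scriptable from the shell:

```
trapdiff simulate --config run.yaml --seed 1
trapdiff sweep    --config run.yaml --seed 1      # D_A(Δt), α(Δt) grids
trapdiff render   --config run.yaml --tracks run/tracks.csv
trapdiff track    --config run.yaml --movie run/movie.tif
trapdiff analyze  --config run.yaml --tracks run/tracks.csv
trapdiff end-to-end --config run.yaml --seed 1
```

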