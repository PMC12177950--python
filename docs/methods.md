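# Methods

This note records the models implemented in `trapdiff`, the assumptions
behind them, the defaults and why they were chosen, and the numerical
decisions that were genuinely open.

## Trajectory model and units

A trajectory is an ordered sequence of positions r(k) = [x(k), y(k)] at
strictly increasing, 0-based frame indices with a fixed frame time Δt.
Positions are micrometres and times seconds everywhere in the package;
pixel→μm conversion happens exactly once, when the tracker emits
coordinates. MSD estimators require contiguous frames and reject gapped
tracks rather than silently interpolating. The ensemble length filter
keeps tracks *strictly longer* than 20 frames (length ≥ 21 at the
default), the common practice of excluding short, noise-dominated
tracks.

## MSD estimation and the anomalous-diffusion fit

The time-averaged MSD at lag n is the mean of |r(i+n) − r(i)|² over all
l − n displacement pairs; the ensemble curve is the unweighted mean over
all tracks long enough to contribute at that lag. The power law
⟨r²(τ)⟩ = 4 D_A τ^α is fitted by ordinary least squares on
(log τ, log MSD) — slope α, intercept log(4 D_A) — over a configurable
lag range (default: the first min(10, available) lags). On noiseless
power-law input the fit is exact to machine precision.

A caveat that matters when interpreting fits at very short lags: because
D_A is the intercept at τ = 1 s, small slope perturbations are amplified
exponentially with the distance between the probed lags and τ = 1 s. On
a confined terrace the MSD carries a slight, real, boundary-induced
downward curvature at *any* lag (relative deficit ≈ 2.13 σ(τ)/L per axis
with σ(τ) = √(2Dτ), from folding displacements near the walls), so
"D_A ≈ D₀" statements for the no-trap control are evaluated on a large
terrace where the probed lags sit below the confinement regime; this is
a property of the estimator, not of the simulator.

## Temporal diffusion coefficient and mobility states

D_A,temp over a T-frame window is the weighted combination of per-lag
estimates MSD(jΔt)/(4jΔt), j = 1..T−1, with weights inversely
proportional to the relative variance of the windowed MSD,
w(j)⁻¹ = j(2j²+1)/(T−j+1). The weights are **normalized to sum to one**:
each per-lag term is an unbiased estimate of D for Brownian motion, so
the convex combination is unbiased as well — verified by a property test
(mean over 10⁴ Brownian windows within 5% of truth). Unnormalized
weights would rescale the estimator by an arbitrary T-dependent factor.

Defaults: window T = 16 frames (1.6 s at Δt = 0.1 s), a compromise
between state-change latency (the changepoint test localizes a
mobile→frozen switch within T frames) and estimator variance; threshold
0.031 μm²/s for stationary classification. Segmentation uses a centered
sliding window, clamped to full windows at the track ends; a single
threshold without hysteresis; minimum dwell length one frame. Dwells
touching either track end are right-censored and excluded from the
log-normal fit (their durations are lower bounds); the maximum-
likelihood fit of ψ(τ_t | μ, σ) is the sample mean and SD of
ln(τ_t/τ₀) over uncensored dwells, τ₀ = 1 s.

## Jump-distance mixture

Jump lengths at lag τ pool |r(i+n) − r(i)| across tracks. The
two-component model is f·Ray(r; s_stat) + (1−f)·Ray(r; s_mob) with
s²_stat = 2σ²_loc (lag-independent — apparent stationary jumps reflect
localization uncertainty, not motion) and s²_mob = 2σ²_loc + 2D_mobile τ.
Fitting is by maximum likelihood (Nelder–Mead on transformed parameters,
multistart over the mixture fraction). The stationary scale is bounded
to the localization regime, σ_loc ≤ 0.15 μm (just above the ~0.1 μm
practical resolution of the imaging model): without the bound the
stationary component can absorb a purely mobile population and the
fraction becomes unidentifiable on single-population data. Each lag is
fitted independently (no joint fit across lags).

## Trap-diffusion Monte Carlo

The model: free 2D Brownian motion with coefficient D₀ on a square
terrace [0, L_d]², mirror (reflecting) boundaries, and at each 1 ns step
a probability P_tr of entering a trap, where the molecule is immobile
for a log-normal dwell τ_t ~ ψ(τ_t | μ, σ), τ₀ = 1 s. All molecules
start mobile, at uniform positions. Defaults are the conditions the
model is designed around: D₀ = 749 μm²/s (the fastest strand), μ = −8.0,
σ = 2.25, L_d = 2 μm, 100 molecules, 2 s of simulated time. The
per-step RMS displacement at full speed, √(2D₀·1 ns) ≈ 1.2 nm per axis
(1.7 nm in 2D), is an order of magnitude below the ~50 nm defect
spacing, so trapping cannot be "skipped over" within one step. (The
nanometre scale of this displacement is sometimes quoted as "below
1 nm"; the exact value at 749 μm²/s is slightly above.)

**Event-driven scheme.** Iterating 2×10⁹ single steps per molecule is
not desk-tractable, so the simulator advances event by event: the number
of steps in a free run is geometric with success probability P_tr
(support ≥ 1 — the trap check is applied after each move; the ordering
is a convention, invisible at P_tr ≪ 1), the run displacement is
Gaussian with per-axis variance 2D₀t, and the trap duration is drawn
directly. This is *exact* for unconfined motion. Reflection folds the
run endpoint into the domain by the triangle wave of period 2L_d;
because folding an unconstrained Brownian path pointwise *is* the
standard construction of reflected Brownian motion, endpoint folding is
also exact within a run, and the Markov property makes the run-to-run
chaining exact. What is neglected is only the interaction between a
wall and the *unobserved interior* of a free run when the endpoint did
not cross (a sub-nanometre-to-nanometre effect at the default step). A
literal per-nanosecond reference simulator (`simulate_stepwise`) is kept
for validation; the two agree on ≤ 100 μs instances within Monte Carlo
error (the equivalence test uses a short-trap, fast-mixing configuration
so the comparison has statistical power; with the heavy-tailed default
traps the ensemble MSD of a 100 μs window is dominated by a few slow
molecules and any comparison drowns in Monte Carlo noise).

**Resampling.** Observation at frame time Δt evaluates the event
trajectory at t = 0, Δt, 2Δt, …: inside a trap, the trap position;
inside a free run, sequential Brownian-bridge interpolation between the
(unfolded) run endpoints, folded into the domain on output. Bridge
increments are unconditionally exact Brownian increments (verified:
variance 2DΔt, zero serial correlation). Per-molecule RNG streams are
seeded as (seed, molecule), so results per molecule are independent of
how many molecules are simulated; resampling uses a separately derived
stream so event generation and observation do not interact.

**Sweeps.** The (P_tr, Δt) grid simulates once per P_tr and resamples
per Δt, capping frames per molecule (default 2000) so sub-microsecond
frame times stay tractable — the MSD fit uses only the first ~10 lags.
The MSD for simulated data is computed per molecule (time-averaged) and
then averaged across molecules; an ensemble-from-origin variant is not
provided, as all acceptance-level statements target the Δt = 0.1 s
regime where the two coincide in practice.

**Analytic defect estimates.** τ_d = step/P_tr (mean free time),
l_d = √(4D₀τ_d) (2D random-walk length), defect density (10⁴ μm/l_d)²
per cm². The characteristic trap time is reported as τ₀·exp(μ) — the
log-normal *median*, ≈ 335 μs at μ = −8 — with the distribution mean
τ₀·exp(μ + σ²/2) exposed separately (≈ 4.2 ms at σ = 2.25); quoting
exp(−μ) as an "average" is a sign slip, since it would be ~3000 s.

## Synthetic imaging model

The renderer emulates a typical EMCCD single-molecule acquisition:

- pixel size 0.176 μm (a 0.88 μm linking gate spans 5 px), frame time
  0.1 s, image 64×64 px by default;
- per-molecule photon rate uniform in 400–450 photons/s (≈ 42.5
  photons per 100 ms frame), Poisson photon counts per frame;
- motion blur: the frame's photons are spread over 10 sub-frame
  positions along the linear interpolation between the frame's position
  and the next (a fast molecule's spot dims and elongates; a qualitative
  model of intra-frame motion, not a path-exact one);
- integrated (pixel-averaged) Gaussian PSF with σ = 0.084 μm by
  default — the width at which the Thompson localization-precision
  formula √(s²/N + a²/12N + 8πs⁴b²/a²N²) reproduces the observed
  0.096 μm at N = 42.5 photons, b = 20 background photons, a = 0.176 μm.
  The calibration takes the quoted ~20 background as photons; converting
  it through the camera gain instead (≈ 0.94 photons/px) would force an
  implausible σ ≈ 0.35 μm, while 0.084 μm is consistent with a
  diffraction-limited spot for a green-orange dye. The formula variant
  (background counts vs photons, SD vs mean) is not uniquely pinned by
  the source material, so 0.096 μm is used as a calibration input, not
  claimed as an independent reproduction;
- uniform background of 20 camera counts/pixel/frame (0.94 photons via
  the gain chain), EM gain 200, CCD sensitivity 9.41 e⁻/count;
  amplification noise as a Poisson stage on the amplified count (a mild
  excess-noise model — it adds ~5% variance, far less than the factor-2
  excess of a physical EM register; localization-scatter checks are
  calibrated against this model, not against real EMCCD statistics);
- photobleaching as a geometric per-frame survival (default off), giving
  the smooth monotone spot-count decay seen in long acquisitions.

What the generator does *not* emulate: dye blinking and triplet states,
substrate autofluorescence, aberrated or astigmatic PSFs, detector
fixed-pattern noise, and real EMCCD excess noise. Tests passing on these
movies therefore demonstrate correctness of the analysis chain under a
faithful-but-idealized imaging model, not performance bounds on real
data.

## Spot detection and linking

Detection band-passes each frame with a difference of Gaussians
(defaults 1.0 and 1.6 px scaled by the pixel size), takes local maxima
above a response threshold (default 15 counts, which cleanly separates
the ~60-count peak response of a default-SNR molecule from the ~5-count
filtered background noise), and refines to subpixel with a separable
three-point quadratic fit to the *log* of the response — exact for a
Gaussian peak, < 0.05 px worst-case error on noiseless renders across a
grid of fractional offsets (a quadratic on the raw response leaves
0.05–0.08 px of pixelation bias at this PSF width; the raw fit is kept
as a fallback where the response is not strictly positive). Spot
intensity is the background-subtracted sum over a small disk
(background = image median).

Linking solves, per consecutive frame pair, the exact rectangular
assignment minimizing total squared displacement among pairs within the
0.88 μm gate; unmatched spots start or end tracks. No gap closing, no
splitting or merging. Within-frame processing order is fixed
(descending DoG response, then position) so results are reproducible;
ties in cost are broken deterministically by that ordering.

The end-to-end benchmark tiles nine independent 2 μm terraces across the
field of view (~0.07 molecules/μm², below the 0.2 μm⁻² sparsity bound of
the imaging regime) with trap-diffusion dynamics at P_tr = 0.2%, chosen
so the resampled tracks show the apparent mobility observed in the
experiments this pipeline emulates (D_A ≈ 0.06 μm²/s at Δt = 0.1 s).
Recovery is scored as the fraction of ground-truth (track, frame)
samples matched within 0.3 μm by the best-overlapping recovered track.
The benchmark's ground truth is the instantaneous position at the frame
start while the detector sees the blur centroid, so recovery is
penalized (honestly) during relocation frames; at mobilities well above
the emulated regime this mismatch, not detection, dominates the error.

## Problem sizes

Default test and acceptance runs use 40–150 molecules, 0.5–4 s of
simulated time, ≤ 100-frame movies at 64×64 px, 10⁴ windows for the
unbiasedness check and 10⁵ samples for distribution-recovery checks —
sizes at which every Monte Carlo tolerance quoted above has ≥ 3σ margin
under seed variation while the whole suite stays interactive.

## Known limitations

- Trapping is probabilistic per step; there is no explicit spatial
  defect map, so repeated revisits to the same defect are not modeled.
- Step-edge channels are approximated by terrace boundaries; no distinct
  1D potential along an edge (a thin rectangular domain can mimic a
  ribbon geometry, but no quantitative ribbon claims are made).
- The mobility segmentation is a single-threshold classifier; no HMM or
  Bayesian state model, no hysteresis.
- Dwell-time censoring is handled by exclusion, which biases the
  log-normal fit when dwells are long relative to track length;
  frame-time discretization additionally censors dwells shorter than Δt.
- The jump-mixture fit is per lag; a joint fit across lags would share
  σ_loc and D_mobile and be more efficient.
- 2D only; no drift correction; no gap-filled tracks.
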