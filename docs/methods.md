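# Methods

## Signal model

A voxel contains two exchanging liquid water pools: myelin water (MW;
T1 = 280 ms, T2 = 8 ms) and merged intra/extra-cellular water (IE;
T1 = 1450 ms, T2 = 36 ms), with equilibrium fractions MWF and 1 − MWF and
total magnetisation normalised to 1.  Exchange is directional: a spin
stays in the MW pool for a mean residency time τ (k_mw→ie = 1/τ), and the
reverse rate follows from detailed balance, k_ie→mw = k_mw→ie·MWF/(1−MWF),
so the equilibrium net flux is exactly zero.  Magnetisation transfer to a
semisolid pool is deliberately outside the model.

### EPG-X steady state

The spoiled gradient-echo steady state is computed with the extended phase
graph formalism for coupled pools (EPG-X with full Bloch-McConnell
dynamics).  Per TR the simulator applies

1. an RF rotation (flip α, quadratic phase schedule φ_n = ½·n(n+1)·144°)
   to the (F+, F−, Z) configuration triplets of both pools;
2. relaxation + exchange over TR with exact 2×2 matrix exponentials —
   transverse configuration states of the two pools are coupled by the
   complex Bloch-McConnell propagator (including optional per-pool
   frequency offsets), longitudinal states by its real counterpart, with
   recovery feeding the zeroth longitudinal order;
3. diffusion damping of each configuration order (constant-gradient
   b-factors: dk²·TR·(k² + k + 1/3) for transverse transitions,
   dk²·TR·k² for longitudinal states, dk = 6π per voxel length);
4. a gradient shift of the transverse orders by one.

Configuration orders are truncated at 30; with the 6π spoiler and the
short pool T2s relative to TR, states beyond a handful of orders are
numerically zero, so the truncation is far from active.  The diffusion
coefficient (default 1 µm²/ms) and spoiling length scale (1 mm voxel) are
configuration defaults, not literature facts; the simulated summary
statistics tolerate this choice weakly (diffusion damping changes fitted
R2* by ≲0.1%).

The pseudo-steady state is detected by comparing the demodulated net
signal magnitude averaged over successive 5-pulse RF-phase cycles (the
144° quadratic schedule has period 5); the default tolerance is 1e-6
relative with a budget of 2000 pulses, and non-convergence raises an
error carrying the last relative change.  Reported pool amplitudes are
the demodulated F0 states at TE = 0 averaged over the final cycle.  An
ideal-spoiling mode (transverse states zeroed every TR) reduces the
simulator to the closed-form Ernst/Bloch-McConnell fixed point
s_p = sin α · [(I − A cos α)⁻¹(I − A) M0]_p, A = exp(Λ_L·TR), which the
test suite asserts to 1e-6.

### Isochromat oracle

An independent cross-check propagates a dephasing ensemble (default
10,000 isochromats spanning one spoiler period) through the identical
pulse train in the spatial domain: RF pulses as geometric rotations
(scipy rotation classes), relaxation/exchange as per-position 2×2 matrix
exponentials, the spoiler as a per-position phase ramp, and diffusion as
spectral damping of the magnetisation profile with the exact
constant-gradient b-factor per spatial frequency.  Because relaxation/
exchange is position-independent and diffusion is diagonal in the spatial
spectrum, the per-TR operator splitting is exact, so the comparison
isolates bookkeeping errors (state shifts, phase conventions, truncation)
rather than integration error.  EPG-X and the oracle agree to better than
1e-3 relative over the condition grid (machine precision in practice).

### Echo trains, orientation offsets and noise

The net magnitude signal at echo time t is
|S_MW·e^(−t(R2_MW + iΔω_MW)) + S_IE·e^(−t(R2_IE + iΔω_IE))| with pool
decay rates approximated by 1/T2 (exchange during the echo train is not
modelled, matching the net-signal definition of the analysis).  Per-pool
bulk offsets come from hollow-cylinder closed forms whose angular
dependence enters only via sin²θ: the myelin-water term combines the
isotropic and anisotropic sheath susceptibility plus a chemical-shift
term, and the merged IE pool sees the intra-axonal term scaled by the
fraction of IE water inside the axon (extra-axonal mean offset zero).
Defaults (χ_iso = χ_aniso = −0.10 ppm, g = 0.8, E = 0.02 ppm, intra-axonal
weight 0.5, B0 = 7 T) follow the hollow-cylinder literature; they are
config-visible and no quantitative summary depends on them — only the
qualitative orientation behaviour does.  Within-compartment frequency
dispersion is not modelled.

Noise is zero-mean complex Gaussian with σ = S(TE=0)/SNR added per
channel before the magnitude (Rician samples).  The SNR reference is
per-train by default (each train's own TE = 0 amplitude, keeping SNR
constant across flip angles); a global-max reference is available as a
config switch.

## Estimators

* **Log-linear R2\***: unweighted OLS of ln S on TE (closed-form masked
  normal equations, vectorised over voxels).  Samples ≤ 1e-12 are
  excluded with a reported count; no Rician bias correction, matching
  standard toolbox behaviour.  Rates are reported in 1/s.
* **ESTATICS**: joint OLS across flip-angle acquisitions with one shared
  decay and per-acquisition intercepts; a single acquisition reproduces
  the log-linear fit bit for bit (same arithmetic path).
* **Linear flip-angle model**: OLS of per-α R2\* on the effective angle
  α·B1+eff.  α enters in degrees (the protocol quotes angles in degrees),
  so slopes are 1/s per degree.  B1+ efficiency is a dimensionless
  multiplier; maps supplied in percent are normalised on read.
* **Quadratic MWF model**: origin-constrained least squares
  dR2\*/dα = β1·MWF + β2·MWF², inverted by the quadratic root in
  [0, 0.5] with explicit failure diagnostics.

These are scikit-learn-style estimators (fit/predict, get_params, fitted
attributes with trailing underscores); the simulator, phantom and CLI are
plain functions/commands because nothing about them is fit/predict-shaped.

## Statistics conventions

Standard deviations use the sample (n − 1) convention throughout.  The
RMS percentage error puts the factor 100 inside the square and divides
the sum by the number of conditions; under noise, both the residual and
its percentage reference are the same per-instantiation noisy per-α fit,
and per-set summaries average the per-α RMS over the nine evaluation
angles, then across instantiations.  Sensitivities are
100·(max − min)/mean along one grid axis, maximised over levels of the
other.  The flip-angle COV is the per-voxel 100·std/mean across maps,
summarised by the median over masked voxels (voxels with zero mean are
excluded with a count).  Inter-session bias is the voxel mean of the
per-voxel median difference across flip-angle pairs; the 95% interval is
1.96× the voxel standard deviation of that median.

The flip-angle sets used in robustness analyses are
set 1 = [6, 9, 12, 15, 19, 26, 31, 36, 42]°, set 2 = [6, 9, 15, 26, 31, 42]°,
set 3 = [6, 9, 26, 42]°, set 4 = [6, 26, 42]°, set 5 = [6, 26]°.

## Orientation analysis

The fiber-to-B0 angle is arccos(|v_z|/|v|) ∈ [0°, 90°] (the absolute
value enforces antipodal fiber symmetry; B0 is the world z-axis).
Reorientation between acquisition spaces applies only the rotation factor
(polar decomposition) of the supplied affine so shears/scales cannot
distort directions, then renormalises.  Voxels are selected by WM
probability > 0.9 and FA > 0.6, sorted by angle with ties broken by
linear voxel index, grouped into equal-count bins (default 200 voxels,
trailing partial bin dropped), and per-bin means are fitted with
R2\*(θ) = R2\*_iso + R2\*_aniso·sin⁴θ by linear least squares.

## Phantom

The generator emulates the acquisition the estimators expect: a WM-like
ellipsoid (MWF 0.16) inside a GM-like shell (MWF 0.06), both exchanging at
τ = 300 ms; smooth within-region MWF variation of ±10% relative, snapped
to 9 discrete levels so the forward model is exact per level; a radial
quadratic B1+ field spanning 0.7–1.15; a swirling fiber field whose pitch
spans θ = 0–90° well inside the high-FA core; a fabricated FA map (high
deep inside WM, falling toward the boundary — no diffusion simulation, it
exists to exercise the FA > 0.6 mask rule); and per-train Rician noise at
SNR(TE = 0) = 50.  Pool amplitudes are simulated per MWF level on a dense
effective-angle grid (0.5° spacing) and linearly interpolated to each
voxel's α·B1, an approximation that perturbs fitted R2\* by ≪ 0.1 1/s.
Everything is drawn from a single seeded generator; identical spec + seed
give byte-identical volumes.

What the phantom does not emulate — receive-coil inhomogeneity, motion,
co-registration interpolation (and its strong noise averaging),
macroscopic B0 gradients, spatial iron variation — limits what passing
tests say about real data: they validate the estimators and statistics,
not acquisition artefact handling.

## Problem sizes and defaults

The condition grid is 10 MWF × 5 residency × 9 flip angles (450 steady
states, ~1 s batched).  Monte-Carlo error summaries use 1000 noise
instantiations by default in tests and the reproduction script (the
statistics are stable to <1% Monte-Carlo error at this size; the analysis
supports any count).  Phantoms default to 32×32×16 voxels with ~1400 WM
and ~4400 GM voxels.

## Known limitations

* Only two liquid pools; no semisolid (MT) pool, no three-pool variants.
* Exchange is ignored during the echo-train decay (pools decay with fixed
  1/T2 after excitation), consistent with the net-signal definition used
  throughout; at τ ≥ 100 ms this is a second-order effect on the fitted
  R2\* but it does mean the simulated flip-angle dependence is an upper
  bound relative to models with transverse exchange during readout.
* Noise-free extrapolation of the linear model far outside the fitted
  flip-angle range (e.g. a [6, 26]° fit evaluated at 42°) inherits the
  model's curvature error, visible as the larger errors of the smallest
  flip-angle sets.
* The hollow-cylinder coefficients are literature defaults; orientation
  results should be read qualitatively (orderings, trends), not as
  quantitative susceptibility estimates.
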