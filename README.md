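# r2hat

Two-pool spoiled gradient-echo (SPGR) simulation and flip-angle-resolved
R2\* mapping for quantitative MRI.

## The problem

The effective transverse relaxation rate R2\* measured with multi-echo
gradient-echo imaging is a workhorse probe of brain microstructure (iron,
myelin).  Neuroscientific pipelines almost always fit a single
mono-exponential decay per voxel, but tissue is multi-compartmental: a
fast-relaxing myelin-water (MW) pool exchanges with a slower
intra/extra-cellular (IE) water pool.  Because the two pools have very
different T1 (280 vs 1450 ms), the excitation flip angle α changes their
relative steady-state weights, so the apparent single-compartment R2\*
depends on α; compartmental frequency offsets described by the hollow
cylinder fiber model additionally make it depend on the fiber-to-B0 angle
θ.  Both dependences confound comparisons across protocols, sites and head
positions.

A simple remedy is a linear partition of the flip-angle dependence,

    R2*(α) = R2*^ + (dR2*/dα) · α·B1+eff + ε,

whose intercept R2\*^ is a flip-angle-independent (and substantially less
orientation-dependent) R2\* measure, while the slope dR2\*/dα carries the
myelin-water sensitivity (approximately β1·MWF + β2·MWF² in the myelin
water fraction).  This package implements, end to end:

* a **two-pool EPG-X simulator** — extended-phase-graph SPGR steady state
  with full Bloch-McConnell exchange, RF spoiling (144° quadratic
  increment), 6π gradient dephasing per TR and diffusion damping — plus an
  independent **isochromat Bloch-McConnell oracle** used to cross-validate
  it to 1e-3;
* the **estimation suite**: per-α log-linear R2\*, joint shared-decay
  fitting across flip angles (ESTATICS), the linear flip-angle model with
  B1+ correction, and the quadratic MWF model with inversion — written as
  scikit-learn-style estimators that broadcast over voxel grids;
* the **statistics of the analysis**: RMSE / RMS-percentage error across
  tissue conditions, component sensitivities, coefficients of variation
  across flip-angle sets, inter-session bias/CI and Bland–Altman
  summaries, and the sin⁴(θ) orientation fit with equal-count angle
  binning;
* a **digital phantom generator** (NIfTI volumes with known ground truth:
  WM/GM regions, spatially varying MWF, smooth B1+ bias, a swirling fiber
  field spanning θ = 0–90°, Rician noise at SNR 50) and a **CLI**
  (`simulate-grid`, `make-phantom`, `fit-maps`, `orientation`, `report`).

## Worked example

Simulate a white-matter-like voxel (MWF 0.16, 300 ms myelin-water
residency) at four flip angles, fit the mono-exponential R2\* per angle,
and partition the flip-angle dependence:

```python
import numpy as np
from r2hat import (SequenceParams, ExchangeParams, EchoTimes, two_pool_wm,
                   simulate_spgr_steady_state, synthesize_echo_train,
                   fit_loglinear_r2star, fit_alpha_linear_model)

pools = two_pool_wm(0.16)            # white matter: 16% myelin water
exchange = ExchangeParams(300.0)     # 300 ms residency in the myelin pool
seq = SequenceParams()               # TR 19.5 ms, 6*pi spoiler, 144 deg RF spoiling
te = EchoTimes()                     # 6 echoes, 2.56:2.38:14.46 ms

alphas = [6.0, 9.0, 26.0, 42.0]
r2stars = []
for alpha in alphas:
    sig = simulate_spgr_steady_state(pools, exchange, seq, alpha)
    train = synthesize_echo_train(sig, pools, te)
    r2stars.append(fit_loglinear_r2star(train).r2star)
    print(f"alpha = {alpha:4.0f} deg   R2* = {r2stars[-1]:.2f} 1/s")

fit = fit_alpha_linear_model(np.array(r2stars), np.array(alphas))
print(f"R2*^ = {fit.r2star_hat:.2f} 1/s   dR2*/dalpha = {fit.dr2star_dalpha:.3f} 1/s/deg")
```

Output:

```
alpha =    6 deg   R2* = 36.30 1/s
alpha =    9 deg   R2* = 37.21 1/s
alpha =   26 deg   R2* = 44.74 1/s
alpha =   42 deg   R2* = 50.36 1/s
R2*^ = 33.89 1/s   dR2*/dalpha = 0.398 1/s/deg
```

The apparent R2\* climbs by 14 1/s between 6° and 42° — purely a
steady-state weighting effect, with no change in the underlying tissue —
while the intercept R2\*^ is the flip-angle-free summary of the voxel.
The same estimators run voxel-wise on NIfTI volumes via `r2hat fit-maps`.

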