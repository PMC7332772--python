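# Methods

This note documents the models, parameters, numerical choices and known
limitations of `mtuenergy`.  Everything quantitative stated here is computed
by the test suite or the analysis/acceptance scripts.

## Contraction dynamics

The MTU is a four-element Hill-type model: contractile element (CE) and
parallel elastic element (PEE) in parallel, in series with the tendon,
itself a serial elastic element (SEE) in parallel with a serial damping
element (SDE).  The single internal degree of freedom is the fiber length
`l_CE`; its rate follows from the instantaneous force balance

```
F_CE(l_CE, l̇_CE, a) + F_PEE(l_CE) = F_SEE(l_MTU − l_CE) + F_SDE(l̇_MTU − l̇_CE).
```

Element characteristics (shape constants in `src/mtuenergy/data/default_curves.yaml`,
a versioned document; all shapes are reconstructions of the established
open-source four-element model family and are *not* subject-specific):

* **CE force–length**: exponential bell
  `F_isom = exp(−|(l_CE/l_CE,opt − 1)/Δw|^ν)` with
  (Δw, ν) = (0.45, 3.0) ascending and (0.45, 1.5) descending.
* **CE force–velocity**: Hill hyperbola with activity-scaled constants
  `A_rel = A_rel,0·L(l_CE)·(1+3a)/4`, `B_rel = B_rel,0·(3+4a)/7`
  (`L` = 1 below optimal length, `F_isom` above).  At full activity and zero
  load the unloaded shortening speed is `(B_rel,0/A_rel,0)·l_CE,opt`
  = 12 l_opt/s, consistent with the fast-twitch maximum shortening velocity
  that motivates `B_rel,0 = 12·A_rel,0`.  The eccentric branch is a second
  hyperbola with force asymptote 1.5× isometric and double the concentric
  slope at zero velocity.
* **PEE**: `K·(l_CE − 0.95·l_CE,opt)^2.5` above its slack length, scaled so
  it carries 2·Fmax at the end of the descending limb.
* **SEE**: toe region `K_nl·Δl^ν_see` up to 4.25% strain (carrying 0.4·Fmax
  there), linear above; `ν_see` = 4.25/1.7 = 2.5.
* **SDE**: coefficient `d_max·((1−R)·(F_CE+F_PEE)/Fmax + R)` with
  `d_max = 0.3·Fmax·A_rel,0/(l_CE,opt·B_rel,0)` and `R = 0.01`.

Pennation enters only through cos α in Fmax; the contraction dynamics is
one-dimensional along the line of action.

### Solving the force balance

For either Hill branch, multiplying the balance residual by the hyperbola
denominator `(1 − l̇_CE/(B_rel·l_CE,opt))` yields an expression *exactly*
quadratic in `l̇_CE` (the damping coefficient is linear in the elastic
force).  The quadratic coefficients are recovered from three exact samples
of that product rather than hand-expanded algebra.  Roots are admissible if
they lie on the correct side of the hyperbola asymptote **and** give a
non-negative damping coefficient — discarding algebraic roots in the
negative-damping regime, which solve the equation but not the physics.  The
concentric branch is tried first; ties at zero net force break concentric.
A bracketed `brentq` on the exact residual is the guarded fallback.

### Initial state and integration

The initial fiber length solves the static equilibrium
`a·F_isom·Fmax + F_PEE = F_SEE` by bracketed root finding (residual
< 1e−6·Fmax).  With the reference parameters at the study's initial
conditions (l_MTU = 0.311 m, a = 0.005) this gives l_CE,init = 0.0520 m.
The coupled (l_CE, a) system is integrated with a stiff-capable
variable-step solver (LSODA; relative tolerance 1e−4, absolute tolerances
1e−7 m on l_CE and 1e−6 on a; output every 10 ms).  The system is genuinely
stiff — the tendon's linear stiffness against the damping coefficient gives
time constants of tens of microseconds — and integrator *trial* states can
leave the physical domain; the right-hand side therefore floors the
isometric-bell term (which otherwise underflows far from optimal length)
and steers `l_CE ≥ l_MTU` trial states back with a finite restoring
velocity instead of failing the step.  Accepted states are unaffected
(force-balance residual < 1e−6·Fmax along whole trajectories, tested).

## Activation dynamics

`ȧ = (u − a)·((1/τ_ACT − 1/τ_DEACT)·u + 1/τ_DEACT)` with a clamped to
[0.001, 1]; the lower bound prevents singular force terms, and u between
samples is linearly interpolated.  Fiber-length–dependent activation
dynamics are deliberately not modeled: with measured EMG as input, the
simpler stimulation-driven first-order form is the established choice.

## Parameters

Subject-specific values (reference morphometry, from anatomical MRI plus
literature constants):

| symbol | meaning | value | derivation |
|---|---|---|---|
| V | muscle volume | 379.89 cm³ | MRI segmentation |
| l_CE,opt | optimal fiber length | 0.0574 m | MRI |
| α | pennation angle | 27° | MRI |
| l_MTU(0°) | MTU rest length | 0.315 m | MRI |
| r | ankle moment arm | 0.064 m | MRI |
| σ | maximum muscle stress | 0.25 MPa | literature |
| ρ | tissue density | 1059.7 kg/m³ | literature |
| r_fib | fast-twitch fiber ratio | 0.45 | literature |
| Fmax | σ·V/l_CE,opt·cos α | 1474 N | derived |
| l_SEE,0 | l_MTU(0°) − l_CE,opt | 0.2576 m | derived |
| A_rel,0 | 0.1 + 0.4·r_fib | 0.28 | derived |
| B_rel,0 | 12·A_rel,0 | 3.36 s⁻¹ | derived |
| τ_ACT, τ_DEACT | 80−0.47·%FT, 90−0.56·%FT ms | 58.85, 64.8 ms | derived |
| M | muscle mass | 0.3587 kg | value of record |

Two provenance notes.  (1) The affine fiber-type interpolation of the time
constants is a *reconstruction* of the standard formulation: it reproduces
the published endpoint values (80/90 ms slow, 33/34 ms fast) and the
reference subject's 58.85/64.8 ms at 45 %FT.  (2) The morphometric product
V·ρ gives 0.4026 kg, while the reference parameter table of record lists
M = 0.3587 kg; the tabulated value is kept for simulation (`REFERENCE_MASS`)
and the discrepancy is surfaced rather than silently resolved — mass only
scales the mass-specific work rate, so the effect on Ė is the ratio of the
work share (small at this effort).  Angles are degrees in configuration
files and converted to radians exactly once at derivation.

## Energetics

`Ė = ḣ_AM + ḣ_SL + ẇ_CE`, all mass-specific (W/kg = J kg⁻¹ s⁻¹):

* effective activation `A = u` if `u ≥ a`, else `(u+a)/2`;
* `ḣ_AM = (1.28·%FT + 25)·A^0.6`, reduced by `0.4 + 0.6·F_isom` above
  optimal length (82.6 W/kg fully active for the 45 %FT reference muscle);
* `ḣ_SL`: shortening heat `−α_S·(l̇_CE/l_CE,opt)·A²` with the slow/fast
  coefficient `α_S = (100/v_max,ST)·(1−r_fib) + (153/v_max,FT)·r_fib`
  (v_max,FT = 12 l_opt/s, v_max,ST = v_max,FT/2.5); lengthening heat
  `4·(100/v_max,ST)·(l̇_CE/l_CE,opt)·A` (linear in A); both scaled by
  `F_isom` above optimal length;
* `ẇ_CE = −F_CE·l̇_CE/M` (shortening positive; `l̇_CE < 0` = shortening).

The total is clamped at ≥ 0 (this accounting cannot net-absorb chemical
energy); components are reported unclamped so the decomposition stays
inspectable.  Cumulative energy is the trapezoidal integral of the clamped
total on the output grid.  The heat coefficients are reconstructions of the
published mixed-fiber energy model; their exact fidelity to any particular
implementation cannot be asserted, which is why the package's checks on the
energetics are property-based (decomposition identity, scaling exponents,
mass-specific invariance, magnitude) rather than value-based.

## PCr-based estimation

`[PCr] = 8.2 mmol/l · I_PCr/I_γ-ATP` when raw intensities are given.  The
conversion constant is ΔH_ATP·c_vol→mass = 21 kJ/mol · 0.68 l/kg = 14.28
J kg⁻¹ per mmol l⁻¹, with the sign fixed so depletion yields positive
expenditure.  The estimator fits cumulative energy
`E(t) = ([PCr](0) − [PCr](t))·14.28` by OLS over the validation window —
equivalent to averaging the per-interval forward-difference rates in the
noiseless case and more stable under noise; the 95% CI uses the
t-distribution with n−2 degrees of freedom.  Estimates are invariant to a
constant [PCr] offset (tested), which is why the unknown true baseline does
not matter.  Window detection: 3-point moving average of pH, argmax
(excluding the convolution-biased edge samples), clipped to [10, 60] s;
without a pH channel the documented default end is 25 s.  Fitting beyond
the detected window raises an error unless explicitly overridden, encoding
the central caveat that the PCr slope underestimates expenditure once
glycolysis starts.

## Synthetic data

The generators emulate the study conditions: raised-cosine pedaling between
0° and 25° at 0.8 Hz starting at 3.13° (the waveform shape beyond range and
cadence is a modeling assumption); per-cycle Hann-shaped stimulation bursts
occupying 40% of each cycle (the pedal-push phase); a PCr record at 5 s
sampling with 120 s rest, 180 s load, linear depletion at the generating
rate for 25 s (the exact inverse of the 14.28 conversion), then an
exponentially decaying slope (time constant 25 s, a phenomenological
glycolytic/oxidative takeover — not a pathway model); pH rising 7.05 → 7.10
over the validation phase, then falling; Gaussian [PCr] noise (default
0.5 mmol/l).  The default PCr baseline, 32 mmol/l, is an assumption kept as
a configuration field and never used by the estimator (offset invariance).
The raw EMG is 10–500 Hz band-limited Gaussian noise amplitude-modulated so
its local RMS equals the burst envelope; a moving-RMS envelope of the
rectified, normalized signal recovers the ground-truth u(t) to a few
percent.

**Stimulation level.**  The default envelope peak is `emg_peak = 0.10`.
The exercise is at 20% of the maximal *pedal* force, which is shared among
all plantarflexors; surface-EMG amplitude scales roughly linearly with task
force, and normalizing to the MVC rectified *maximum* (a noise peak about
twice the burst-mean level) halves the normalized amplitude again.
Calibrating the stimulation so that this one muscle's force reaches 20% of
its own Fmax instead would demand near-maximal bursts (during the pedal
push the fiber shortens near its force–velocity limit, so force per unit
activation is low) and put the simulated rate an order of magnitude above
the few-J kg⁻¹ s⁻¹ regime this exercise occupies.  A bisection utility
(`calibrate_emg_peak`) is provided for users who do want a target
peak-force fraction; its result is logged.

What the synthetic data does *not* capture: motor-unit structure and
EMG–force nonlinearity, cycle-to-cycle variability and drift, fatigue,
partial-volume contamination of the MRS voxel, pH-dependent enthalpy, and
any coupling between mechanics and the PCr record (the two branches are
generated independently, linked only through the generating rate).  Passing
tests therefore demonstrate internal consistency and correct estimator
behavior under the assumed structure, not fidelity to any particular
subject.

## Pipeline conventions

* Simulated rate Ė_sim: OLS slope of cumulative energy over the same 25 s
  window used by the PCr branch (configurable); its uncertainty is labelled
  as fit standard error (95%), not a physiological error bar.
* Monte-Carlo sensitivity: uniform perturbations on ±(relative error) —
  "estimated errors" are read as bounds; a normal option (sd = rel/2) exists
  behind a flag.  Each run re-derives Fmax, l_SEE,0 and the kinematic
  mapping from the perturbed morphometry.  Perturbing the MTU rest length
  alone cancels exactly (it shifts l_MTU(t) and l_SEE,0 equally), so the
  deviation is driven by fiber length and pennation through Fmax and the
  force–length operating point.  Failures are excluded and counted; > 10%
  aborts.
* Problem sizes: analyses and tests simulate 27–30 s spans (the 25 s
  validation window plus margin) rather than the full 3 min load — the rate
  is fitted inside the window, so the remainder adds cost without
  information.  The test suite runs the sensitivity at 25 perturbations;
  `scripts/acceptance.py` runs the full 100.
* Determinism: all generators and the Monte-Carlo draw from
  `numpy.random.default_rng(seed)`; reports embed a configuration hash.

## Known limitations

* Curve shapes and heat coefficients are reconstructions of the model
  family (see above); quantities sensitive to them (e.g. l_CE,init, checked
  to ~1 mm) carry that reconstruction uncertainty.
* No force-level validation: the simulated F_MTU is small at this effort
  (the muscle shortens near its force–velocity limit during the push), and
  no dynamometry branch exists to check it.
* The activation model ignores fiber-length dependence; the energetics
  ignores basal metabolism and explicit glycolytic/oxidative pathways
  (out of scope — the comparison is confined to the validation window).
* Single-muscle scope: load sharing among plantarflexors is not modeled;
  the stimulation level encodes it only implicitly (see above).
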