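# mtuenergy

Muscle-level energy expenditure during dynamic exercise, estimated two
independent ways and compared: a forward-dynamic Hill-type simulation of the
M. gastrocnemius medialis driven by pedal-angle and EMG recordings, and a
model-free estimate from the phosphocreatine (PCr) depletion measured with
dynamic ³¹P magnetic resonance spectroscopy.  The package is aimed at
researchers in neuromuscular biomechanics who want to validate muscle
energetics models *in vivo* at the level of a single muscle, where neither
spirometry (whole-body) nor heat measurements (muscle groups, confounded by
perfusion) can reach.

## The two branches

**Simulation branch.**  The muscle-tendon unit (MTU) is a contractile
element CE with force–length–velocity behavior, a parallel elasticity PEE,
and an in-series tendon modeled as elasticity SEE plus damping SDE.  The
single internal state is the fiber length, evolving by the force balance

    l̇_CE = f(l_CE, l_MTU, l̇_MTU, a),
    F_CE + F_PEE = F_SEE + F_SDE ,

with MTU kinematics from the pedal angle φ through a constant moment arm,
l_MTU(φ) = l_MTU(0°) − r·φ.  Muscle activity a follows the stimulation u
(rectified, MVC-normalized EMG) through first-order activation dynamics

    ȧ = (u − a)·((1/τ_ACT − 1/τ_DEACT)·u + 1/τ_DEACT).

Along the trajectory the mass-specific metabolic rate is accounted as

    Ė = ḣ_AM + ḣ_SL + ẇ_CE    [J kg⁻¹ s⁻¹]

(activation/maintenance heat, shortening–lengthening heat, fiber work rate).
All muscle parameters derive from morphometry (MRI) and literature tissue
constants — e.g. Fmax = σ·V/l_CE,opt·cos α = 1474 N for the reference
subject — leaving no free parameter fitted to the validation data.

**Experimental branch.**  During the first ~25 s of exercise ATP resynthesis
is dominated by the creatine kinase reaction, so the PCr depletion rate
equals the ATP hydrolysis rate and

    Ė = −d[PCr]/dt · ΔH_ATP · c_vol→mass = −d[PCr]/dt · 14.28

in J kg⁻¹ s⁻¹ per mmol l⁻¹ s⁻¹.  The creatine kinase reaction consumes
protons, so intracellular pH rises while it dominates; the pH maximum marks
the end of this *validation window*, beyond which the PCr slope
underestimates expenditure and the estimator refuses to fit (unless forced).

Because the original single-subject recordings are not public, the package
ships a synthetic-data module that generates protocol-faithful inputs
(0.8 Hz pedaling between 0° and 25°, per-cycle EMG bursts at ~20% effort,
PCr/pH series with a 25 s validation phase) with known ground truth.

## Worked example

```
python analysis/01_generate_inputs.py
python analysis/02_simulate_energetics.py
python analysis/03_estimate_mrs_rate.py
python analysis/04_sensitivity.py
python analysis/05_validate.py
```

Output of the final comparison (seeded, reproducible):

```
simulation branch:  6.582 ± 0.007 J/kg/s
experimental branch: 6.351 ± 2.568 J/kg/s (n=5, window 25 s)
intervals overlap — branches agree
```

The simulation branch reports the slope of the cumulative mass-specific
energy over the 25 s window (its small uncertainty is the fit standard
error, not a physiological error bar); the experimental branch reports the
linear-fit rate of the PCr-derived energy with a 95% CI from five 5 s
samples.  The synthetic PCr record was generated at 5.8 J kg⁻¹ s⁻¹; both
branches recover that magnitude and their intervals intersect.  Forcing the
PCr fit to 60 s yields 4.523 J kg⁻¹ s⁻¹ — the expected underestimation once
anaerobic glycolysis (invisible to the PCr slope) takes over.  The
Monte-Carlo sensitivity run (100 perturbations of fiber length ±10%, MTU
rest length ±5%, pennation ±10%) changes the 25 s cumulative energy by
0.037% on average: the simulated energy is dominated by the
activation/maintenance heat, which is insensitive to the perturbed geometry.

The same steps are available as a CLI (`mtuenergy synth | simulate |
estimate-mrs | sensitivity | validate`) for use on recorded data files.

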