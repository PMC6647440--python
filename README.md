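# uteroflow

A closed-loop 1D–0D model of the maternal cardiovascular system, built to
study utero-ovarian blood flow across pregnancy. The package couples:

- **1D pulse-wave vessels** — visco-elastic tube law (power-law elastic branch
  plus a Voigt wall term), nonlinear continuity/momentum with a friction term
  for a nearly flat velocity profile (ξ = −22), discretised with an implicit
  element-trapezoidal (box) scheme in space and BDF2 in time;
- **lumped (0D) vascular beds** — R–C–R–C–R ladders with pressure-dependent
  resistances `R_vb = R0 (p_tm0 − p_zf)/(p_tm − p_zf)` that shut off below the
  zero-flow pressure (5 mmHg), plus volume-dependent coronary elements;
- **a four-chamber varying-elastance heart** — normalised double-activation
  elastance curves, septal and pericardial interaction, an atrial "piston"
  effect, and Bernoulli-resistance/inertance valves whose orifice follows a
  rate-limited opening state ζ ∈ [0, 1];
- **an iterative participant-adaptation scheme** — systemic bed resistances
  seeded from TPR = MAP/CO and a table of regional cardiac-output fractions,
  total arterial compliance from τ = TPR·C_T (τ = 1.79 s), then three
  feedback controls (resistance → mean pressure, arterial compliance → pulse
  pressure, blood volume → stroke volume) iterated until the model matches
  measured SBP, DBP and CO to ±0.5% with a periodic final cycle;
- **clinical indices** — MABP, two TPR estimators, local (PWV = c0) and
  two-site transit pulse wave velocity, the pulsatility index
  PI = (u_max − u_min)/u_mean, and uterine-waveform notch detection.

The utero-ovarian circuit (ovarian, communicating, ascending/descending
uterine, ×4 arcuate and ×50 radial/spiral vessels, with ovary, fundus,
uterus, placenta and cervix|vagina beds) ships as a packaged vessel table
with both non-pregnant and late-pregnancy reference areas; a reduced
closed-loop surrogate network stands in for the full-body geometry so every
workflow runs at desk scale.

## Worked example

```bash
python examples/03_adaptation.py
```

prints (seed-1 synthetic post-partum record):

```
targets: HR 60.3 bpm, 102.9/62.7 mmHg, CO 5.78 L/min (SV 95.9 ml)
converged = True after 9 iterations
model: 103.2/63.0 mmHg (MABP 80.1), CO 5.793 L/min
errors (%): {'SBP': '+0.24', 'DBP': '+0.40', 'CO': '+0.23'} | final cycle change 0.40%
controls: resistance x0.630, compliance x1.828, blood volume +116 ml
```

The three controls converge the beating closed loop onto the drawn targets:
the final model reproduces systolic/diastolic brachial pressure and cardiac
output to a fraction of a percent, the resistance/compliance multipliers say
how far the seeded vasculature had to move, and the added blood volume is the
amount injected through the venular compliance nodes to reach the target
stroke volume. `examples/04_uterine_waveforms.py` shows the clinical
signature of pregnancy remodelling: the non-pregnant uterine artery notches
at end systole with near-zero diastolic flow and a high pulsatility index,
while the term configuration flows throughout diastole with a much lower PI.

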