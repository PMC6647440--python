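# Methods

## Model overview

`uteroflow` simulates the maternal circulation as a closed loop of three
coupled sub-models sharing one implicit time level.

**1D vessels.** Each vessel segment carries cross-sectional area *A*,
pressure *P* and volumetric flow *Q* along its axis. Continuity is
`∂A/∂t + ∂Q/∂x = 0`; momentum is
`(ρ/A)∂Q/∂t + (ρ/A)∂(Q²/A)/∂x + ∂P/∂x + |ξ|μπQ/A² = 0`, with blood density
ρ = 1.06 g/cm³, viscosity μ = 0.035 P and friction coefficient ξ = −22
(nearly flat velocity profile with a thin boundary layer; the viscous force
opposes the flow, so the steady balance yields a pressure drop
`|ξ|μπLQ/A²`). The wall is visco-elastic:
`P = P0 + P_ext + (2ρc0²/b)((A/A0)^{b/2} − 1) + (Γ/(A0√A))·∂A/∂t`, with
stiffening exponent `b = 2ρc0²/(P0 − P_collapse)`. The reference wave speed
follows the empirical law `c0² = (2/3ρ)(k1·exp(k2·D0/2) + k3)` with
per-compartment coefficients (systemic/coronary/pulmonary, arterial/venous);
the wall viscosity is `Γ = b1/D + b0` (b1 = 100 g·cm/s, b0 = 400 g/s) in
systemic arteries and a constant 200 g/s in systemic veins and the pulmonary
circulation. Collapse pressures are not measured quantities; the defaults
(−119 mmHg arterial, −10 mmHg venous) give physiological stiffening
exponents and are exposed in `parameters.py`.

**Vascular beds.** Terminal arteries and veins of an organ or region meet in
an R–C–R–C–R ladder: per-arterial-terminal inlet resistances, a shared
arteriolar compliance node, a middle resistance, a shared venular compliance
node (which also carries the blood-volume source *S*), and
per-venous-terminal outlet resistances. The split of the bed totals
(0.4/0.4/0.2 for resistance, 0.1/0.9 for compliance) is configurable; the
behaviourally binding quantities are the totals. All bed resistances scale
with the arteriolar transmural pressure as
`R = R0(p_tm0 − p_zf)/(p_tm − p_zf)` above the zero-flow pressure
p_zf = 5 mmHg and shut the bed off below it (implemented as a conductance
factor so the zero-flow branch is a regular state). Coronary beds use
volume-dependent resistances `R_i = R0_i·V0_i²/V_i²` with compartment
volumes integrated from the intramyocardial compliances and a 0.75/0.25
layer weighting for the middle resistance; a volume floor of 5% of the
reference keeps the law finite. The element library (resistor, capacitor
with source, inductor) is exposed separately; the reduced closed-loop
network contains no coronary bed, so the coronary elements are exercised at
unit level.

**Heart and valves.** Each chamber's free-wall elastance is a
double-activation curve `E_fw = k·[g1/(1+g1)]·[1/(1+g2)] + E_min` with
`g_i = ((t − t_onset)/τ_i)^{m_i}` and timing parameters given as fractions
of the cardiac period, so contraction rates track heart rate. The
normalisation *k* is computed numerically so that the **peak of the product
curve equals E_max exactly** (writing the normalisation against either
factor alone would not make the peak land on E_max). Chamber pressure is
`P = P_pc + E_nat(V − V0) − R_s·Q + (E_nat/E_sep)·P*` with the source
resistance `R_s = K_s·E_nat(V − V0)`, the septal elastance
`E_sep = κ_L·E_fw,L + κ_R·E_fw,R` formed per ventricle and per atrium pair
(κ = 6 for ventricles, 2 for atria), the contralateral pressure P*, a piston
term `−μ_AV·Q_V` on the atrial native elastance (Q_V is the forward
atrioventricular valve flow), and a common exponential pericardial pressure
`P_pc = K_pc·exp[(V_pc − V0_pc)/Φ]` on the summed chamber volumes plus a
constant pericardial fluid. The pericardial constants are not part of the
tabulated parameter set; mild defaults (K_pc = 0.5 mmHg, V0 = 500 ml,
Φ = 45 ml, 30 ml fluid) are used and exposed. Valves obey
`ΔP = B·Q|Q| + L·∂Q/∂t` with `B = ρ/2A_eff²`, `L = ρ·l_eff/A_eff` and an
orifice `A_eff = (A_max − A_min)ζ + A_min` driven by
`dζ/dt = K_vo(1 − ζ)ΔP` when ΔP > 0 and `K_vc·ζ·ΔP` otherwise; the branch
is frozen per time step using the previously accepted ΔP so the within-step
residual stays smooth, ζ is clamped to [0, 1] on acceptance, and the
orifice is floored at 10⁻⁶ cm² so a closed valve is a huge-but-finite
Bernoulli resistance. Venous valves (one per 4 cm of systemic vein path,
none in the venae cavae) reuse the same element with the local vessel area
as maximal orifice; the reduced network leaves them out by default since
without gravity they are passive.

## Numerical scheme

All unknowns — nodal (A, P, Q) of every meshed vessel, bed compartment
pressures and element flows, chamber volumes and pressures, valve flows and
states — form one flat vector advanced by a monolithic Newton solve per time
step. Choices that matter:

- **Space:** 2-node element (box) integration of continuity and momentum —
  the trapezoid of the nodal time-derivative and friction terms plus exact
  differences of Q, P and the advective flux. Nodal collocation with central
  differences admits odd–even decoupled modes (observed as a violent
  checkerboard in short stiff vessels); the box form couples adjacent nodes
  directly, is second order, and telescopes to *exact* discrete mass
  conservation (closed-loop volume drift is at Newton tolerance). The tube
  law is collocated at nodes. Default spacing ≤ 1 cm with ≥ 3 nodes per
  vessel; the reduced networks run at 4–5 cm elements, which resolves their
  100–1000 cm/s waves at dt = 1 ms (the packaged tests and the acceptance
  runs use these sizes).
- **Time:** BDF2 with a backward-Euler first step; dt snapped so a cardiac
  period is an integer number of steps (cycles compare sample-by-sample).
  On a Newton failure the step is retried from the previous state and then
  sub-stepped (backward Euler, 2, 4, … substeps up to 5 halvings).
- **Couplings:** junction mass conservation and static-pressure continuity,
  1D–0D and 1D–heart attachments are exact linear constraint rows that
  replace the boundary continuity equations — the direct-elimination form of
  Lagrange-multiplier coupling. Being linear, they are satisfied to LU
  round-off after every Newton update, so junction mass defects sit at
  ~10⁻¹⁰ of the mean flow.
- **Newton:** finite-difference Jacobian compressed by greedy column
  colouring over a numerically detected sparsity structure (probed at
  randomized generic states with valves half open and all flows nonzero),
  column-scaled by unknown magnitudes and row-equilibrated before sparse LU
  (raw entries span ~10⁻¹⁰…10¹² because of the Voigt terms of the 0.2 mm
  spiral arteries). The factorisation is reused across steps and refreshed
  on a cadence, on valve phase changes, or when a backtracking line search
  on the equilibrated residual norm detects slow contraction. `|Q|` in the
  valve law is smoothed as `√(Q² + 10⁻⁶)` so the Jacobian stays accurate
  through closure. Convergence: relative step below 10⁻⁸, at most 50
  iterations.
- **Periodicity:** cycles are compared by the maximum over probe pressure
  and flow signals of the relative L2 difference between consecutive
  cycles, in percent; a run is periodic below 0.5%.

## Initial conditions

Flows start at zero everywhere; 1D pressures start at the per-compartment
reference pressures (systemic arteries at the participant's DBP, systemic
veins 5, hepatic portal 8.5, pulmonary arteries 11, pulmonary veins
10 mmHg) with areas at A0; chamber volumes at their tabulated initial
values; all valves closed. Bed compartments start at the reference
pressures of the vessels they bridge so that the initial state carries no
flow at all — seeding them at the reference transmural pressure instead
injects a startup shock through the near-rigid non-pregnant spiral
arteries. A sensitivity experiment (`initial_pressure_scale`) perturbs the
1D initial pressures with areas set consistently from the elastic branch;
after adaptation the converged waveforms agree with the unperturbed run to
well under 0.2% mean absolute percentage error, mirroring the reported
insensitivity of the full model.

## Participant adaptation

Measured inputs are heart rate, brachial SBP/DBP and cardiac output; height
scales every vessel length by γ = height/185.42 cm (areas unchanged).
Seeding: TPR = MAP/CO with MAP estimated as (2·DBP + SBP)/3; regional
resistances `R_region = TPR/α` from cardiac-output fractions α (the direct
product form α·TPR is dimensionally inconsistent with parallel fractions and
is available behind `distribute_resistance_literal`); within multi-bed
regions flow shares follow Murray-law weights on distal diameters
(exponent 2.76). Total arterial compliance C_T = 1.79 s / TPR; the meshed
1D tree's compliance Σ m·A0·L/(ρc0²) is subtracted and the 0D remainder
distributed ∝ α, with the venular share 9× the arteriolar. Pulmonary beds
have no measurements and are seeded for healthy mean pressures (6 mmHg
arterio-venous drop at the target CO, RC time 0.35 s).

Each iteration then: runs to periodicity, measures SBP/DBP (extrema of the
brachial midpoint pressure), MABP (sampled time average) and CO (mean aortic
valve flow), and applies three multiplicative controls with relaxation 0.8 —
systemic bed resistance × (MAP_t/MAP_m)^0.8, systemic arterial compliance ×
(PP_m/PP_t)^0.8 (1D wave speeds and arteriolar compliances together, so the
1D compliance distribution is preserved), and a volume increment
ΔV = 0.8·g·(SV_t − SV_m) injected equally across all beds' venular nodes
over one cycle, with the gain g refined by a secant estimate of dSV/dV. The
mean pressure driving the resistance control is the form-factor mean
(2·DBP + SBP)/3 evaluated identically on targets and model: together with
the pulse-pressure control this is a bijection of (SBP, DBP), so the
termination test on systolic and diastolic pressure individually can
actually be met — matching the *sampled* model mean to a form-factor target
instead would leave a waveform-shape offset of (k − ⅓)·PP in DBP that no
control could remove. The sampled time average remains the reported model
MABP. Termination (inclusive): |errors| on SBP, DBP and CO all ≤ 0.5% *and*
cycle-to-cycle change ≤ 0.5%. The relaxation adapts: it halves (down to 0.1)
if the worst error grows three iterations running, and recovers by ×1.4 (up
to its 0.8 default) once errors shrink steadily — without the recovery a
transient early in the run can leave the controller crawling.

## Regional cardiac-output fractions

The utero-ovarian region takes a stage-dependent fraction of cardiac output
(uterine + placental beds combined): 0.6% post-partum, 3.5% in the first
trimester, 8% in the second, 12% at term, with 0.4% to the ovaries — the
pregnant values follow the published physiological range for the uterine
supply (≈3.5% early rising to ≈12% at term), the post-partum value the
sub-percent non-pregnant uterine share. Within the region, beds split by
Murray-law weights on their distal (spiral) diameters. Remaining systemic
beds scale their per-network hints (arm 0.15/body 0.85 in the reduced loop)
to close the budget. Trimester-1/2 vessel geometry interpolates the
reference areas linearly between the non-pregnant and late-pregnancy columns
with weights ⅓ and ⅔ (configurable) — only the two endpoint states are
tabulated.

## Reduced networks and the synthetic generator

The packaged `mini_closed_loop` (aorta → brachial + descending arteries, arm
and body beds, matching veins and a vena cava into the right atrium, a
pulmonary artery/bed/vein loop into the left atrium) makes every closed-loop
workflow desk-scale; the utero-ovarian table plugs into its descending
artery for pregnancy configurations. Since the left and right utero-ovarian sides are mirror images and their
solutions identical by symmetry, the default
attachment builds one side with doubled multiplicities — exactly the
symmetric solution at half the unknown count (`sides="both"` builds both).

Synthetic target records emulate the measured inputs: per-stage draws with
HR 70–95 bpm pregnant (60–80 post-partum), DBP 60–80 mmHg, pulse pressure
within the published 37–61 mmHg span (per-stage sub-ranges anchored to the
preset clinical trajectories), CO 4–9 L/min pregnant (3.5–6 post-partum), height
155–180 cm; deterministic under (stage, seed). Participant-like preset
trajectories carry published per-stage pulse pressures and heights, with
plausible synthetic fill-ins for DBP, HR and CO (marked as such). What
passing tests show is therefore that the *pipeline* — seeding, closed-loop
dynamics, adaptation, indices — behaves correctly over realistic input
ranges; they do not validate against any individual's measured waveforms,
which are not published.

## Known limitations

- No gravity, vessel collapse, baroreflex or autoregulation; heart
  parameters fixed across gestation (afterload/preload/heart-rate effects
  enter implicitly).
- The reduced loop lumps the systemic periphery into two beds, so wave
  reflections are cruder than in the full 513-vessel geometry; uterine flow
  *fractions* follow the α table but absolute uterine flows sit below the
  published full-network values because the non-pregnant spiral/arcuate path
  resistance adds to the allocated bed resistance.
- Trimester-1/2 geometry interpolation and the pericardial constants are
  modelling choices, not tabulated data.
- The qualitative stage runs (notch, PI ordering) are read at a 1%
  periodicity threshold; the slow venular-compliance transients of the tiny
  uterine beds take tens of cycles more to meet 0.5% without changing the
  waveform shape quantities.
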