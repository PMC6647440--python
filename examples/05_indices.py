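"""Derived clinical indices from a converged run.

Computes the model-side mean arterial pressure (sampled time average at the
brachial midpoint), both total-peripheral-resistance estimators in device
units (mmHg min/L x 80), the local pulse-wave-velocity estimate PWV = c0,
and a two-site transit PWV from the foot-of-wave delay between the aortic
and brachial midpoints.
"""
from uteroflow import (GlobalSystem, ParticipantTargets, SolverConfig,
                       build_mini_closed_loop, run_to_periodic)
from uteroflow.adaptation import estimate_initial_parameters, measure_cycle
from uteroflow.indices import (local_pwv, mabp, pwv_brachial_ankle,
                               tpr_variants, waveform_from_record)

targets = ParticipantTargets(HR=70, SBP=120, DBP=80, CO=5.0, stage="PP")
net = build_mini_closed_loop()
estimate_initial_parameters(net, targets)
system = GlobalSystem(net, stage="PP", dbp_mmhg=targets.DBP,
                      heart_rate_bpm=targets.HR, config=SolverConfig(dx_max=5.0))
rec, _ = run_to_periodic(system)

aorta_i = next(i for i, p in enumerate(system.probes) if p.segment_id == 1)
brachial_i = next(i for i, p in enumerate(system.probes) if p.segment_id == 2)
wf_a = waveform_from_record(system, rec, aorta_i)      # 10 cm from the valve
wf_b = waveform_from_record(system, rec, brachial_i)   # 30 cm from the valve
meas = measure_cycle(system, rec, brachial_i)

print(f"MABP (sampled mean) = {mabp(wf_b):.1f} mmHg; "
      f"SBP/DBP = {meas.SBP:.1f}/{meas.DBP:.1f} mmHg; CO = {meas.CO:.2f} L/min")
tpr = tpr_variants(meas.CO, mabp_mmhg=meas.MABP, sbp=meas.SBP, dbp=meas.DBP)
print(f"TPR from sampled mean: {tpr['ptpr_mean']:.0f}; "
      f"from (2DBP+SBP)/3: {tpr['tpr_ff']:.0f}  (mmHg min/L x 80)")
print(f"local PWV at the aorta (reference wave speed): "
      f"{local_pwv(system, 1):.0f} cm/s")
v = pwv_brachial_ankle(wf_a, wf_b, L_brachial=10.0, L_ankle=30.0)
print(f"two-site transit PWV (aorta mid -> brachial mid): {v:.0f} cm/s")
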