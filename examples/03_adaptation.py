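"""Adapt the closed loop to a synthetic participant record.

Draws a reproducible post-partum target record, then iterates the three
controls (systemic bed resistance -> mean pressure, systemic arterial
compliance -> pulse pressure, blood volume -> stroke volume) until the model
matches systolic/diastolic pressure and cardiac output to +-0.5%.
"""
from uteroflow import GlobalSystem, SolverConfig, build_mini_closed_loop, make_synthetic_targets
from uteroflow.adaptation import estimate_initial_parameters, run_adaptation
from uteroflow.builders import BRACHIAL_SEGMENT

case = make_synthetic_targets("PP", seed=1)
tg = case.targets
print(f"targets: HR {tg.HR:.1f} bpm, {tg.SBP:.1f}/{tg.DBP:.1f} mmHg, "
      f"CO {tg.CO:.2f} L/min (SV {tg.SV:.1f} ml)")

net = build_mini_closed_loop()
estimate_initial_parameters(net, tg)
system = GlobalSystem(net, stage=tg.stage, dbp_mmhg=tg.DBP,
                      heart_rate_bpm=tg.HR, config=SolverConfig(dx_max=5.0))
res = run_adaptation(system, tg, brachial_segment_id=BRACHIAL_SEGMENT)

m = res.measurement
print(f"converged = {res.converged} after {res.iterations} iterations")
print(f"model: {m.SBP:.1f}/{m.DBP:.1f} mmHg (MABP {m.MABP:.1f}), "
      f"CO {m.CO:.3f} L/min")
print("errors (%):", {k: f"{v:+.2f}" for k, v in res.errors_pct.items()},
      f"| final cycle change {res.cycle_metric_pct:.2f}%")
print(f"controls: resistance x{res.state.resistance_scale:.3f}, "
      f"compliance x{res.state.compliance_scale:.3f}, "
      f"blood volume {res.state.added_volume:+.0f} ml")
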