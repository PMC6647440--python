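"""Shared fixtures.

The expensive closed-loop computations (adaptation runs on the reduced
closed-loop network, pregnancy-stage runs with the utero-ovarian circuit)
are session-scoped and shared across test modules.
"""
from __future__ import annotations

import numpy as np
import pytest

from uteroflow.adaptation import estimate_initial_parameters, run_adaptation
from uteroflow.builders import BRACHIAL_SEGMENT, attach_uteroovarian, build_mini_closed_loop
from uteroflow.synthetic import make_synthetic_targets, preset_targets
from uteroflow.system import CycleMonitor, GlobalSystem, SolverConfig, run_to_periodic

#: coarse-but-adequate resolution for the reduced networks (documented choice:
#: elements no longer than 5 cm resolve the ~100-1000 cm/s waves at dt = 1 ms)
MINI_CFG = dict(dx_max=5.0)
STAGE_CFG = dict(dx_max=4.0)


def build_adapted(initial_pressure_scale=1.0):
    case = make_synthetic_targets("PP", seed=1)
    net = build_mini_closed_loop()
    estimate_initial_parameters(net, case.targets)
    system = GlobalSystem(net, stage="PP", dbp_mmhg=case.targets.DBP,
                          heart_rate_bpm=case.targets.HR,
                          config=SolverConfig(**MINI_CFG),
                          initial_pressure_scale=initial_pressure_scale)
    result = run_adaptation(system, case.targets,
                            brachial_segment_id=BRACHIAL_SEGMENT)
    return case, result


@pytest.fixture(scope="session")
def adapted_mini():
    """Full adaptation of the mini closed loop to synthetic post-partum
    targets (seed 1)."""
    return build_adapted()


@pytest.fixture(scope="session")
def adapted_mini_perturbed():
    """The same adaptation started from +10% initial 1D pressures."""
    return build_adapted(initial_pressure_scale=1.1)


@pytest.fixture(scope="session")
def stage_runs():
    """Periodic runs of the mini loop + utero-ovarian circuit for each
    gestational stage (participant-A-like presets).

    Run to a 1% cycle-to-cycle change: the waveform shape quantities examined
    (notch presence, pulsatility-index ordering) are stable well before the
    slow venular-compliance drift meets the 0.5% production threshold.
    """
    out = {}
    for stage in ("PP", "T1", "T2", "T3"):
        tg = preset_targets("A", stage)
        net = attach_uteroovarian(stage, sides="merged")
        estimate_initial_parameters(net, tg)
        system = GlobalSystem(net, stage=stage, dbp_mmhg=tg.DBP,
                              heart_rate_bpm=tg.HR,
                              config=SolverConfig(**STAGE_CFG))
        rec, mon = run_to_periodic(system, tol_pct=1.0)
        out[stage] = (system, rec, mon)
    return out


def probe_index(system, segment_id):
    return next(i for i, pr in enumerate(system.probes)
                if pr.segment_id == segment_id)
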