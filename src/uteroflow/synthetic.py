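"""Synthetic participant-target generator.

Individual measured participant records are not part of the package, so
tests and examples draw physiologically anchored synthetic targets: pulse
pressures within the 37-61 mm Hg span reported across pregnancy, normal-range
mean pressures, cardiac output 4-9 L/min while pregnant, and post-partum
ranges typical of healthy non-pregnant adults.  All draws are deterministic
under (stage, seed).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adaptation import ParticipantTargets
from .network import STAGES

#: per-stage draw ranges: HR bpm, DBP mm Hg, pulse pressure mm Hg, CO L/min
RANGES = {
    "T1": {"HR": (70, 95), "DBP": (60, 80), "PP": (40, 50), "CO": (4, 9)},
    "T2": {"HR": (70, 95), "DBP": (60, 80), "PP": (39, 61), "CO": (4, 9)},
    "T3": {"HR": (70, 95), "DBP": (60, 80), "PP": (40, 48), "CO": (4, 9)},
    "PP": {"HR": (60, 80), "DBP": (60, 80), "PP": (37, 44), "CO": (3.5, 6)},
}
HEIGHT_RANGE = (155.0, 180.0)


@dataclass(frozen=True)
class SyntheticCase:
    seed: int
    stage: str
    targets: ParticipantTargets
    note: str = "synthetic targets (anchored to published population ranges)"


def make_synthetic_targets(stage: str, seed: int) -> SyntheticCase:
    """Draw one reproducible synthetic target record for a gestational stage."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    rng = np.random.default_rng([int(seed) % (2 ** 31), STAGES.index(stage)])
    r = RANGES[stage]
    hr = rng.uniform(*r["HR"])
    dbp = rng.uniform(*r["DBP"])
    pp = rng.uniform(*r["PP"])
    co = rng.uniform(*r["CO"])
    height = rng.uniform(*HEIGHT_RANGE)
    targets = ParticipantTargets(HR=hr, SBP=dbp + pp, DBP=dbp, CO=co,
                                 height=height, stage=stage,
                                 label=f"synthetic-{stage}-{seed}")
    return SyntheticCase(seed=seed, stage=stage, targets=targets)


#: participant-like preset trajectories.  Pulse pressures and heights follow
#: published per-stage clinical values; heart rate, diastolic pressure and cardiac
#: output are plausible synthetic fill-ins (not measured values).
PRESETS = {
    "A": {"height": 164.6,
          "PP_mmHg": {"T1": 47.0, "T2": 61.0, "T3": 43.0, "PP": 37.0},
          "DBP": {"T1": 68.0, "T2": 62.0, "T3": 70.0, "PP": 72.0},
          "CO": {"T1": 4.2, "T2": 5.6, "T3": 5.0, "PP": 4.4},
          "HR": {"T1": 82.0, "T2": 86.0, "T3": 88.0, "PP": 70.0}},
    "B": {"height": 168.0,
          "PP_mmHg": {"T1": 44.0, "T2": 39.0, "T3": 42.0, "PP": 44.0},
          "DBP": {"T1": 64.0, "T2": 68.0, "T3": 72.0, "PP": 70.0},
          "CO": {"T1": 8.0, "T2": 7.2, "T3": 5.8, "PP": 4.6},
          "HR": {"T1": 88.0, "T2": 86.0, "T3": 84.0, "PP": 72.0}},
}


def preset_targets(participant: str, stage: str) -> ParticipantTargets:
    p = PRESETS[participant]
    dbp = p["DBP"][stage]
    return ParticipantTargets(HR=p["HR"][stage], SBP=dbp + p["PP_mmHg"][stage],
                              DBP=dbp, CO=p["CO"][stage], height=p["height"],
                              stage=stage, label=f"preset-{participant}-{stage}")
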