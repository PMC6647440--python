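"""Packaged reduced networks.

``build_mini_closed_loop`` constructs a desk-scale closed loop: an aortic
artery that bifurcates into a brachial-like probe artery and a descending
artery, two systemic beds (arm, body), matching veins joining a vena cava
into the right atrium, and a pulmonary artery/bed/vein loop.  It stands in
for the full 513-vessel systemic geometry in every closed-loop test; the
utero-ovarian vessel table plugs into its descending artery for the
pregnancy configurations.
"""
from __future__ import annotations

from dataclasses import replace

from .network import (NetworkModel, RIGHT_SIDE_OFFSET, UO_ARTERIAL_INLETS,
                      UO_VENOUS_OUTLETS, VascularBedSpec, VesselSegment,
                      area_to_diameter, build_uteroovarian, diameter_to_area,
                      murray_fill, vein_from_artery)

ARM_BED, BODY_BED, LUNG_BED = 11, 12, 13
BRACHIAL_SEGMENT = 2
AORTA_SEGMENT = 1

AORTA_AREA = 4.5          # cm^2
ARM_FLOW_FRACTION = 0.15  # of systemic cardiac output


def build_mini_closed_loop() -> NetworkModel:
    """Reduced closed loop whose branch areas follow the package's own
    diameter rules: the aortic bifurcation is filled by Murray's law with the
    regional flow fractions as weights (an impedance-matched branch point —
    a crude mismatch reflects enough wave energy to distort the aortic-valve
    dynamics), and veins take 1.25x their artery's diameter."""
    net = NetworkModel(closed_loop=True)
    S = VesselSegment
    d_aorta = area_to_diameter(AORTA_AREA)
    d_arm, d_body = murray_fill(d_aorta, 2,
                                [ARM_FLOW_FRACTION, 1.0 - ARM_FLOW_FRACTION])
    a_arm, a_body = diameter_to_area(d_arm), diameter_to_area(d_body)
    av_arm, av_body = vein_from_artery(a_arm), vein_from_artery(a_body)
    d_vc = (area_to_diameter(av_arm) ** 2.76
            + area_to_diameter(av_body) ** 2.76) ** (1 / 2.76)
    a_vc = diameter_to_area(d_vc)
    segs = [
        S(1, "aorta", 20.0, AORTA_AREA, AORTA_AREA,
          region="systemic_artery", parent_ids=("AV",)),
        S(2, "left brachial artery", 20.0, a_arm, a_arm,
          region="systemic_artery", parent_ids=(1,), bed_id=ARM_BED),
        S(3, "descending artery", 20.0, a_body, a_body,
          region="systemic_artery", parent_ids=(1,), bed_id=BODY_BED),
        S(4, "arm vein", 20.0, av_arm, av_arm, region="systemic_vein",
          parent_ids=("bed:11",)),
        S(5, "body vein", 20.0, av_body, av_body, region="systemic_vein",
          parent_ids=("bed:12",)),
        S(6, "vena cava", 10.0, a_vc, a_vc, region="systemic_vein",
          parent_ids=(4, 5), bed_id="RA", is_vena_cava=True),
        S(7, "pulmonary artery", 5.0, 4.0, 4.0, region="pulmonary_artery",
          parent_ids=("PV",), bed_id=LUNG_BED),
        S(8, "pulmonary vein", 5.0, 4.5, 4.5, region="pulmonary_vein",
          parent_ids=("bed:13",), bed_id="LA"),
    ]
    for s in segs:
        net.segments[s.id] = s
    net.beds[ARM_BED] = VascularBedSpec(ARM_BED, "arm", [2], [4], alpha=0.15)
    net.beds[BODY_BED] = VascularBedSpec(BODY_BED, "body", [3], [5], alpha=0.85)
    net.beds[LUNG_BED] = VascularBedSpec(LUNG_BED, "lung", [7], [8])
    net.heart = {"AV": 1, "PV": 7, "RA": [6], "LA": [8]}
    net.validate()
    return net


def attach_uteroovarian(stage: str, sides: str = "merged") -> NetworkModel:
    """Mini closed loop with the utero-ovarian table wired into the
    descending artery and the body vein.

    With ``sides='merged'`` the left/right symmetry of the loop is exploited:
    one side is built with doubled multiplicities, which is the exact
    symmetric solution at half the unknown count.
    """
    net = build_mini_closed_loop()
    frag = build_uteroovarian(stage, sides=sides)
    # the body bed moves onto short perfusion stubs so the descending artery
    # can also feed the utero-ovarian inlets through a junction
    net.segments[3] = replace(net.segments[3], bed_id=None)
    a_body = net.segments[3].area_ref_np
    a_stub = 0.96 * a_body   # the utero-ovarian take-off carries a few % of flow
    net.segments[9] = VesselSegment(9, "body perfusion artery", 3.0, a_stub,
                                    a_stub, region="systemic_artery",
                                    parent_ids=(3,), bed_id=BODY_BED)
    av_stub = vein_from_artery(a_stub)
    net.segments[10] = VesselSegment(10, "body perfusion vein", 3.0, av_stub,
                                     av_stub, region="systemic_vein",
                                     parent_ids=("bed:12",))
    net.beds[BODY_BED].arterial_terminal_ids = [9]
    net.beds[BODY_BED].venous_terminal_ids = [10]
    for bid, bed in frag.beds.items():
        net.beds[bid] = bed
    for sid, seg in frag.segments.items():
        net.segments[sid] = seg
    offsets = [0] + ([RIGHT_SIDE_OFFSET] if sides == "both" else [])
    vein_parents = [10]
    for off in offsets:
        for sid in UO_ARTERIAL_INLETS:
            seg = net.segments[sid + off]
            net.segments[sid + off] = replace(seg, parent_ids=(3,))
        vein_parents += [sid + off for sid in UO_VENOUS_OUTLETS]
    net.segments[5] = replace(net.segments[5], parent_ids=tuple(vein_parents))
    net.validate()
    return net
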