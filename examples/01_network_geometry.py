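"""Load the packaged utero-ovarian vessel table and derive its geometry.

Builds the non-pregnant and term-pregnancy variants of the utero-ovarian
circuit, prints the lumen diameters the model works with and the wave speeds
the empirical stiffness law assigns, and shows the height-based length
scaling used to personalise the network.
"""
from uteroflow import ParticipantInfo, area_to_diameter, build_uteroovarian, scale_lengths
from uteroflow.network import init_wave_speed

for stage in ("PP", "T3"):
    net = build_uteroovarian(stage, sides="left")
    asc = net.segments[67]       # ascending uterine artery
    spiral = net.segments[66]    # radial/spiral arteries (x50)
    d_asc = area_to_diameter(asc.area_ref(stage))
    d_sp = area_to_diameter(spiral.area_ref(stage))
    print(f"stage {stage}: ascending uterine artery D = {d_asc * 10:.2f} mm "
          f"(c0 = {init_wave_speed(d_asc, 'systemic_artery'):.0f} cm/s), "
          f"spiral artery D = {d_sp * 10:.2f} mm")

# vessel lengths scale with participant height relative to the 6 ft 1 in base
net = build_uteroovarian("T3", sides="left")
short = scale_lengths(net, ParticipantInfo("A", 36, 164.6, "T3"))
print(f"communicating artery: {net.segments[64].length:.2f} cm at base height,"
      f" {short.segments[64].length:.3f} cm for a 164.6 cm participant")
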