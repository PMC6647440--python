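"""Unit conversions.

All internal state is CGS (cm, g, s; pressure in dyn/cm^2, flow in cm^3/s).
User-facing I/O follows clinical conventions: pressures in mm Hg, cardiac
output in L/min, compliances in ml/mm Hg, resistances in mm Hg min/L (the
"Wood unit" as printed by monitoring devices) or the CGS dyn s/cm^5 obtained
with the factor 80.
"""

MMHG = 1333.22  # dyn/cm^2 per mm Hg

#: dyn s/cm^5 per (mm Hg min/L): 1333.22 * 60 / 1000 = 79.99 ~ the device's "80"
WOOD_TO_CGS = MMHG * 60.0 / 1000.0


def mmhg_to_cgs(p):
    return p * MMHG


def cgs_to_mmhg(p):
    return p / MMHG


def lmin_to_mls(q):
    """L/min -> cm^3/s."""
    return q * 1000.0 / 60.0


def mls_to_lmin(q):
    """cm^3/s -> L/min."""
    return q * 60.0 / 1000.0


def wood_to_cgs(r):
    """mm Hg min/L -> dyn s/cm^5."""
    return r * WOOD_TO_CGS


def cgs_to_wood(r):
    """dyn s/cm^5 -> mm Hg min/L."""
    return r / WOOD_TO_CGS


def compliance_mlmmhg_to_cgs(c):
    """ml/mm Hg -> cm^5/dyn."""
    return c / MMHG


def compliance_cgs_to_mlmmhg(c):
    """cm^5/dyn -> ml/mm Hg."""
    return c * MMHG
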