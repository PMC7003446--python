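"""Unit conversions.

The package works internally in CGS (cm, g, s, dyn). Pressures are reported
in mmHg and material moduli are specified in kPa at the interface layer.
"""

MMHG_TO_DYN_CM2 = 1333.22
KPA_TO_DYN_CM2 = 1.0e4
ML_TO_CM3 = 1.0  # 1 mL == 1 cm^3
MM_TO_CM = 0.1
ERG = 1.0  # 1 erg == 1 dyn*cm


def mmhg(p):
    """Pressure in mmHg -> dyn/cm^2."""
    return p * MMHG_TO_DYN_CM2


def to_mmhg(p):
    """Pressure in dyn/cm^2 -> mmHg."""
    return p / MMHG_TO_DYN_CM2


def kpa(s):
    """Stress/modulus in kPa -> dyn/cm^2."""
    return s * KPA_TO_DYN_CM2


def to_kpa(s):
    return s / KPA_TO_DYN_CM2
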