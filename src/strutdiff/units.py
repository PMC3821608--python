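"""Centralized unit conversions.

Public quantities use the field's customary mixed units (cm^2/s for
diffusivities, micrometers for lengths, seconds or hours for time, mol/m^3
for concentrations); internal numerics are SI.  Every conversion in the
package goes through these helpers so the factors are written (and tested)
exactly once.
"""

UM_PER_CM = 1.0e4
M_PER_UM = 1.0e-6
M2_PER_CM2 = 1.0e-4
UM2_PER_CM2 = 1.0e8
S_PER_HR = 3600.0
HR_PER_DAY = 24.0


def cm2s_to_um2s(d: float) -> float:
    """Diffusivity cm^2/s -> um^2/s."""
    return d * UM2_PER_CM2


def cm2s_to_m2s(d: float) -> float:
    """Diffusivity cm^2/s -> m^2/s."""
    return d * M2_PER_CM2


def um_to_cm(x: float) -> float:
    return x / UM_PER_CM


def um_to_m(x: float) -> float:
    return x * M_PER_UM


def hours_to_seconds(t: float) -> float:
    return t * S_PER_HR


def hours_to_days(t: float) -> float:
    return t / HR_PER_DAY
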