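"""Centralized unit conversions.

Internally the toolkit works in SI (Pa, s, m, W/m^3); interfaces use the
field-conventional mm / ms / MPa / dB. Keeping every conversion factor here
avoids scattered magic constants.
"""

MPA_TO_PA = 1.0e6
PA_TO_MPA = 1.0e-6
MM_TO_M = 1.0e-3
M_TO_MM = 1.0e3
MS_TO_S = 1.0e-3
S_TO_MS = 1.0e3
MHZ_TO_HZ = 1.0e6
HZ_TO_MHZ = 1.0e-6
MIN_TO_S = 60.0
S_TO_MIN = 1.0 / 60.0


def db_to_amplitude_ratio(db: float) -> float:
    """Convert an attenuation in dB to a (pressure-)amplitude ratio."""
    return 10.0 ** (-db / 20.0)


def truncate(value: float, decimals: int) -> float:
    """Truncate (not round) toward zero at ``decimals`` decimal places.

    Printed treatment-console tables truncate trailing digits (13.333 ms is
    printed as 13.3, a 6.667% duty cycle as 6.66), so comparisons against
    printed values must truncate the computed number first.
    """
    factor = 10.0**decimals
    return int(value * factor) / factor
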