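"""Radionuclide physics constants shared by simulation and quantification."""

from __future__ import annotations

__all__ = ["TC99M_HALF_LIFE_H", "decay_factor"]

#: Tc-99m physical half-life (hours)
TC99M_HALF_LIFE_H = 6.0058


def decay_factor(minutes: float, half_life_h: float = TC99M_HALF_LIFE_H) -> float:
    """Fraction of activity remaining ``minutes`` after calibration."""
    return float(2.0 ** (-minutes / (half_life_h * 60.0)))
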