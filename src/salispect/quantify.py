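"""Per-gland VOI quantification (%ID, %EF, volume) and dose bookkeeping.

%ID of a gland is the activity inside its VOI divided by the administered
activity, times 100.  Activities are handled in Bq internally and reported
in MBq.  By default the reference activity is decay-corrected to the
acquisition time with the Tc-99m physical half-life (6.0058 h), so %ID
reflects tracer biology rather than physical decay and %EF — computed as
100 x (20-min %ID - 40-min %ID) / 20-min %ID — is not inflated by decay
between the two timepoints.  The correction is toggleable.

Dose bookkeeping follows the standard coefficients route: tracer effective
dose = injected activity x mSv/MBq coefficient; CT effective dose =
dose-length product x head-region mSv per mGy.cm coefficient; the protocol
dose is their sum over sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .physics import TC99M_HALF_LIFE_H, decay_factor
from .volumes import GLAND_CODES, GLAND_NAMES, CalibratedVolume, GlandLabelMap

__all__ = [
    "GlandQuant",
    "DoseInputs",
    "UndefinedExcretionError",
    "percent_injected_dose",
    "excretion_fraction",
    "voi_volume",
    "quantify_study",
    "tracer_effective_dose",
    "ct_effective_dose",
    "protocol_effective_dose",
    "round_reported",
]

#: pertechnetate effective-dose coefficient, mSv per MBq (adult)
PERTECHNETATE_MSV_PER_MBQ = 0.013
#: head-region DLP-to-effective-dose conversion, mSv per mGy.cm
HEAD_DLP_COEFF_MSV_PER_MGY_CM = 0.0031


class UndefinedExcretionError(ValueError):
    """%EF is undefined when the 20-min %ID is not positive."""


@dataclass
class GlandQuant:
    """Quantification result for one gland VOI."""

    gland_code: int
    voi_volume_mL: float
    pid20: float
    pid40: float

    def __post_init__(self) -> None:
        if self.voi_volume_mL < 0 or self.pid20 < 0 or self.pid40 < 0:
            raise ValueError("volumes and %ID values must be non-negative")

    @property
    def gland_name(self) -> str:
        return GLAND_NAMES.get(self.gland_code, str(self.gland_code))

    @property
    def ef_percent(self) -> Optional[float]:
        if self.pid20 <= 0:
            return None
        return excretion_fraction(self.pid20, self.pid40)


@dataclass
class DoseInputs:
    """Inputs of the protocol radiation-dose accounting."""

    injected_activity_MBq: float = 555.0
    tracer_coeff_mSv_per_MBq: float = PERTECHNETATE_MSV_PER_MBQ
    dlp_mGy_cm: float = 60.31
    ctdi_vol_mGy: float = 1.49
    head_dlp_coeff: float = HEAD_DLP_COEFF_MSV_PER_MGY_CM
    n_ct_sessions: int = 1

    def __post_init__(self) -> None:
        vals = (
            self.injected_activity_MBq,
            self.tracer_coeff_mSv_per_MBq,
            self.dlp_mGy_cm,
            self.ctdi_vol_mGy,
            self.head_dlp_coeff,
        )
        if any(v < 0 for v in vals) or self.n_ct_sessions < 0:
            raise ValueError("dose inputs must be non-negative")

    def tracer_dose_mSv(self) -> float:
        return tracer_effective_dose(self.injected_activity_MBq, self.tracer_coeff_mSv_per_MBq)

    def ct_dose_mSv(self) -> float:
        return ct_effective_dose(self.dlp_mGy_cm * self.n_ct_sessions, self.head_dlp_coeff)

    def total_mSv(self) -> float:
        return protocol_effective_dose(
            self.tracer_dose_mSv(),
            [ct_effective_dose(self.dlp_mGy_cm, self.head_dlp_coeff)] * self.n_ct_sessions,
        )


def round_reported(x: float, ndigits: int = 2) -> float:
    """Round half-up at ``ndigits`` decimals, as clinical reports print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# VOI quantification
# ---------------------------------------------------------------------------

def percent_injected_dose(
    spect: CalibratedVolume,
    labels: GlandLabelMap,
    injected_activity_MBq: float,
    decay_correct: bool = True,
    time_post_injection_min: Optional[float] = None,
    half_life_h: float = TC99M_HALF_LIFE_H,
) -> dict[int, float]:
    """Per-gland %ID from a SPECT volume and a gland label map.

    The gland activity is the sum of concentration x voxel volume over the
    gland's voxels.  The reference is the injected activity, decayed to
    the acquisition time when ``decay_correct`` is on.
    """
    if injected_activity_MBq <= 0:
        raise ValueError("injected activity must be positive")
    if spect.modality != "SPECT":
        raise ValueError("percent_injected_dose requires a SPECT volume")
    if spect.shape != labels.shape or not np.allclose(spect.spacing, labels.spacing):
        raise ValueError("labels must be on the SPECT grid (resample first)")
    ref_bq = injected_activity_MBq * 1e6
    if decay_correct:
        t = time_post_injection_min
        if t is None:
            t = spect.time_post_injection_min
        if t is None:
            raise ValueError("decay correction requires the acquisition time post-injection")
        ref_bq *= decay_factor(t, half_life_h)
    vox_mL = labels.voxel_volume_mL
    out = {}
    for code in GLAND_CODES:
        m = labels.labels == code
        act_bq = float(spect.voxels[m].sum(dtype=np.float64)) * vox_mL
        out[code] = 100.0 * act_bq / ref_bq
    return out


def excretion_fraction(pid20: float, pid40: float) -> float:
    """Percent excretion fraction, 100 x (pid20 - pid40) / pid20."""
    if pid20 <= 0:
        raise UndefinedExcretionError("%EF undefined for non-positive 20-min %ID")
    if pid40 < 0:
        raise ValueError("40-min %ID must be non-negative")
    return 100.0 * (pid20 - pid40) / pid20


def voi_volume(labels: GlandLabelMap) -> dict[int, float]:
    """Per-gland VOI volume in mL (voxel count x voxel volume)."""
    vox_mL = labels.voxel_volume_mL
    return {code: float((labels.labels == code).sum()) * vox_mL for code in GLAND_CODES}


def quantify_study(
    spect20: CalibratedVolume,
    spect40: CalibratedVolume,
    labels: GlandLabelMap,
    injected_activity_MBq: float,
    decay_correct: bool = True,
    sum_lateral: bool = False,
) -> list[GlandQuant]:
    """Full per-gland quantification of a two-timepoint study.

    With ``sum_lateral`` the left and right glands of each type are merged
    into one VOI before quantification (reported under the right-side code).
    """
    pid20 = percent_injected_dose(
        spect20, labels, injected_activity_MBq, decay_correct, time_post_injection_min=20.0
    )
    pid40 = percent_injected_dose(
        spect40, labels, injected_activity_MBq, decay_correct, time_post_injection_min=40.0
    )
    vols = voi_volume(labels)
    if sum_lateral:
        groups = {1: (1, 2), 3: (3, 4)}
        return [
            GlandQuant(
                gland_code=k,
                voi_volume_mL=sum(vols[c] for c in cs),
                pid20=sum(pid20[c] for c in cs),
                pid40=sum(pid40[c] for c in cs),
            )
            for k, cs in groups.items()
        ]
    return [
        GlandQuant(gland_code=c, voi_volume_mL=vols[c], pid20=pid20[c], pid40=pid40[c])
        for c in GLAND_CODES
    ]


def quant_table(quants: Iterable[GlandQuant], study_id: str = "") -> pd.DataFrame:
    """Tabulate GlandQuant records (columns: study_id, gland, voi_mL, pid20, pid40, ef)."""
    rows = []
    for q in quants:
        rows.append(
            {
                "study_id": study_id,
                "gland": q.gland_name,
                "voi_mL": q.voi_volume_mL,
                "pid20": q.pid20,
                "pid40": q.pid40,
                "ef": q.ef_percent if q.ef_percent is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Radiation dose accounting
# ---------------------------------------------------------------------------

def tracer_effective_dose(
    injected_activity_MBq: float, coeff_mSv_per_MBq: float = PERTECHNETATE_MSV_PER_MBQ
) -> float:
    """Effective dose (mSv) of the administered tracer activity."""
    if injected_activity_MBq < 0 or coeff_mSv_per_MBq < 0:
        raise ValueError("dose inputs must be non-negative")
    return injected_activity_MBq * coeff_mSv_per_MBq


def ct_effective_dose(
    dlp_mGy_cm: float, k: float = HEAD_DLP_COEFF_MSV_PER_MGY_CM
) -> float:
    """CT effective dose (mSv) from a dose-length product."""
    if dlp_mGy_cm < 0 or k < 0:
        raise ValueError("dose inputs must be non-negative")
    return dlp_mGy_cm * k


def protocol_effective_dose(tracer_mSv: float, ct_session_mSv: Sequence[float]) -> float:
    """Total protocol effective dose: tracer plus all CT sessions."""
    if tracer_mSv < 0 or any(d < 0 for d in ct_session_mSv):
        raise ValueError("dose components must be non-negative")
    return float(tracer_mSv + sum(ct_session_mSv))
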