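"""Synthetic head-and-neck SPECT/CT phantoms with known gland kinetics.

Every downstream stage of the pipeline (cropping, network training, rigid
misregistration correction, %ID/%EF quantification, agreement statistics)
is exercised on these phantoms, since no patient data ship with the
package.  A phantom emulates a neck field of view: a body ellipsoid in air
with a spinal bone column, four salivary-gland ellipsoids (right/left parotid and
submandibular) of realistic volume, a thyroid and an oral cavity.  The CT
carries the structures as Hounsfield levels plus voxel noise; the SPECT
carries Tc-99m pertechnetate activity with programmed per-gland %ID and
%EF, Gaussian system blur (PSF), Poisson counting noise, physical decay
and a random rigid misalignment of the post-stimulation acquisition.

Programmed %ID semantics: the per-gland %ID is defined as the value a
truth-VOI measurement recovers from the blurred, pre-noise activity map —
i.e. the same quantity the reference ranges describe, which are themselves
VOI measurements on resolution-limited SPECT.  The generator calibrates
each gland's pre-blur concentration linearly so the truth-VOI sum
(including background/thyroid/oral spill-in) hits the programmed value
exactly; recovery error on noiseless phantoms is then limited only by
inter-gland spill (~0.1%).

A rater model emulates manual segmentation as performed clinically:
contours drawn on every 2nd-3rd axial slice with occasional one-voxel
over/under-segmentation, intermediate slices filled by shape-based
(signed-distance) interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import ndimage

from .physics import decay_factor
from .registration import RigidTransform, apply_alignment
from .volumes import GLAND_CODES, CalibratedVolume, GlandLabelMap, StudyRecord

__all__ = [
    "PhantomSpec",
    "generate_study",
    "generate_cohort",
    "simulate_manual_labels",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic study population.

    Defaults are the study conditions: gland volumes 23.43 +/- 10.42 mL
    (parotid) and 11.57 +/- 4.48 mL (submandibular); 20-min %ID
    0.36 +/- 0.11 and 0.17 +/- 0.09; %EF 61.41 +/- 9.04 and
    45.22 +/- 16.14; injected activity 555 MBq; SPECT PSF FWHM 10 mm.
    """

    # grid
    shape: tuple[int, int, int] = (112, 80, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    # anatomy
    body_semiaxes_mm: tuple[float, float, float] = (75.0, 55.0, 110.0)
    parotid_volume_mL: tuple[float, float] = (23.43, 10.42)  # mean, SD
    submandibular_volume_mL: tuple[float, float] = (11.57, 4.48)
    min_gland_volume_mL: float = 3.0
    parotid_hu: float = 15.0
    submandibular_hu: float = 55.0
    soft_tissue_hu: float = 40.0
    bone_hu: float = 700.0
    air_hu: float = -1000.0
    hu_noise_sd: float = 15.0
    position_jitter_mm: float = 4.0
    # kinetics (percent of injected dose / percent excretion fraction)
    parotid_pid20: tuple[float, float] = (0.36, 0.11)
    submandibular_pid20: tuple[float, float] = (0.17, 0.09)
    parotid_ef: tuple[float, float] = (61.41, 9.04)
    submandibular_ef: tuple[float, float] = (45.22, 16.14)
    min_pid20: float = 0.04
    min_pid40: float = 0.01
    ef_bounds: tuple[float, float] = (5.0, 95.0)
    thyroid_pid: float = 1.5
    oral_pid: float = 0.2
    oral_pid40_factor: float = 2.5  # excreted saliva pools in the mouth
    soft_tissue_pid: float = 2.0  # diffuse background over the whole body
    injected_activity_MBq: float = 555.0
    # imaging physics
    psf_fwhm_mm: float = 10.0
    count_scale_counts_per_Bq: float = 5.6e-4  # ~3% relative noise on a parotid VOI sum
    noiseless: bool = False
    simulate_decay: bool = True
    # inter-timepoint motion
    misalign_translation_mm: float = 6.0
    misalign_rotation_deg: float = 5.0
    # rater model
    rater_slice_step: int = 2
    rater_jitter_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "parotid_volume_mL",
            "submandibular_volume_mL",
            "parotid_pid20",
            "submandibular_pid20",
            "parotid_ef",
            "submandibular_ef",
        ):
            mean, _sd = getattr(self, name)
            if mean <= 0:
                raise ValueError(f"{name} mean must be positive")
        if self.parotid_ef[0] >= 100 or self.submandibular_ef[0] >= 100:
            raise ValueError("mean %EF must be < 100")
        if self.psf_fwhm_mm <= 0:
            raise ValueError("PSF FWHM must be positive")
        if not self.noiseless and self.count_scale_counts_per_Bq <= 0:
            raise ValueError("count scale must be positive")
        if self.injected_activity_MBq <= 0:
            raise ValueError("injected activity must be positive")

    @classmethod
    def desk_small(cls, **overrides) -> "PhantomSpec":
        """A coarser grid for Monte-Carlo-heavy experiments."""
        kw = dict(shape=(64, 48, 32), spacing_mm=(3.0, 3.0, 4.0))
        kw.update(overrides)
        return cls(**kw)


# gland placement in mm relative to the body center:
# (code, name, (dx, dy, dz), axial elongation c/a)
_GLAND_LAYOUT = (
    (1, "parotid_r", (-50.0, 8.0, 5.0), 1.6),
    (2, "parotid_l", (50.0, 8.0, 5.0), 1.6),
    (3, "submandibular_r", (-25.0, -18.0, -16.0), 1.4),
    (4, "submandibular_l", (25.0, -18.0, -16.0), 1.4),
)
_THYROID = ((0.0, -22.0, -54.0), (18.0, 10.0, 9.0))
_ORAL = ((0.0, 28.0, 32.0), (16.0, 12.0, 10.0))


def _world_grid(spec: PhantomSpec):
    xs = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing_mm)]
    return np.meshgrid(*xs, indexing="ij")


def _ellipsoid_mask(grid, center, semiaxes) -> np.ndarray:
    X, Y, Z = grid
    return (
        ((X - center[0]) / semiaxes[0]) ** 2
        + ((Y - center[1]) / semiaxes[1]) ** 2
        + ((Z - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _gland_semiaxes(volume_mL: float, elong: float, rng) -> tuple[float, float, float]:
    """Semi-axes of an ellipsoid of the given volume, elongated along z."""
    vol_mm3 = volume_mL * 1000.0
    ratio = elong * float(np.exp(rng.normal(0.0, 0.08)))
    a = (vol_mm3 / (4.0 / 3.0 * np.pi * ratio)) ** (1.0 / 3.0)
    b = a * float(np.exp(rng.normal(0.0, 0.06)))
    c = ratio * a
    # renormalise exactly to the drawn volume
    s = (vol_mm3 / (4.0 / 3.0 * np.pi * a * b * c)) ** (1.0 / 3.0)
    return a * s, b * s, c * s


def _truncnorm(rng, mean: float, sd: float, lo: float, hi: float = np.inf) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def _psf_sigma_vox(spec: PhantomSpec) -> tuple[float, ...]:
    sigma_mm = spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return tuple(sigma_mm / s for s in spec.spacing_mm)


def _study_params(spec: PhantomSpec, rng) -> dict:
    """Draw one study's per-gland volumes, positions, %ID20 and %EF."""
    glands = {}
    for code, name, offset, elong in _GLAND_LAYOUT:
        if name.startswith("parotid"):
            vol = _truncnorm(rng, *spec.parotid_volume_mL, spec.min_gland_volume_mL)
            pid20 = _truncnorm(rng, *spec.parotid_pid20, spec.min_pid20)
            ef = _truncnorm(rng, *spec.parotid_ef, *spec.ef_bounds)
            hu = spec.parotid_hu
        else:
            vol = _truncnorm(rng, *spec.submandibular_volume_mL, spec.min_gland_volume_mL)
            pid20 = _truncnorm(rng, *spec.submandibular_pid20, spec.min_pid20)
            ef = _truncnorm(rng, *spec.submandibular_ef, *spec.ef_bounds)
            hu = spec.submandibular_hu
        jitter = rng.uniform(-spec.position_jitter_mm, spec.position_jitter_mm, 3)
        # keep the 40-min activity above the background/spill floor; caps
        # only extreme joint draws of low uptake and high excretion
        pid40 = max(pid20 * (1.0 - ef / 100.0), spec.min_pid40)
        ef = 100.0 * (pid20 - pid40) / pid20
        glands[code] = {
            "name": name,
            "volume_mL": vol,
            "pid20": pid20,
            "pid40": pid40,
            "ef": ef,
            "offset_mm": tuple(np.asarray(offset) + jitter),
            "elong": elong,
            "hu": hu,
        }
    return glands


def _build_ct_and_labels(spec: PhantomSpec, glands: dict, rng):
    grid = _world_grid(spec)
    center = (np.asarray(spec.shape) - 1) / 2.0 * np.asarray(spec.spacing_mm)
    body = _ellipsoid_mask(grid, center, spec.body_semiaxes_mm)
    ct = np.full(spec.shape, spec.air_hu, dtype=np.float64)
    ct[body] = spec.soft_tissue_hu

    # spine: a posterior bone cylinder running the z extent of the body
    X, Y, _Z = grid
    spine = (((X - center[0]) / 12.0) ** 2 + ((Y - (center[1] - 38.0)) / 12.0) ** 2) <= 1.0
    ct[spine & body] = spec.bone_hu

    labels = np.zeros(spec.shape, dtype=np.int16)
    for code, g in glands.items():
        axes = _gland_semiaxes(g["volume_mL"], g["elong"], rng)
        mask = _ellipsoid_mask(grid, center + np.asarray(g["offset_mm"]), axes) & body
        ct[mask] = g["hu"]
        labels[mask] = code
        g["mask"] = mask
        g["drawn_volume_mL"] = float(mask.sum()) * np.prod(spec.spacing_mm) / 1000.0
        if not mask.any():
            raise ValueError(f"gland {g['name']} fell outside the body volume")

    thy = _ellipsoid_mask(grid, center + np.asarray(_THYROID[0]), _THYROID[1]) & body
    oral = _ellipsoid_mask(grid, center + np.asarray(_ORAL[0]), _ORAL[1]) & body
    ct[thy] = 70.0  # thyroid is mildly hyperdense on CT
    ct[oral & (labels == 0)] = -200.0  # air/soft mix in the oral cavity

    ct = ct + rng.normal(0.0, spec.hu_noise_sd, spec.shape)
    ct = np.clip(ct, -1024.0, None)
    return ct, labels, body, thy, oral


def _expected_spect(
    spec: PhantomSpec, glands: dict, body, thy, oral, t_min: float
) -> np.ndarray:
    """Pre-noise activity-concentration map (Bq/mL) at time ``t_min``."""
    inj_bq = spec.injected_activity_MBq * 1e6
    dec = decay_factor(t_min) if spec.simulate_decay else 1.0
    vox_mL = float(np.prod(spec.spacing_mm)) / 1000.0
    sigma = _psf_sigma_vox(spec)

    # non-gland components, blurred once; glands displace the diffuse
    # soft-tissue background (no background inside a gland VOI pre-blur)
    others = np.zeros(spec.shape, dtype=np.float64)
    gland_any = np.zeros(spec.shape, dtype=bool)
    for g in glands.values():
        gland_any |= g["mask"]
    bg = body & ~gland_any & ~thy & ~oral
    bg_mL = float(bg.sum()) * vox_mL
    others[bg] += spec.soft_tissue_pid / 100.0 * inj_bq * dec / bg_mL
    if thy.any():
        others[thy] += spec.thyroid_pid / 100.0 * inj_bq * dec / (float(thy.sum()) * vox_mL)
    oral_pid = spec.oral_pid * (spec.oral_pid40_factor if t_min >= 40 else 1.0)
    if oral.any():
        others[oral] += oral_pid / 100.0 * inj_bq * dec / (float(oral.sum()) * vox_mL)
    conc = ndimage.gaussian_filter(others, sigma)

    key = "pid20" if t_min < 40 else "pid40"
    for g in glands.values():
        target_bq = g[key] / 100.0 * inj_bq * dec
        unit = ndimage.gaussian_filter(g["mask"].astype(np.float64), sigma)
        in_voi_unit = float(unit[g["mask"]].sum()) * vox_mL  # Bq in VOI per unit conc
        spill_in = float(conc[g["mask"]].sum()) * vox_mL
        c = (target_bq - spill_in) / in_voi_unit
        if c <= 0:
            raise ValueError(
                f"background spill exceeds programmed activity for {g['name']}"
            )
        conc = conc + c * unit
    return conc


def _poisson_sample(conc: np.ndarray, spec: PhantomSpec, rng) -> np.ndarray:
    if spec.noiseless:
        return conc
    vox_mL = float(np.prod(spec.spacing_mm)) / 1000.0
    scale = vox_mL * spec.count_scale_counts_per_Bq
    counts = rng.poisson(conc * scale)
    return counts / scale


def generate_study(spec: PhantomSpec, study_index: int = 0) -> StudyRecord:
    """Generate one synthetic two-timepoint study.

    Fully determined by ``(spec, study_index)``: per-study anatomy and
    kinetics are drawn from the spec's population distributions with an
    index-stable random stream.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(study_index,)))
    glands = _study_params(spec, rng)
    ct, labels, body, thy, oral = _build_ct_and_labels(spec, glands, rng)

    conc20 = _expected_spect(spec, glands, body, thy, oral, 20.0)
    conc40 = _expected_spect(spec, glands, body, thy, oral, 40.0)

    if spec.misalign_translation_mm > 0 or spec.misalign_rotation_deg > 0:
        mis = RigidTransform(
            translation_mm=tuple(
                rng.uniform(-spec.misalign_translation_mm, spec.misalign_translation_mm, 3)
            ),
            rotation_deg=tuple(
                rng.uniform(-spec.misalign_rotation_deg, spec.misalign_rotation_deg, 3)
            ),
        )
    else:
        mis = RigidTransform()

    spect20 = CalibratedVolume(
        voxels=_poisson_sample(conc20, spec, rng),
        spacing=spec.spacing_mm,
        modality="SPECT",
        time_post_injection_min=20.0,
    )
    vol40 = CalibratedVolume(
        voxels=conc40, spacing=spec.spacing_mm, modality="SPECT", time_post_injection_min=40.0
    )
    if not mis.is_identity:
        vol40 = apply_alignment(vol40, mis, interp="linear")
    spect40 = vol40.with_voxels(_poisson_sample(vol40.voxels, spec, rng))

    ct_vol = CalibratedVolume(voxels=ct, spacing=spec.spacing_mm, modality="CT")
    truth = GlandLabelMap(labels=labels, spacing=spec.spacing_mm)
    programmed = {
        g["name"]: {k: g[k] for k in ("volume_mL", "drawn_volume_mL", "pid20", "pid40", "ef")}
        for g in glands.values()
    }
    return StudyRecord(
        study_id=f"phantom_{spec.seed:05d}_{study_index:04d}",
        ct20=ct_vol,
        spect20=spect20,
        spect40=spect40,
        injected_activity_MBq=spec.injected_activity_MBq,
        truth_labels=truth,
        applied_misalignment=mis,
        meta={"programmed": programmed},
    )


def generate_cohort(spec: PhantomSpec, n: int) -> list[StudyRecord]:
    """Generate ``n`` independent studies (index-stable, reproducible)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_study(spec, i) for i in range(n)]


# ---------------------------------------------------------------------------
# Manual-rater simulation
# ---------------------------------------------------------------------------

def _signed_distance_2d(mask: np.ndarray) -> np.ndarray:
    if mask.any():
        inside = ndimage.distance_transform_edt(mask)
    else:
        inside = np.zeros(mask.shape)
    if (~mask).any():
        outside = ndimage.distance_transform_edt(~mask)
    else:
        outside = np.zeros(mask.shape)
    return inside - outside


_DISK = ndimage.generate_binary_structure(2, 1)


def _jitter_slice(mask2d: np.ndarray, rng, prob: float) -> np.ndarray:
    if not mask2d.any() or rng.random() >= prob:
        return mask2d
    if rng.random() < 0.5:
        return ndimage.binary_dilation(mask2d, structure=_DISK)
    eroded = ndimage.binary_erosion(mask2d, structure=_DISK)
    return eroded if eroded.any() else mask2d


def simulate_manual_labels(
    truth: GlandLabelMap,
    every_k_slices: int = 2,
    jitter_prob: float = 0.5,
    seed: int = 0,
) -> GlandLabelMap:
    """Emulate manual contouring of the glands on axial CT slices.

    Keeps every ``k``-th occupied axial slice per gland (plus the last),
    perturbs each kept contour by a one-voxel dilation or erosion with
    probability ``jitter_prob``, and reconstructs the skipped slices by
    linear interpolation of per-slice signed distance maps — the standard
    shape-based interpolation used by clinical contouring software.
    """
    if every_k_slices not in (2, 3):
        raise ValueError("every_k_slices must be 2 or 3")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(truth.labels)
    for code in GLAND_CODES:
        mask = truth.labels == code
        if not mask.any():
            continue
        zs = np.flatnonzero(mask.any(axis=(0, 1)))
        kept = sorted(set(zs[::every_k_slices]) | {zs[-1]})
        sdts: dict[int, np.ndarray] = {}
        result = np.zeros_like(mask)
        for z in kept:
            sl = _jitter_slice(mask[:, :, z], rng, jitter_prob)
            result[:, :, z] = sl
            sdts[z] = _signed_distance_2d(sl)
        for z0, z1 in zip(kept[:-1], kept[1:]):
            for z in range(z0 + 1, z1):
                w = (z - z0) / (z1 - z0)
                result[:, :, z] = ((1 - w) * sdts[z0] + w * sdts[z1]) > 0
        out[result & (out == 0)] = code
    return truth.with_labels(out)


def simulate_rater_pair(
    truth: GlandLabelMap, spec: PhantomSpec, seed_a: int, seed_b: int
) -> tuple[GlandLabelMap, GlandLabelMap]:
    """Two independent simulated raters contouring the same truth anatomy."""
    kw = dict(every_k_slices=spec.rater_slice_step, jitter_prob=spec.rater_jitter_prob)
    return (
        simulate_manual_labels(truth, seed=seed_a, **kw),
        simulate_manual_labels(truth, seed=seed_b, **kw),
    )
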