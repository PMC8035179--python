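"""Core volumetric data types, NIfTI/DICOM I/O and grid resampling.

Conventions used throughout the package:

* arrays are indexed ``[x, y, z]``; spacing is per-axis voxel size in mm;
* the study frame is the 20-min CT frame; world coordinates are mm offsets
  from the CT volume origin (voxel indices are 0-based);
* the canonical on-disk format is NIfTI-1 with an axis-aligned affine.
  DICOM series import converts to this canonical form.

SPECT voxel values are activity concentration in Bq/mL; CT values are
Hounsfield units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "CalibratedVolume",
    "GlandLabelMap",
    "StudyRecord",
    "GLAND_CODES",
    "GLAND_NAMES",
    "VolumeFormatError",
    "CalibrationError",
    "read_volume",
    "write_volume",
    "read_label_map",
    "read_dicom_series",
    "resample_to_grid",
    "resample_labels_to_grid",
]

#: label codes of the four salivary glands (0 is background)
GLAND_CODES = (1, 2, 3, 4)
GLAND_NAMES = {
    1: "parotid_r",
    2: "parotid_l",
    3: "submandibular_r",
    4: "submandibular_l",
}

MIN_HU = -1024.0


class VolumeFormatError(ValueError):
    """Raised for unreadable files, missing geometry or invalid voxel data."""


class CalibrationError(VolumeFormatError):
    """Raised when SPECT calibration information is required but absent."""


def _as_triple(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(x).ravel())
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {t!r}")
    return t  # type: ignore[return-value]


@dataclass
class CalibratedVolume:
    """A 3D scalar grid with voxel geometry, modality and physical units.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        CT values in Hounsfield units or SPECT activity concentration
        in Bq/mL.
    spacing : (3,) float
        Voxel size in mm per axis; strictly positive.
    origin : (3,) float
        World position (mm) of voxel ``(0, 0, 0)`` in the study frame.
    modality : {"CT", "SPECT"}
    time_post_injection_min : float, optional
        Acquisition time post-injection (20 or 40 min in the standard
        sialoscintigraphy protocol).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"
    units: str = ""
    time_post_injection_min: Optional[float] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeFormatError("voxels must be a 3D array")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be strictly positive, got {self.spacing}")
        if self.modality not in ("CT", "SPECT"):
            raise VolumeFormatError(f"unknown modality {self.modality!r}")
        if not self.units:
            self.units = "HU" if self.modality == "CT" else "Bq/mL"
        expected = {"CT": "HU", "SPECT": "Bq/mL"}[self.modality]
        if self.units != expected:
            raise VolumeFormatError(
                f"units {self.units!r} inconsistent with modality {self.modality!r}"
            )
        if np.isnan(self.voxels).any():
            raise VolumeFormatError("voxels contain NaN")
        if self.modality == "SPECT" and self.voxels.size and self.voxels.min() < 0:
            raise VolumeFormatError("SPECT voxels must be non-negative")
        if self.modality == "CT" and self.voxels.size and self.voxels.min() < MIN_HU:
            raise VolumeFormatError(f"CT voxels below {MIN_HU} HU")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_mL(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def world_center(self) -> np.ndarray:
        """World coordinates (mm) of the geometric volume center."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.spacing
        )

    def same_grid(self, other: "CalibratedVolume | GlandLabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_voxels(self, voxels: np.ndarray) -> "CalibratedVolume":
        return replace(self, voxels=voxels)

    def total_activity_Bq(self) -> float:
        """Sum of concentration x voxel volume over the field (SPECT only)."""
        if self.modality != "SPECT":
            raise ValueError("total activity is defined for SPECT volumes")
        return float(self.voxels.sum(dtype=np.float64) * self.voxel_volume_mL)


@dataclass
class GlandLabelMap:
    """Integer label volume marking background and the four salivary glands.

    Codes: 0 background, 1 right parotid, 2 left parotid,
    3 right submandibular, 4 left submandibular.  Shares the grid of a
    reference :class:`CalibratedVolume`.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeFormatError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(np.mod(self.labels, 1) == 0):
                raise VolumeFormatError("labels must be integers")
            self.labels = self.labels.astype(np.int16)
        bad = set(np.unique(self.labels)) - {0, 1, 2, 3, 4}
        if bad:
            raise VolumeFormatError(f"invalid label codes {sorted(bad)}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mL(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def with_labels(self, labels: np.ndarray) -> "GlandLabelMap":
        return replace(self, labels=labels)


@dataclass
class StudyRecord:
    """One patient-equivalent acquisition of the two-timepoint protocol.

    Carries the 20-min CT + SPECT pair (shared frame), the post-sialagogue
    40-min SPECT (possibly misaligned relative to the CT frame), injected
    activity and — for synthetic studies — the ground truth labels and the
    rigid misalignment that was applied to the 40-min SPECT.
    """

    study_id: str
    ct20: CalibratedVolume
    spect20: CalibratedVolume
    spect40: CalibratedVolume
    injected_activity_MBq: float
    ct40: Optional[CalibratedVolume] = None
    truth_labels: Optional[GlandLabelMap] = None
    applied_misalignment: Optional[object] = None  # registration.RigidTransform
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.injected_activity_MBq <= 0:
            raise ValueError("injected_activity_MBq must be > 0")
        if not self.spect20.same_grid(self.ct20):
            raise ValueError("spect20 must share the ct20 frame")


# ---------------------------------------------------------------------------
# NIfTI / DICOM I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _descrip(kind: str, vol) -> bytes:
    if kind == "labels":
        return b"salispect;kind=labels"
    t = "" if vol.time_post_injection_min is None else f";tpi={vol.time_post_injection_min:g}"
    return f"salispect;kind={vol.modality}{t}".encode()


def _parse_descrip(raw: bytes) -> dict:
    out: dict = {}
    try:
        txt = bytes(raw).decode(errors="ignore").rstrip("\x00").strip()
    except Exception:
        return out
    if not txt.startswith("salispect"):
        return out
    for part in txt.split(";")[1:]:
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def write_volume(vol: CalibratedVolume | GlandLabelMap, path) -> None:
    """Write a volume or label map to NIfTI-1 (.nii / .nii.gz).

    Label maps are stored as int16; scalar volumes as float32.  The file
    roundtrips through :func:`read_volume` / :func:`read_label_map` with
    identical grid and values.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    if isinstance(vol, GlandLabelMap):
        data = vol.labels.astype(np.int16)
        kind = "labels"
    else:
        if np.isnan(vol.voxels).any():
            raise VolumeFormatError("refusing to write NaN voxels")
        data = vol.voxels.astype(np.float32)
        kind = "volume"
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    img.header["descrip"] = _descrip(kind, vol)
    zooms = tuple(float(s) for s in vol.spacing)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def _load_nifti(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as e:  # pragma: no cover - nibabel error text varies
        raise VolumeFormatError(f"cannot read {path}: {e}") from e
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    meta = _parse_descrip(img.header["descrip"].tobytes())
    return data, tuple(float(z) for z in zooms), origin, meta


def read_volume(
    path,
    modality: str,
    calibration_Bq_per_unit: Optional[float] = None,
    time_post_injection_min: Optional[float] = None,
) -> CalibratedVolume:
    """Read a scalar volume from NIfTI.

    For ``modality="SPECT"`` the stored values must already be Bq/mL
    (written by this package) or a ``calibration_Bq_per_unit`` factor must
    be supplied to convert stored units (e.g. counts) to Bq/mL.
    """
    data, spacing, origin, meta = _load_nifti(path)
    stored_kind = meta.get("kind")
    tpi = time_post_injection_min
    if tpi is None and "tpi" in meta:
        tpi = float(meta["tpi"])
    data = np.asarray(data, dtype=np.float64)
    if modality == "SPECT":
        if calibration_Bq_per_unit is not None:
            data = data * float(calibration_Bq_per_unit)
        elif stored_kind != "SPECT":
            raise CalibrationError(
                f"{path} was not written as calibrated SPECT; supply "
                "calibration_Bq_per_unit (Bq/mL per stored unit)"
            )
        data = np.clip(data, 0.0, None)  # guard tiny negative interpolation residue
    return CalibratedVolume(
        voxels=data,
        spacing=spacing,
        origin=origin,
        modality=modality,
        time_post_injection_min=tpi,
    )


def read_label_map(path) -> GlandLabelMap:
    """Read an integer gland label map from NIfTI."""
    data, spacing, origin, _ = _load_nifti(path)
    return GlandLabelMap(labels=np.rint(data).astype(np.int16), spacing=spacing, origin=origin)


def read_dicom_series(directory, modality: str = "CT") -> CalibratedVolume:
    """Import a DICOM series directory and convert to the canonical frame.

    Convenience reader: geometry is taken from the series; the array is
    reordered to the package's (x, y, z) axis convention.
    """
    import SimpleITK as sitk

    directory = str(directory)
    reader = sitk.ImageSeriesReader()
    ids = reader.GetGDCMSeriesIDs(directory)
    if not ids:
        raise VolumeFormatError(f"no DICOM series found in {directory}")
    reader.SetFileNames(reader.GetGDCMSeriesFileNames(directory, ids[0]))
    img = reader.Execute()
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float64)
    return CalibratedVolume(
        voxels=data,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        modality=modality,
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_INTERP_ORDER = {"nearest": 0, "linear": 1}


def _resample_array(
    src: np.ndarray,
    src_spacing,
    src_origin,
    ref_shape,
    ref_spacing,
    ref_origin,
    order: int,
    cval: float,
) -> np.ndarray:
    """Sample ``src`` at the world positions of a reference grid."""
    idx = np.indices(ref_shape, dtype=np.float64)
    coords = [
        (idx[a] * ref_spacing[a] + ref_origin[a] - src_origin[a]) / src_spacing[a]
        for a in range(3)
    ]
    return ndimage.map_coordinates(
        np.asarray(src, dtype=np.float64), coords, order=order, mode="constant", cval=cval
    )


def resample_to_grid(
    src: CalibratedVolume, ref: CalibratedVolume, interp: str = "linear"
) -> CalibratedVolume:
    """Resample ``src`` onto the grid of ``ref`` (world-coordinate match).

    Out-of-field voxels are set to 0 (SPECT) or -1000 HU (CT).  Linear
    interpolation of a smooth in-field activity distribution conserves
    total activity to well within 1%.
    """
    if interp not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation mode {interp!r}")
    if src.same_grid(ref):
        return src.with_voxels(src.voxels.copy())
    cval = 0.0 if src.modality == "SPECT" else -1000.0
    out = _resample_array(
        src.voxels, src.spacing, src.origin, ref.shape, ref.spacing, ref.origin,
        _INTERP_ORDER[interp], cval,
    )
    if src.modality == "SPECT":
        out = np.clip(out, 0.0, None)
    return CalibratedVolume(
        voxels=out,
        spacing=ref.spacing,
        origin=ref.origin,
        modality=src.modality,
        time_post_injection_min=src.time_post_injection_min,
    )


def resample_labels_to_grid(src: GlandLabelMap, ref: CalibratedVolume) -> GlandLabelMap:
    """Nearest-neighbour label resampling; never invents new label codes."""
    out = _resample_array(
        src.labels, src.spacing, src.origin, ref.shape, ref.spacing, ref.origin, 0, 0.0
    )
    return GlandLabelMap(
        labels=np.rint(out).astype(np.int16), spacing=ref.spacing, origin=ref.origin
    )


def save_study(record: StudyRecord, directory) -> dict:
    """Write all volumes of a study to ``directory``; returns the file map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, vol in (
        ("ct20", record.ct20),
        ("spect20", record.spect20),
        ("spect40", record.spect40),
        ("ct40", record.ct40),
        ("truth_labels", record.truth_labels),
    ):
        if vol is None:
            continue
        p = directory / f"{record.study_id}_{name}.nii.gz"
        write_volume(vol, p)
        files[name] = str(p)
    meta = {
        "study_id": record.study_id,
        "injected_activity_MBq": record.injected_activity_MBq,
        "files": files,
    }
    if record.applied_misalignment is not None:
        meta["applied_misalignment"] = record.applied_misalignment.to_dict()
    if record.meta:
        meta["meta"] = record.meta
    with open(directory / f"{record.study_id}_study.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return meta
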