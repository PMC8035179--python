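"""CT cropping to the fixed network matrix and intensity normalization.

The segmentation network expects a fixed matrix (256 x 128 x 64 voxels as
x by y by z at clinical resolution; smaller targets are used at desk
scale).  The crop is planned on the CT alone: the z window is the
contiguous run of slices maximising the summed soft-tissue profile
(per-slice count of voxels in the soft-tissue HU band), and the x/y
window is centred on the bounding box of the axial maximum-intensity
projection of the soft-tissue mask.  The soft-tissue band is the
display window used for manual contouring: level 40, width 400 HU,
i.e. [-160, 240] HU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Union

import numpy as np

from .volumes import CalibratedVolume, GlandLabelMap

__all__ = [
    "SOFT_TISSUE_WINDOW_HU",
    "CropPlan",
    "soft_tissue_mask",
    "plan_crop",
    "apply_crop",
    "uncrop",
    "normalize_for_network",
]

#: soft-tissue CT display window (level 40, width 400): HU in [-160, 240]
SOFT_TISSUE_WINDOW_HU = (-160.0, 240.0)

DEFAULT_TARGET_SHAPE = (256, 128, 64)


@dataclass
class CropPlan:
    """Per-axis source window and padding realising a fixed target shape.

    ``start[a]:stop[a]`` indexes the source; ``pad_before/pad_after`` are
    applied to the extracted block so that
    ``(stop - start) + pad_before + pad_after == target_shape`` per axis.
    """

    start: tuple[int, int, int]
    stop: tuple[int, int, int]
    pad_before: tuple[int, int, int]
    pad_after: tuple[int, int, int]
    target_shape: tuple[int, int, int]
    source_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        for a in range(3):
            if not (0 <= self.start[a] <= self.stop[a] <= self.source_shape[a]):
                raise ValueError(f"axis {a}: window outside source bounds")
            got = self.stop[a] - self.start[a] + self.pad_before[a] + self.pad_after[a]
            if got != self.target_shape[a]:
                raise ValueError(
                    f"axis {a}: window+padding = {got} != target {self.target_shape[a]}"
                )

    def to_json(self, path=None) -> str:
        d = {k: list(getattr(self, k)) for k in (
            "start", "stop", "pad_before", "pad_after", "target_shape", "source_shape")}
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "CropPlan":
        if isinstance(src, (str, bytes)) and "{" in str(src):
            d = json.loads(src)
        else:
            with open(src) as fh:
                d = json.load(fh)
        return cls(**{k: tuple(v) for k, v in d.items()})


def soft_tissue_mask(ct: CalibratedVolume) -> np.ndarray:
    """Binary mask of voxels inside the soft-tissue HU band [-160, 240]."""
    if ct.modality != "CT":
        raise ValueError("soft_tissue_mask requires a CT volume")
    lo, hi = SOFT_TISSUE_WINDOW_HU
    return (ct.voxels >= lo) & (ct.voxels <= hi)


def _axis_window(lo: int, hi: int, target: int, n: int):
    """Centered window of width ``target`` on [lo, hi) clipped to [0, n)."""
    center = (lo + hi) / 2.0
    start = int(round(center - target / 2.0))
    start = max(0, min(start, n - target)) if n >= target else 0
    if n >= target:
        return start, start + target, 0, 0
    pad = target - n
    before = pad // 2
    return 0, n, before, pad - before


def plan_crop(
    ct: CalibratedVolume, target_shape: tuple[int, int, int] = DEFAULT_TARGET_SHAPE
) -> CropPlan:
    """Plan the crop of a CT to ``target_shape`` (x, y, z).

    z: among all contiguous windows of ``target_shape[2]`` slices, the one
    maximising the summed soft-tissue z profile; ties are broken toward
    the window whose center is closest to the profile centroid.
    x/y: centred on the bounding box of the axial maximum-intensity
    projection of the soft-tissue mask.  Deterministic.
    """
    mask = soft_tissue_mask(ct)
    if not mask.any():
        raise ValueError("empty soft-tissue mask; cannot plan a crop")
    nx, ny, nz = mask.shape
    tx, ty, tz = target_shape

    # z window from the soft-tissue z profile
    profile = mask.sum(axis=(0, 1)).astype(np.int64)
    if nz > tz:
        sums = np.convolve(profile, np.ones(tz, dtype=np.int64), mode="valid")
        best = sums.max()
        starts = np.flatnonzero(sums == best)
        centroid = float((profile * np.arange(nz)).sum()) / float(profile.sum())
        z0 = int(starts[np.argmin(np.abs(starts + (tz - 1) / 2.0 - centroid))])
        zwin = (z0, z0 + tz, 0, 0)
    elif nz == tz:
        zwin = (0, nz, 0, 0)
    else:
        pad = tz - nz
        zwin = (0, nz, pad // 2, pad - pad // 2)

    # x/y from the axial MIP bounding box
    mip = mask.any(axis=2)
    xs = np.flatnonzero(mip.any(axis=1))
    ys = np.flatnonzero(mip.any(axis=0))
    xwin = _axis_window(xs[0], xs[-1] + 1, tx, nx)
    ywin = _axis_window(ys[0], ys[-1] + 1, ty, ny)

    return CropPlan(
        start=(xwin[0], ywin[0], zwin[0]),
        stop=(xwin[1], ywin[1], zwin[1]),
        pad_before=(xwin[2], ywin[2], zwin[2]),
        pad_after=(xwin[3], ywin[3], zwin[3]),
        target_shape=tuple(target_shape),
        source_shape=(nx, ny, nz),
    )


def _default_pad(vol) -> float:
    if isinstance(vol, GlandLabelMap):
        return 0.0
    return -1000.0 if vol.modality == "CT" else 0.0


def apply_crop(
    vol: Union[CalibratedVolume, GlandLabelMap], plan: CropPlan, pad_value=None
):
    """Crop (and pad) a volume or label map according to a plan.

    The output grid origin is shifted so world coordinates of in-window
    voxels are preserved.  Padded voxels get ``pad_value`` (-1000 HU for
    CT, 0 for SPECT and labels).
    """
    arr = vol.labels if isinstance(vol, GlandLabelMap) else vol.voxels
    if arr.shape != plan.source_shape:
        raise ValueError(f"plan built for {plan.source_shape}, volume is {arr.shape}")
    if pad_value is None:
        pad_value = _default_pad(vol)
    sl = tuple(slice(plan.start[a], plan.stop[a]) for a in range(3))
    block = arr[sl]
    pads = tuple((plan.pad_before[a], plan.pad_after[a]) for a in range(3))
    if any(p != (0, 0) for p in pads):
        block = np.pad(block, pads, constant_values=pad_value)
    new_origin = tuple(
        vol.origin[a] + (plan.start[a] - plan.pad_before[a]) * vol.spacing[a]
        for a in range(3)
    )
    if isinstance(vol, GlandLabelMap):
        return GlandLabelMap(labels=block.astype(arr.dtype), spacing=vol.spacing,
                             origin=new_origin)
    return CalibratedVolume(
        voxels=block,
        spacing=vol.spacing,
        origin=new_origin,
        modality=vol.modality,
        time_post_injection_min=vol.time_post_injection_min,
    )


def uncrop(
    vol: Union[CalibratedVolume, GlandLabelMap], plan: CropPlan, fill_value=None
):
    """Inverse of :func:`apply_crop`: place the window back into a
    source-shaped volume; voxels outside the window get ``fill_value``."""
    arr = vol.labels if isinstance(vol, GlandLabelMap) else vol.voxels
    if arr.shape != plan.target_shape:
        raise ValueError("volume does not match the plan's target shape")
    if fill_value is None:
        fill_value = _default_pad(vol)
    out = np.full(plan.source_shape, fill_value, dtype=arr.dtype)
    inner = tuple(
        slice(plan.pad_before[a], plan.target_shape[a] - plan.pad_after[a])
        for a in range(3)
    )
    sl = tuple(slice(plan.start[a], plan.stop[a]) for a in range(3))
    out[sl] = arr[inner]
    orig = tuple(
        vol.origin[a] - (plan.start[a] - plan.pad_before[a]) * vol.spacing[a]
        for a in range(3)
    )
    if isinstance(vol, GlandLabelMap):
        return GlandLabelMap(labels=out, spacing=vol.spacing, origin=orig)
    return CalibratedVolume(
        voxels=out, spacing=vol.spacing, origin=orig, modality=vol.modality,
        time_post_injection_min=vol.time_post_injection_min,
    )


def normalize_for_network(ct_cropped: CalibratedVolume) -> np.ndarray:
    """Clip HU to the soft-tissue window and map linearly to [0, 1]."""
    if ct_cropped.modality != "CT":
        raise ValueError("normalize_for_network expects a CT volume")
    lo, hi = SOFT_TISSUE_WINDOW_HU
    x = np.clip(ct_cropped.voxels, lo, hi)
    return ((x - lo) / (hi - lo)).astype(np.float32)
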