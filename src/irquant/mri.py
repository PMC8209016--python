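"""Dual-contrast MRI infarct/salvage volumetry.

Pipeline: in-plane interpolation to a finer grid, relative-threshold
segmentation of the reperfused territory on the T2* volume (iron signal
void) and of the infarct on the squared T1 inversion-recovery volume
(gadolinium enhancement), clipping by the left-ventricle mask, and
voxel-count volumetry with salvage = reperfusion - infarct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datatypes import Mask3D, VolumeImage, VolumetryResult

__all__ = [
    "interpolate_inplane",
    "interpolate_mask_inplane",
    "mask_volume",
    "segment_reperfusion_t2star",
    "segment_infarct_t1",
    "compute_volumetry",
    "run_mri_pipeline",
    "dice",
    "MriConfig",
]


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------


def _resize_inplane(data: np.ndarray, target: tuple[int, int], order: int) -> np.ndarray:
    """Resample axes (0, 1) to ``target`` with align-corners spline mapping.

    Output sample ``i`` maps to input coordinate ``i * (n_in - 1) / (n_out - 1)``,
    so the first/last samples coincide and linear interpolation reproduces
    affine ramps exactly (no edge extrapolation).
    """
    nx, ny, nz = data.shape
    tx, ty = target

    def axis_coords(n_in: int, n_out: int) -> np.ndarray:
        if n_out == 1:
            return np.array([(n_in - 1) / 2.0])
        return np.arange(n_out) * (n_in - 1) / (n_out - 1)

    cx = axis_coords(nx, tx)
    cy = axis_coords(ny, ty)
    xx, yy = np.meshgrid(cx, cy, indexing="ij")
    out = np.empty((tx, ty, nz), dtype=float)
    for k in range(nz):
        out[:, :, k] = ndimage.map_coordinates(
            np.asarray(data[:, :, k], dtype=float), [xx, yy], order=order, mode="nearest"
        )
    return out


def _rescaled_spacing(
    spacing: tuple[float, float, float],
    source: tuple[int, int],
    target: tuple[int, int],
) -> tuple[float, float, float]:
    dx, dy, dz = spacing
    return (dx * source[0] / target[0], dy * source[1] / target[1], dz)


def interpolate_inplane(
    vol: VolumeImage,
    target_inplane: tuple[int, int] = (256, 256),
    order: int = 1,
) -> VolumeImage:
    """Interpolate each slice to ``target_inplane``; slice count unchanged.

    Spacing is rescaled so the in-plane physical extent is preserved.
    Raises on downsampling requests.
    """
    nx, ny, _ = vol.shape
    tx, ty = (int(v) for v in target_inplane)
    if tx < nx or ty < ny:
        raise ValueError("in-plane target dimensions must be >= source dimensions")
    if (tx, ty) == (nx, ny):
        return VolumeImage(vol.intensities.copy(), vol.spacing, vol.contrast)
    data = _resize_inplane(vol.intensities, (tx, ty), order=order)
    return VolumeImage(data, _rescaled_spacing(vol.spacing, (nx, ny), (tx, ty)), vol.contrast)


def interpolate_mask_inplane(
    mask: Mask3D, target_inplane: tuple[int, int] = (256, 256)
) -> Mask3D:
    """Interpolate a boolean mask (linear on floats, threshold at 0.5)."""
    nx, ny, _ = mask.shape
    tx, ty = (int(v) for v in target_inplane)
    if tx < nx or ty < ny:
        raise ValueError("in-plane target dimensions must be >= source dimensions")
    if (tx, ty) == (nx, ny):
        return Mask3D(mask.voxels.copy(), mask.spacing, mask.label)
    data = _resize_inplane(mask.voxels.astype(float), (tx, ty), order=1)
    return Mask3D(data >= 0.5, _rescaled_spacing(mask.spacing, (nx, ny), (tx, ty)), mask.label)


# ---------------------------------------------------------------------------
# Volumetry primitives
# ---------------------------------------------------------------------------


def mask_volume(mask: Mask3D) -> float:
    """Number of true voxels times the voxel volume, in mm^3."""
    return mask.count * mask.voxel_volume_mm3


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) between two boolean arrays."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return math.nan
    return 2.0 * int((a & b).sum()) / denom


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def _check_shapes(vol: VolumeImage, *masks: Mask3D) -> None:
    for m in masks:
        if m.shape != vol.shape:
            raise ValueError(f"shape mismatch: volume {vol.shape} vs mask {m.shape}")


def segment_reperfusion_t2star(
    vol: VolumeImage,
    lv: Mask3D,
    fraction: float = 0.66,
    direction: str = "below",
) -> Mask3D:
    """Threshold the T2* volume at ``fraction`` of its max over the LV mask.

    The default ``direction='below'`` keeps voxels with intensity <= the
    threshold — the iron-induced signal void marking the reperfused
    territory.  The result is clipped by the LV mask.
    """
    _check_shapes(vol, lv)
    if lv.count == 0:
        raise ValueError("LV mask is empty")
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    inside = vol.intensities[lv.voxels]
    threshold = fraction * float(inside.max())
    if direction == "below":
        selected = vol.intensities <= threshold
    else:
        selected = vol.intensities >= threshold
    return Mask3D(selected & lv.voxels, lv.spacing, "REPERFUSION")


def segment_infarct_t1(
    vol: VolumeImage,
    lv: Mask3D,
    reperfusion: Mask3D | None = None,
    fraction: float = 0.10,
    direction: str = "above",
    max_of_squared: bool = True,
) -> Mask3D:
    """Threshold the squared T1-IR volume at ``fraction`` of its LV maximum.

    Intensities are squared first (handles signed real-valued IR
    reconstructions); the default keeps voxels whose squared intensity is >=
    ``fraction`` times the maximum (of the squared intensity when
    ``max_of_squared``, of the squared raw maximum otherwise) over the LV
    mask.  The result is clipped by the LV mask and, when a reperfusion mask
    is supplied, intersected with it so salvage can never go negative.
    """
    _check_shapes(vol, lv)
    if lv.count == 0:
        raise ValueError("LV mask is empty")
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    squared = vol.intensities**2
    inside = squared[lv.voxels]
    if max_of_squared:
        ref = float(inside.max())
    else:
        ref = float(np.abs(vol.intensities[lv.voxels]).max()) ** 2
    if ref == 0.0:
        raise ValueError("threshold undefined: volume is all zero inside the LV mask")
    threshold = fraction * ref
    if direction == "above":
        selected = squared >= threshold
    else:
        selected = squared <= threshold
    voxels = selected & lv.voxels
    if reperfusion is not None:
        if reperfusion.shape != lv.shape:
            raise ValueError("reperfusion mask shape mismatch")
        if not np.all(lv.voxels[reperfusion.voxels]):
            raise ValueError("reperfusion mask must be contained in the LV mask")
        voxels &= reperfusion.voxels
    return Mask3D(voxels, lv.spacing, "INFARCT")


# ---------------------------------------------------------------------------
# Volumetry
# ---------------------------------------------------------------------------


def compute_volumetry(lv: Mask3D, reperfusion: Mask3D, infarct: Mask3D) -> VolumetryResult:
    """Volumes plus all normalized percentages from the three masks.

    Requires infarct ⊆ reperfusion ⊆ LV.  Salvage is computed from voxel
    counts so ``salvage + infarct == reperfusion`` holds exactly.  With an
    empty reperfusion mask the reperfusion-normalized percentages are NaN.
    """
    if not (lv.shape == reperfusion.shape == infarct.shape):
        raise ValueError("masks must share one grid")
    if not np.all(lv.voxels[reperfusion.voxels]):
        raise ValueError("containment violated: reperfusion ⊄ LV")
    if not np.all(reperfusion.voxels[infarct.voxels]):
        raise ValueError("containment violated: infarct ⊄ reperfusion")

    vv = lv.voxel_volume_mm3
    n_lv, n_rep, n_inf = lv.count, reperfusion.count, infarct.count
    n_sal = n_rep - n_inf

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else math.nan

    return VolumetryResult(
        lv_volume=n_lv * vv,
        reperfusion_volume=n_rep * vv,
        infarct_volume=n_inf * vv,
        salvage_volume=n_sal * vv,
        infarct_fraction_of_reperfusion=pct(n_inf, n_rep),
        salvage_fraction_of_reperfusion=pct(n_sal, n_rep),
        reperfusion_fraction_of_lv=pct(n_rep, n_lv),
        infarct_fraction_of_lv=pct(n_inf, n_lv),
        salvage_fraction_of_lv=pct(n_sal, n_lv),
        lv_voxels=n_lv,
        reperfusion_voxels=n_rep,
        infarct_voxels=n_inf,
        salvage_voxels=n_sal,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class MriConfig:
    target_inplane: tuple[int, int] = (256, 256)
    t2_fraction: float = 0.66
    t1_fraction: float = 0.10
    t2_direction: str = "below"
    t1_direction: str = "above"
    t1_max_of_squared: bool = True
    interpolation_order: int = 1


def run_mri_pipeline(
    t2star: VolumeImage,
    t1ir: VolumeImage,
    lv: Mask3D,
    config: MriConfig | None = None,
) -> tuple[VolumetryResult, dict[str, Mask3D]]:
    """Interpolate, segment both contrasts, and compute volumetry.

    The two volumes and the LV mask must live on one grid (co-registered
    input is the caller's responsibility).  Returns the volumetry result and
    the masks (on the interpolated grid) under keys ``lv``, ``reperfusion``,
    ``infarct``.
    """
    cfg = config or MriConfig()
    if t2star.shape != t1ir.shape or t2star.shape != lv.shape:
        raise ValueError("t2star, t1ir and lv must share one grid")
    t2i = interpolate_inplane(t2star, cfg.target_inplane, order=cfg.interpolation_order)
    t1i = interpolate_inplane(t1ir, cfg.target_inplane, order=cfg.interpolation_order)
    lvi = interpolate_mask_inplane(lv, cfg.target_inplane)
    rep = segment_reperfusion_t2star(t2i, lvi, cfg.t2_fraction, cfg.t2_direction)
    inf = segment_infarct_t1(
        t1i, lvi, rep, cfg.t1_fraction, cfg.t1_direction, cfg.t1_max_of_squared
    )
    result = compute_volumetry(lvi, rep, inf)
    return result, {"lv": lvi, "reperfusion": rep, "infarct": inf}
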