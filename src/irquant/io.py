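"""File-format glue: NIfTI volumes, spectra CSVs, section images, tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import Mask3D, SectionImage, Spectrum1D, VolumeImage

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_spectrum",
    "load_spectrum",
    "load_spectra_dir",
    "save_section_images",
    "load_section_images",
    "write_json",
]


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_volume(vol: VolumeImage, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.intensities, np.float32), _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path, contrast: str) -> VolumeImage:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(np.asarray(img.get_fdata(), float), spacing, contrast)


def save_mask(mask: Mask3D, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path, label: str) -> Mask3D:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Mask3D(np.asarray(img.get_fdata()) > 0.5, spacing, label)


def save_spectrum(spec: Spectrum1D, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"ppm": spec.ppm, "intensity": spec.intensity}).to_csv(path, index=False)
    return path


def load_spectrum(
    path: str | Path, sample_id: str = "", group: str = "", timepoint: str = ""
) -> Spectrum1D:
    df = pd.read_csv(path)
    return Spectrum1D(
        df["ppm"].to_numpy(),
        df["intensity"].to_numpy(),
        sample_id=sample_id or Path(path).stem,
        group=group,
        timepoint=timepoint,
    )


def load_spectra_dir(directory: str | Path, design: pd.DataFrame) -> list[Spectrum1D]:
    """Load one CSV per design row (``<sample_id>.csv``) with labels attached."""
    directory = Path(directory)
    spectra = []
    for row in design.itertuples(index=False):
        spectra.append(
            load_spectrum(
                directory / f"{row.sample_id}.csv",
                sample_id=row.sample_id,
                group=row.group,
                timepoint=getattr(row, "timepoint", ""),
            )
        )
    return spectra


def save_section_images(
    fluor: np.ndarray, rgb: np.ndarray, stem: str | Path
) -> tuple[Path, Path]:
    """Write the 16-bit grayscale TIFF and the 8-bit RGB PNG for one section."""
    import imageio.v3 as iio
    import tifffile

    stem = Path(stem)
    tif = stem.with_suffix(".tif")
    png = stem.with_name(stem.name + "_trichrome").with_suffix(".png")
    tifffile.imwrite(tif, np.asarray(fluor, np.uint16))
    iio.imwrite(png, np.asarray(rgb, np.uint8))
    return tif, png


def load_section_images(
    tif_path: str | Path,
    png_path: str | Path,
    um_per_pixel_fluor: float,
    um_per_pixel_rgb: float,
    distance_um: int,
    animal_id: str,
) -> tuple[SectionImage, SectionImage]:
    import imageio.v3 as iio
    import tifffile

    fluor = SectionImage(
        tifffile.imread(str(tif_path)), um_per_pixel_fluor, distance_um, animal_id, "2D10G9"
    )
    rgb = SectionImage(
        iio.imread(str(png_path))[..., :3], um_per_pixel_rgb, distance_um, animal_id, "TRICHROME"
    )
    return fluor, rgb


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
    return path
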