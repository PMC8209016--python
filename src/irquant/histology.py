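"""Section-level histology quantification.

Fluorescence thresholding at fixed 150/350 grayscale levels, color-rule
collagen segmentation of trichrome-stained sections, distance-to-ligation
profiles, and the collagen-vs-oxidative-damage correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

from .datatypes import DISTANCE_GRID_UM, SectionImage, SectionQuant, TestResult
from .stats import pearson_r

__all__ = [
    "quantify_fluorescence",
    "segment_collagen",
    "collagen_area",
    "quantify_section_pair",
    "distance_profile",
    "correlate_collagen_oxidation",
]

BACKGROUND_THRESHOLD = 150
POSITIVE_THRESHOLD = 350

# Hue/saturation boundaries for the trichrome color-rule classifier
# (hue in [0, 1]; blue/purple band covers collagen).
COLLAGEN_HUE = (0.5, 5.0 / 6.0)
BACKGROUND_SATURATION = 0.15


def quantify_fluorescence(
    img: SectionImage,
    background_threshold: int = BACKGROUND_THRESHOLD,
    positive_threshold: int = POSITIVE_THRESHOLD,
) -> tuple[float, float]:
    """Mean tissue intensity and percent of tissue pixels counted positive.

    Tissue pixels are those strictly above ``background_threshold``; positive
    pixels those strictly above ``positive_threshold`` (strict '>' on both,
    matching 'over 150' / 'over 350' semantics).  Raises when no pixel
    clears the background threshold.
    """
    if img.is_rgb:
        raise ValueError("fluorescence quantification needs a grayscale image")
    if not background_threshold < positive_threshold:
        raise ValueError("background threshold must lie below the positive threshold")
    pixels = np.asarray(img.pixels)
    tissue = pixels > background_threshold
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("no tissue: no pixel above the background threshold")
    mean_intensity = float(pixels[tissue].mean())
    percent_positive = 100.0 * int((pixels > positive_threshold).sum()) / n_tissue
    return mean_intensity, percent_positive


def segment_collagen(img: SectionImage) -> tuple[np.ndarray, np.ndarray]:
    """Three-way color-rule partition of a trichrome image.

    Background: low-saturation pixels.  Collagen: remaining pixels with hue
    in the blue/purple band.  Myocardium: the rest.  Returns
    ``(collagen_mask, tissue_mask)``; myocardium is their difference and the
    three classes partition the frame.
    """
    if not img.is_rgb:
        raise ValueError("collagen segmentation needs an RGB image")
    hsv = rgb2hsv(np.asarray(img.pixels, dtype=np.uint8))
    hue, sat = hsv[..., 0], hsv[..., 1]
    tissue = sat >= BACKGROUND_SATURATION
    collagen = tissue & (hue >= COLLAGEN_HUE[0]) & (hue <= COLLAGEN_HUE[1])
    return collagen, tissue


def collagen_area(
    collagen_mask: np.ndarray, tissue_mask: np.ndarray, um_per_pixel: float
) -> tuple[float, float]:
    """Collagen area in um^2 and as percent of the tissue pixel count."""
    n_tissue = int(np.count_nonzero(tissue_mask))
    if n_tissue == 0:
        raise ValueError("empty tissue mask")
    n_col = int(np.count_nonzero(collagen_mask))
    return n_col * um_per_pixel**2, 100.0 * n_col / n_tissue


def quantify_section_pair(
    fluor: SectionImage, trichrome: SectionImage, group: str = ""
) -> SectionQuant:
    """Quantify matched fluorescence + trichrome images of one section."""
    mean_int, pct_pos = quantify_fluorescence(fluor)
    col_mask, tis_mask = segment_collagen(trichrome)
    area, pct_col = collagen_area(col_mask, tis_mask, trichrome.um_per_pixel)
    return SectionQuant(
        animal_id=fluor.animal_id,
        distance_um=fluor.distance_um,
        mean_intensity=mean_int,
        percent_positive=pct_pos,
        collagen_area_um2=area,
        collagen_percent=pct_col,
        group=group,
    )


def distance_profile(quants: list[SectionQuant], metric: str) -> pd.DataFrame:
    """Group mean ± SEM of one metric over the fixed distance grid.

    Distances with no sections in a group appear with NaN mean and are
    flagged in the ``missing`` column.
    """
    if not quants:
        raise ValueError("no section quantifications supplied")
    df = pd.DataFrame(
        {
            "group": [q.group for q in quants],
            "distance_um": [q.distance_um for q in quants],
            "value": [getattr(q, metric) for q in quants],
        }
    )
    rows = []
    for group, gdf in df.groupby("group", sort=True):
        for d in DISTANCE_GRID_UM:
            vals = gdf.loc[gdf["distance_um"] == d, "value"].to_numpy()
            n = vals.size
            mean = float(vals.mean()) if n else float("nan")
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else (0.0 if n == 1 else float("nan"))
            rows.append(
                dict(group=group, distance_um=d, mean=mean, sem=sem, n=n, missing=n == 0)
            )
    return pd.DataFrame(rows)


def correlate_collagen_oxidation(
    quants: list[SectionQuant], scope: str = "pooled"
) -> pd.DataFrame:
    """Pearson r between collagen percent and positive-fluorescence percent.

    ``scope='pooled'`` computes one r per group over all its sections;
    ``scope='per-animal'`` one r per animal.  Each r needs >= 3 paired
    observations with non-zero variance.
    """
    if scope not in ("pooled", "per-animal"):
        raise ValueError("scope must be 'pooled' or 'per-animal'")
    df = pd.DataFrame(
        {
            "group": [q.group for q in quants],
            "animal_id": [q.animal_id for q in quants],
            "collagen_percent": [q.collagen_percent for q in quants],
            "percent_positive": [q.percent_positive for q in quants],
        }
    )
    key = "group" if scope == "pooled" else "animal_id"
    rows = []
    for label, gdf in df.groupby(key, sort=True):
        res: TestResult = pearson_r(
            gdf["collagen_percent"], gdf["percent_positive"], comparison=str(label)
        )
        rows.append(dict(scope=scope, label=label, r=res.statistic, p=res.p_value, n=len(gdf)))
    return pd.DataFrame(rows)
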