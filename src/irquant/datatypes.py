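"""Core domain types shared across the pipeline modules.

All types are plain dataclasses with light invariant checking in
``__post_init__``; heavy validation (shape compatibility between volumes,
containment of masks, ...) lives in the operations that combine them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# ---------------------------------------------------------------------------
# MRI
# ---------------------------------------------------------------------------

#: Allowed contrast tags for :class:`VolumeImage`.
CONTRASTS = ("T2STAR", "T1IR")

#: Allowed labels for :class:`Mask3D`.
MASK_LABELS = ("LV", "REPERFUSION", "INFARCT", "SALVAGE")


@dataclass
class VolumeImage:
    """A 3-D intensity volume with per-axis voxel spacing in mm.

    Axis order is (x, y, slice); coordinates are 0-based.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    contrast: str

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3-D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")
        if self.contrast not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class Mask3D:
    """Boolean voxel mask sharing the grid of its source volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    label: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")
        if self.label not in MASK_LABELS:
            raise ValueError(f"label must be one of {MASK_LABELS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class VolumetryResult:
    """Volumes (mm^3) and normalized percentages for one animal / phantom.

    ``salvage`` is defined from voxel counts (``reperfusion - infarct``) so
    the conservation ``salvage_voxels + infarct_voxels == reperfusion_voxels``
    holds exactly.  When the reperfusion volume is zero the three
    reperfusion-normalized percentages are NaN (undefined, never silently 0).
    """

    lv_volume: float
    reperfusion_volume: float
    infarct_volume: float
    salvage_volume: float
    infarct_fraction_of_reperfusion: float  # percent
    salvage_fraction_of_reperfusion: float  # percent
    reperfusion_fraction_of_lv: float  # percent
    infarct_fraction_of_lv: float  # percent
    salvage_fraction_of_lv: float  # percent
    lv_voxels: int = 0
    reperfusion_voxels: int = 0
    infarct_voxels: int = 0
    salvage_voxels: int = 0

    FIELDS = (
        "lv_volume",
        "reperfusion_volume",
        "infarct_volume",
        "salvage_volume",
        "infarct_fraction_of_reperfusion",
        "salvage_fraction_of_reperfusion",
        "reperfusion_fraction_of_lv",
        "infarct_fraction_of_lv",
        "salvage_fraction_of_lv",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}


# ---------------------------------------------------------------------------
# NMR
# ---------------------------------------------------------------------------

GROUPS = ("vehicle/sham", "vehicle/IR", "SCN/sham", "SCN/IR")
TIMEPOINTS_NMR = ("24h", "4w")


@dataclass
class Spectrum1D:
    """A 1-D spectrum: strictly monotone ppm axis plus intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    group: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        if self.ppm.size >= 2:
            d = np.diff(self.ppm)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def copy_with(self, **kwargs) -> "Spectrum1D":
        data = dict(
            ppm=self.ppm,
            intensity=self.intensity,
            sample_id=self.sample_id,
            group=self.group,
            timepoint=self.timepoint,
        )
        data.update(kwargs)
        return Spectrum1D(**data)


@dataclass
class MetaboliteAssignment:
    """A named chemical shift with an integration half-window (ppm)."""

    name: str
    shift_ppm: float
    window_halfwidth_ppm: float = 0.02

    def __post_init__(self) -> None:
        if self.window_halfwidth_ppm <= 0:
            raise ValueError("window_halfwidth_ppm must be positive")


@dataclass
class FoldChangeEntry:
    metabolite: str
    comparison: str
    fold_change: float
    p_value: float
    significant: bool
    shift_ppm: float = math.nan


# ---------------------------------------------------------------------------
# Histology
# ---------------------------------------------------------------------------

#: Fixed distance-to-ligation grid (micrometres).
DISTANCE_GRID_UM = (0, 600, 1200, 1800, 2400, 3000, 3600, 4200, 4800)

CHANNELS = ("DAPI", "2D10G9", "TRICHROME")


@dataclass
class SectionImage:
    """A single tissue-section image plus acquisition metadata."""

    pixels: np.ndarray
    um_per_pixel: float
    distance_um: int
    animal_id: str
    channel: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if self.channel == "TRICHROME":
            if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
                raise ValueError("trichrome images must be RGB (H, W, 3)")
        elif self.pixels.ndim != 2:
            raise ValueError("fluorescence images must be 2-D grayscale")

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3


@dataclass
class SectionQuant:
    """Per-section measurements keyed by distance to the ligation site."""

    animal_id: str
    distance_um: int
    mean_intensity: float = math.nan
    percent_positive: float = math.nan
    collagen_area_um2: float = math.nan
    collagen_percent: float = math.nan
    group: str = ""


# ---------------------------------------------------------------------------
# Echo / serum
# ---------------------------------------------------------------------------

ECHO_SITES = ("base", "mid", "apex")
ECHO_TIMEPOINTS = ("pre", "48h", "1w", "2w", "4w")


@dataclass
class EchoRecord:
    animal_id: str
    group: str
    site: str
    timepoint: str
    lv_diastole: float
    lv_systole: float
    lved_area: float = math.nan
    lves_area: float = math.nan
    flagged: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        # Physiologically d >= s > 0; violations are flagged, not dropped.
        self.flagged = not (self.lv_diastole >= self.lv_systole > 0)


@dataclass
class StandardCurve:
    concentrations: np.ndarray
    peak_areas: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.peak_areas = np.asarray(self.peak_areas, dtype=float)
        if self.concentrations.size < 3:
            raise ValueError("a standard curve needs at least 3 points")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    test_name: str
    comparison: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


# ---------------------------------------------------------------------------
# Ground truth containers emitted by the synthetic generators
# ---------------------------------------------------------------------------


@dataclass
class PhantomTruth:
    """Ground truth for one cardiac phantom."""

    lv_mask: np.ndarray
    reperfusion_mask: np.ndarray
    infarct_mask: np.ndarray
    infarct_fraction: float
    snr: float
    seed: int

    def __post_init__(self) -> None:
        lv = np.asarray(self.lv_mask, bool)
        rep = np.asarray(self.reperfusion_mask, bool)
        inf = np.asarray(self.infarct_mask, bool)
        if not np.all(lv[rep]) or not np.all(rep[inf]):
            raise ValueError("containment violated: infarct ⊆ reperfusion ⊆ LV required")

    @property
    def realized_infarct_fraction(self) -> float:
        rep = int(np.count_nonzero(self.reperfusion_mask))
        inf = int(np.count_nonzero(self.infarct_mask))
        return inf / rep if rep else math.nan


@dataclass
class CohortTruth:
    """Ground truth for one synthetic NMR cohort."""

    group_labels: list[str]
    sample_ids: list[str]
    metabolite_concentrations: "object"  # pandas DataFrame, sample x metabolite
    group_mean_concentrations: "object"  # pandas DataFrame, group x metabolite
    planted_fold_changes: "object"  # pandas DataFrame, metabolite x comparison
    dilution_factors: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.dilution_factors = np.asarray(self.dilution_factors, dtype=float)
        if np.any(self.dilution_factors <= 0):
            raise ValueError("dilution factors must be positive")


@dataclass
class SectionTruth:
    """Ground truth for one synthetic histology section."""

    distance_um: int
    true_positive_fraction: float
    true_collagen_fraction: float
    um_per_pixel: float
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.distance_um not in DISTANCE_GRID_UM:
            raise ValueError(f"distance_um must be one of {DISTANCE_GRID_UM}")
        for f in (self.true_positive_fraction, self.true_collagen_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
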