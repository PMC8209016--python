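"""Seeded synthetic-data generators with recorded ground truth.

Every generator is a pure function of its arguments (including ``seed``):
calling it twice with identical arguments yields bit-identical output.  Each
generator returns, alongside the data, a truth container that the consuming
analysis module is tested against (parameter recovery).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    CohortTruth,
    GROUPS,
    Mask3D,
    MetaboliteAssignment,
    PhantomTruth,
    SectionTruth,
    Spectrum1D,
    VolumeImage,
)

__all__ = [
    "generate_cardiac_phantom",
    "generate_nmr_cohort",
    "generate_histology_section",
    "generate_section_cohort",
    "generate_echo_series",
    "generate_standard_curve_data",
]


# ---------------------------------------------------------------------------
# Cardiac MRI phantom
# ---------------------------------------------------------------------------


def _annulus_geometry(grid_shape, spacing):
    """Physical-coordinate radius and angle maps for the in-plane grid."""
    nx, ny, _ = grid_shape
    dx, dy, _ = spacing
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    return np.hypot(xx, yy), np.arctan2(yy, xx)


def generate_cardiac_phantom(
    grid_shape: tuple[int, int, int] = (64, 64, 16),
    spacing: tuple[float, float, float] = (0.117, 0.117, 0.28),
    infarct_fraction: float = 0.5,
    wedge_angle: float = 70.0,
    snr: float | None = 20.0,
    seed: int = 0,
    *,
    t1_polarity: int = -1,
    tissue_signal: float = 1.0,
    void_signal: float = 0.54,
    background_signal: float = 1.0,
    t1_tissue_signal: float = 0.1,
    t1_infarct_signal: float = 0.9,
) -> tuple[VolumeImage, VolumeImage, Mask3D, PhantomTruth]:
    """Build a dual-contrast left-ventricle phantom with known masks.

    The LV is a circular annulus per slice; the reperfused territory is an
    angular wedge over the central slice band; the infarct is the radially
    innermost subset of the wedge sized to the requested fraction of wedge
    voxels.  The T2* volume carries a signal void inside the reperfusion
    territory (iron), the signed T1 inversion-recovery volume carries
    enhanced-magnitude voxels inside the infarct (gadolinium); Rician noise
    is added to the T2* magnitude image and Gaussian noise to the signed T1
    image, both at the requested SNR.

    Parameters
    ----------
    snr : float or None
        Mean tissue signal divided by the noise standard deviation.  ``None``
        (or ``inf``) disables noise.
    t1_polarity : {-1, +1}
        Sign of the infarct signal in the real-valued T1 reconstruction.

    Returns
    -------
    (t2star, t1ir, lv_mask, truth)
    """
    nx, ny, nz = (int(v) for v in grid_shape)
    if nx < 32 or ny < 32:
        raise ValueError("each in-plane dimension must be >= 32")
    if not (0.0 <= infarct_fraction <= 1.0):
        raise ValueError("infarct_fraction must lie in [0, 1]")
    if not (0.0 < wedge_angle <= 360.0):
        raise ValueError("wedge_angle must lie in (0, 360] degrees")
    if snr is not None and not math.isinf(snr) and snr <= 0:
        raise ValueError("snr must be positive (or None for noise-free)")
    spacing = tuple(float(s) for s in spacing)

    radius, angle = _annulus_geometry((nx, ny, nz), spacing)
    dx, dy, _ = spacing
    r_out = 0.45 * min(nx * dx, ny * dy)  # 90% of the half-extent
    r_in = 0.55 * r_out
    annulus2d = (radius <= r_out) & (radius >= r_in)

    half = math.radians(wedge_angle) / 2.0
    wedge2d = annulus2d & (np.abs(angle) <= half)
    if not wedge2d.any():
        raise ValueError("grid too small to realize the requested wedge")

    lv = np.zeros((nx, ny, nz), dtype=bool)
    rep = np.zeros_like(lv)
    z0, z1 = nz // 4, nz - nz // 4  # central slice band
    lv[:, :, :] = annulus2d[:, :, None]
    rep[:, :, z0:z1] = wedge2d[:, :, None]

    # Infarct: k radially innermost wedge voxels, deterministic ordering.
    rep_idx = np.flatnonzero(rep)
    rep_r = np.broadcast_to(radius[:, :, None], rep.shape).ravel()[rep_idx]
    order = np.lexsort((rep_idx, rep_r))  # radius then flat index: stable
    k = int(round(infarct_fraction * rep_idx.size))
    inf_mask = np.zeros_like(lv)
    inf_mask.ravel()[rep_idx[order[:k]]] = True

    # Noise-free signal models.
    t2_clean = np.full(lv.shape, background_signal, dtype=float)
    t2_clean[lv] = tissue_signal
    t2_clean[rep] = void_signal

    t1_clean = np.zeros(lv.shape, dtype=float)
    t1_clean[lv] = t1_tissue_signal
    t1_clean[inf_mask] = t1_polarity * t1_infarct_signal

    rng = np.random.default_rng(seed)
    if snr is not None and math.isfinite(snr):
        sigma_t2 = tissue_signal / snr
        # Rician magnitude: |signal + complex Gaussian noise|
        n_re = rng.normal(0.0, sigma_t2, size=t2_clean.shape)
        n_im = rng.normal(0.0, sigma_t2, size=t2_clean.shape)
        t2 = np.hypot(t2_clean + n_re, n_im)
        sigma_t1 = t1_infarct_signal / snr
        t1 = t1_clean + rng.normal(0.0, sigma_t1, size=t1_clean.shape)
        snr_out = float(snr)
    else:
        t2, t1 = t2_clean, t1_clean
        snr_out = math.inf

    truth = PhantomTruth(
        lv_mask=lv,
        reperfusion_mask=rep,
        infarct_mask=inf_mask,
        infarct_fraction=float(infarct_fraction),
        snr=snr_out,
        seed=int(seed),
    )
    return (
        VolumeImage(t2, spacing, "T2STAR"),
        VolumeImage(t1, spacing, "T1IR"),
        Mask3D(lv, spacing, "LV"),
        truth,
    )


# ---------------------------------------------------------------------------
# NMR cohort
# ---------------------------------------------------------------------------

PPM_MIN, PPM_MAX = -1.0, 10.0
WATER_CUT = (4.67, 4.98)


def _lorentzian(ppm: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-area Lorentzian line shape."""
    return (hwhm / math.pi) / ((ppm - center) ** 2 + hwhm**2)


def default_background_shifts(
    assignments: "list[MetaboliteAssignment]",
    step: float = 0.1,
    exclusion_ppm: float = 0.18,
) -> tuple[float, ...]:
    """Grid of chemical shifts for group-invariant background resonances.

    Serum spectra are dominated by signals that do not respond to the
    intervention; without them a quotient-based normalization would absorb
    part of the planted group effect.  Candidates run over the working ppm
    range at ``step`` spacing, excluding the water band, the reference-peak
    neighborhood, and ``exclusion_ppm`` around every assigned shift (keeps
    window cross-talk negligible).
    """
    shifts = []
    c = 0.3
    while c < 9.95:
        cc = round(c, 2)
        ok = WATER_CUT[0] - 0.05 > cc or cc > WATER_CUT[1] + 0.05
        ok = ok and all(abs(cc - a.shift_ppm) >= exclusion_ppm for a in assignments)
        if ok:
            shifts.append(cc)
        c += step
    return tuple(shifts)


def _group_means_from_folds(
    metabolites: list[str],
    planted_folds: pd.DataFrame,
    base_concentration: float,
) -> pd.DataFrame:
    """Group-mean concentration table realizing all three planted fold columns.

    With ``f1 = veh_sham_vs_veh_IR``, ``f2 = SCN_sham_vs_SCN_IR`` and
    ``f3 = veh_IR_vs_SCN_IR`` (each fold = second arm / first arm):

        vehicle/sham = base            vehicle/IR = base * f1
        SCN/IR       = vehicle/IR * f3 SCN/sham   = SCN/IR / f2
    """
    f1 = planted_folds["veh_sham_vs_veh_IR"].reindex(metabolites)
    f2 = planted_folds["SCN_sham_vs_SCN_IR"].reindex(metabolites)
    f3 = planted_folds["veh_IR_vs_SCN_IR"].reindex(metabolites)
    if f1.isna().any() or f2.isna().any() or f3.isna().any():
        raise ValueError("planted_folds must cover every assigned metabolite")
    base = pd.Series(base_concentration, index=metabolites)
    means = pd.DataFrame(index=list(GROUPS), columns=metabolites, dtype=float)
    means.loc["vehicle/sham"] = base
    means.loc["vehicle/IR"] = base * f1
    means.loc["SCN/IR"] = base * f1 * f3
    means.loc["SCN/sham"] = base * f1 * f3 / f2
    return means


def generate_nmr_cohort(
    n_per_group: int,
    assignments: list[MetaboliteAssignment],
    planted_folds: pd.DataFrame,
    peak_width_ppm: float = 0.002,
    dilution_sd: float = 0.2,
    noise_sd: float = 1.0,
    seed: int = 0,
    *,
    within_cv: float = 0.05,
    base_concentration: float = 10.0,
    n_points: int = 8192,
    tsp_offset_ppm: float = 0.0,
    tsp_amplitude: float = 5.0,
    water_amplitude: float = 50.0,
    background_shifts: tuple[float, ...] | None = None,
    timepoint: str = "24h",
) -> tuple[list[Spectrum1D], CohortTruth]:
    """Simulate a four-group serum cohort of Lorentzian-peak spectra.

    Each spectrum is a sum of unit-area Lorentzians at the assigned shifts,
    scaled by (per-sample true concentration x per-sample dilution factor),
    plus a reference peak near 0 ppm, a residual-water bump inside the
    4.67-4.98 ppm band, and Gaussian baseline noise.

    ``planted_folds`` must be a metabolite-indexed DataFrame with the three
    comparison columns of :data:`irquant.panel.COMPARISONS`; group means are
    constructed so that every planted ratio holds exactly on the group-mean
    concentrations.  Per-sample concentrations are mean-preserving lognormal
    around the group means with coefficient of variation ``within_cv``;
    dilution factors are lognormal with log-sd ``dilution_sd``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if peak_width_ppm <= 0:
        raise ValueError("peak_width_ppm must be positive")
    for a in assignments:
        if not (PPM_MIN <= a.shift_ppm <= PPM_MAX):
            raise ValueError(f"shift {a.shift_ppm} outside [{PPM_MIN}, {PPM_MAX}] ppm")

    rng = np.random.default_rng(seed)
    if background_shifts is None:
        background_shifts = default_background_shifts(assignments)
    ppm = np.linspace(PPM_MIN, PPM_MAX, n_points)
    metabolites = [a.name for a in assignments]
    means = _group_means_from_folds(metabolites, planted_folds, base_concentration)

    # Mean-preserving lognormal: E[exp(N(-s^2/2, s^2))] = 1.
    s_conc = math.sqrt(math.log(1.0 + within_cv**2)) if within_cv > 0 else 0.0

    spectra: list[Spectrum1D] = []
    sample_ids: list[str] = []
    group_labels: list[str] = []
    conc_rows = []
    dilutions = []
    # Precompute the line-shape basis (metabolite x ppm).
    basis = np.stack([_lorentzian(ppm, a.shift_ppm, peak_width_ppm) for a in assignments])
    bg_basis = (
        np.stack([_lorentzian(ppm, s, peak_width_ppm) for s in background_shifts])
        if background_shifts
        else np.zeros((0, ppm.size))
    )
    tsp_line = _lorentzian(ppm, tsp_offset_ppm, peak_width_ppm)
    water_center = 0.5 * (WATER_CUT[0] + WATER_CUT[1])
    water_line = np.exp(-0.5 * ((ppm - water_center) / 0.05) ** 2)

    idx = 0
    for group in GROUPS:
        gmean = means.loc[group].to_numpy()
        for _ in range(n_per_group):
            idx += 1
            sid = f"S{idx:03d}"
            conc = gmean * (
                rng.lognormal(-0.5 * s_conc**2, s_conc, size=gmean.size)
                if s_conc > 0
                else 1.0
            )
            dil = float(rng.lognormal(0.0, dilution_sd)) if dilution_sd > 0 else 1.0
            water_amp = water_amplitude * (0.5 + rng.random())
            bg_conc = 2.0 * base_concentration * (
                rng.lognormal(-0.5 * s_conc**2, s_conc, size=len(background_shifts))
                if s_conc > 0 and len(background_shifts)
                else np.ones(len(background_shifts))
            )
            signal = conc @ basis
            if len(background_shifts):
                signal = signal + bg_conc @ bg_basis
            intensity = dil * signal + tsp_amplitude * tsp_line
            intensity = intensity + water_amp * water_line
            if noise_sd > 0:
                intensity = intensity + rng.normal(0.0, noise_sd, size=ppm.size)
            spectra.append(
                Spectrum1D(ppm, intensity, sample_id=sid, group=group, timepoint=timepoint)
            )
            sample_ids.append(sid)
            group_labels.append(group)
            conc_rows.append(conc)
            dilutions.append(dil)

    truth = CohortTruth(
        group_labels=group_labels,
        sample_ids=sample_ids,
        metabolite_concentrations=pd.DataFrame(
            conc_rows, index=sample_ids, columns=metabolites
        ),
        group_mean_concentrations=means,
        planted_fold_changes=planted_folds.copy(),
        dilution_factors=np.asarray(dilutions),
        seed=int(seed),
    )
    return spectra, truth


# ---------------------------------------------------------------------------
# Histology sections
# ---------------------------------------------------------------------------

FLUOR_BACKGROUND = 100  # below the 150 background threshold
FLUOR_TISSUE = 250  # in (150, 350]
FLUOR_POSITIVE = 600  # above the 350 positive threshold

RGB_BACKGROUND = (245, 245, 245)
RGB_MYOCARDIUM = (180, 40, 50)
RGB_COLLAGEN = (60, 60, 180)


def _tissue_ellipse(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return ((yy - cy) / (0.4 * h)) ** 2 + ((xx - cx) / (0.4 * w)) ** 2 <= 1.0


def generate_histology_section(
    truth: SectionTruth,
    image_shape: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SectionTruth]:
    """Render one fluorescence + one trichrome-like image from a truth record.

    The fluorescence image (uint16) holds an elliptical tissue region whose
    pixels all exceed the 150 background threshold; an exact
    ``round(true_positive_fraction * n_tissue)`` random subset exceeds the
    350 positive threshold.  The RGB image colors an exact
    ``round(true_collagen_fraction * n_tissue)`` subset collagen-blue and the
    remainder myocardium-red on a pale background.
    """
    rng = np.random.default_rng(seed)
    tissue = _tissue_ellipse(tuple(int(v) for v in image_shape))
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("image_shape too small to hold a tissue region")
    tissue_idx = np.flatnonzero(tissue)

    fluor = np.full(tissue.shape, FLUOR_BACKGROUND, dtype=np.uint16)
    fluor[tissue] = FLUOR_TISSUE
    k_pos = int(round(truth.true_positive_fraction * n_tissue))
    pos = rng.choice(tissue_idx, size=k_pos, replace=False)
    fluor.ravel()[pos] = FLUOR_POSITIVE

    rgb = np.empty(tissue.shape + (3,), dtype=np.uint8)
    rgb[:, :] = RGB_BACKGROUND
    rgb[tissue] = RGB_MYOCARDIUM
    k_col = int(round(truth.true_collagen_fraction * n_tissue))
    col = rng.choice(tissue_idx, size=k_col, replace=False)
    flat = rgb.reshape(-1, 3)
    flat[col] = RGB_COLLAGEN

    return fluor, rgb, truth


def generate_section_cohort(
    n_animals_per_group: int = 6,
    seed: int = 0,
    *,
    groups: tuple[str, str] = ("vehicle/IR", "SCN/IR"),
    positive_at_ligation: float = 0.5,
    positive_decay_per_um: float = 8e-5,
    collagen_mean: float = 0.25,
    collagen_positive_r: float = 0.0,
    fraction_sd: float = 0.05,
    um_per_pixel: float = 6.45,
) -> list[SectionTruth]:
    """Truth records for a two-group section cohort over the distance grid.

    The positive-fluorescence fraction decays linearly with distance to the
    ligation (plus Gaussian scatter of sd ``fraction_sd``).  Collagen
    fractions are constructed conditionally on the realized positive
    fractions so that the *pooled* correlation between the two fractions
    targets ``collagen_positive_r`` (per group), with collagen sd
    ``fraction_sd``.  Fractions are clipped to [0.01, 0.99].
    """
    from .datatypes import DISTANCE_GRID_UM

    rng = np.random.default_rng(seed)
    rho = float(collagen_positive_r)
    if not (-1.0 <= rho <= 1.0):
        raise ValueError("collagen_positive_r must lie in [-1, 1]")
    truths: list[SectionTruth] = []
    for group in groups:
        animals = [
            f"{group.replace('/', '-')}-{a + 1:02d}" for a in range(n_animals_per_group)
        ]
        cells = [(animal, d) for animal in animals for d in DISTANCE_GRID_UM]
        trend = np.array(
            [positive_at_ligation - positive_decay_per_um * d for _, d in cells]
        )
        pos = np.clip(trend + fraction_sd * rng.normal(size=len(cells)), 0.01, 0.99)
        # conditional construction: corr(col, pos) = rho, sd(col) = fraction_sd
        sp = pos.std(ddof=0)
        z = rng.normal(size=len(cells))
        col = collagen_mean + fraction_sd * (
            rho * (pos - pos.mean()) / sp + math.sqrt(1.0 - rho**2) * z
        )
        col = np.clip(col, 0.01, 0.99)
        for (animal, d), p, c in zip(cells, pos, col):
            truths.append(
                SectionTruth(
                    distance_um=d,
                    true_positive_fraction=float(p),
                    true_collagen_fraction=float(c),
                    um_per_pixel=um_per_pixel,
                    animal_id=animal,
                    group=group,
                )
            )
    return truths


# ---------------------------------------------------------------------------
# Echocardiography
# ---------------------------------------------------------------------------


def generate_echo_series(
    group_effects: pd.DataFrame,
    sd: float = 0.3,
    n_per_group: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an M-mode diameter table around per-cell group means.

    ``group_effects`` needs columns ``group, site, timepoint, lvd_mm, lvs_mm``
    (one row per cell).  Each animal contributes one record per cell with
    independent Gaussian deviations of standard deviation ``sd`` added to
    both diameters (systole re-drawn to stay below diastole is *not*
    enforced; physiology violations are the analysis module's job to flag).
    """
    req = {"group", "site", "timepoint", "lvd_mm", "lvs_mm"}
    if not req.issubset(group_effects.columns):
        raise ValueError(f"group_effects must have columns {sorted(req)}")
    if (group_effects["lvd_mm"] <= group_effects["lvs_mm"]).any():
        raise ValueError("LVd means must exceed LVs means")
    if (group_effects["lvs_mm"] <= 0).any():
        raise ValueError("diameter means must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")

    rng = np.random.default_rng(seed)
    rows = []
    for group, gdf in group_effects.groupby("group", sort=True):
        for a in range(n_per_group):
            animal = f"{group.replace('/', '-')}-{a + 1:02d}"
            for row in gdf.itertuples(index=False):
                lvd = row.lvd_mm + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                lvs = row.lvs_mm + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                rows.append(
                    dict(
                        animal_id=animal,
                        group=group,
                        site=row.site,
                        timepoint=row.timepoint,
                        lvd_mm=lvd,
                        lvs_mm=lvs,
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ion-chromatography standard curve
# ---------------------------------------------------------------------------

CALIBRATION_UM = (0.0, 25.0, 50.0, 100.0, 150.0, 200.0)


def generate_standard_curve_data(
    true_unknowns: list[float],
    slope: float = 0.5,
    noise_cv: float = 0.0,
    seed: int = 0,
    *,
    calibration_um: tuple[float, ...] = CALIBRATION_UM,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a 0-200 uM calibration table plus unknown peak areas.

    Areas follow ``area = slope * concentration`` with multiplicative
    Gaussian noise of coefficient of variation ``noise_cv``.
    """
    unknowns = np.asarray(true_unknowns, dtype=float)
    if np.any(unknowns < 0):
        raise ValueError("unknown concentrations must be >= 0")
    if slope <= 0:
        raise ValueError("slope must be positive")
    rng = np.random.default_rng(seed)
    conc = np.asarray(calibration_um, dtype=float)

    def areas(c):
        a = slope * c
        if noise_cv > 0:
            a = a * (1.0 + rng.normal(0.0, noise_cv, size=np.shape(c)))
        return a

    calib = pd.DataFrame({"concentration_um": conc, "peak_area": areas(conc)})
    return calib, np.asarray(areas(unknowns), dtype=float)
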