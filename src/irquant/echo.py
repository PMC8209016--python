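"""Echocardiographic indices and ion-chromatography standard curves."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ECHO_SITES, ECHO_TIMEPOINTS, StandardCurve
from .stats import AnovaPosthocResult, two_way_anova_posthoc

__all__ = [
    "fractional_shortening",
    "echo_trajectory",
    "fit_standard_curve",
    "quantify_scn",
]


def fractional_shortening(lv_diastole, lv_systole):
    """Fractional shortening in percent: 100 * (d - s) / d.

    Accepts scalars or arrays; diastolic diameters must be positive.
    """
    d = np.asarray(lv_diastole, float)
    s = np.asarray(lv_systole, float)
    if np.any(d <= 0):
        raise ValueError("diastolic diameter must be positive")
    out = 100.0 * (d - s) / d
    return float(out) if out.ndim == 0 else out


METRIC_COLUMNS = {
    "FS": None,  # derived from lvd_mm / lvs_mm
    "LVD": "lvd_mm",
    "LVS": "lvs_mm",
    "LVED": "lved_area",
    "LVES": "lves_area",
}


def echo_trajectory(
    records: pd.DataFrame,
    metric: str = "FS",
    posthoc: str = "dunnett",
    control_level: str | None = None,
) -> tuple[pd.DataFrame, dict[str, AnovaPosthocResult]]:
    """Per-(group, site, timepoint) mean ± SEM table + per-site two-way ANOVA.

    ``records`` needs columns ``animal_id, group, site, timepoint`` plus the
    metric source columns.  Cells with fewer than 2 records are listed in the
    summary with their actual n (never imputed); sites whose layout is
    incomplete get no ANOVA (recorded as None).
    """
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"metric must be one of {sorted(METRIC_COLUMNS)}")
    df = records.copy()
    if metric == "FS":
        df["_value"] = fractional_shortening(df["lvd_mm"], df["lvs_mm"])
    else:
        col = METRIC_COLUMNS[metric]
        if col not in df.columns:
            raise ValueError(f"records lack column {col!r} needed for metric {metric}")
        df["_value"] = df[col].astype(float)

    rows = []
    for (group, site, tp), cell in df.groupby(["group", "site", "timepoint"], sort=False):
        vals = cell["_value"].to_numpy()
        rows.append(
            dict(
                group=group,
                site=site,
                timepoint=tp,
                mean=float(vals.mean()),
                sem=float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
                n=vals.size,
            )
        )
    summary = pd.DataFrame(rows)
    site_order = [s for s in ECHO_SITES if s in summary["site"].unique()]
    tp_order = [t for t in ECHO_TIMEPOINTS if t in summary["timepoint"].unique()]
    summary["site"] = pd.Categorical(summary["site"], site_order, ordered=True)
    summary["timepoint"] = pd.Categorical(summary["timepoint"], tp_order, ordered=True)
    summary = summary.sort_values(["site", "timepoint", "group"]).reset_index(drop=True)

    if posthoc == "dunnett" and control_level is None:
        posthoc = None  # no control group named: omnibus tests only
    anovas: dict[str, AnovaPosthocResult | None] = {}
    for site in site_order:
        sub = df[df["site"] == site]
        try:
            anovas[site] = two_way_anova_posthoc(
                sub,
                value="_value",
                factor_a="group",
                factor_b="timepoint",
                posthoc=posthoc,
                control_level=control_level,
            )
        except ValueError as err:
            if "missing cells" not in str(err):
                raise
            anovas[site] = None  # incomplete layout: reported, not imputed
    return summary, anovas


def fit_standard_curve(concentrations, peak_areas) -> StandardCurve:
    """Ordinary least-squares calibration line; warns when r^2 < 0.99."""
    conc = np.asarray(concentrations, float)
    area = np.asarray(peak_areas, float)
    if conc.size < 3 or conc.size != area.size:
        raise ValueError("need >= 3 matched calibration points")
    if np.all(conc == conc[0]):
        raise ValueError("degenerate design: all concentrations equal")
    res = sps.linregress(conc, area)
    r2 = float(res.rvalue**2)
    if not np.isfinite(r2) or r2 < 0.99:
        warnings.warn(f"standard curve r^2 = {r2:.4f} < 0.99", stacklevel=2)
    return StandardCurve(
        concentrations=conc,
        peak_areas=area,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
    )


def quantify_scn(peak_area, curve: StandardCurve):
    """Inverse prediction (area - intercept) / slope, in uM.

    Negative predictions are clamped to 0 with a warning.
    """
    if curve.slope <= 0:
        raise ValueError("invalid standard curve: slope must be positive")
    area = np.asarray(peak_area, float)
    conc = (area - curve.intercept) / curve.slope
    if np.any(conc < 0):
        warnings.warn("negative concentration predicted; clamped to 0", stacklevel=2)
        conc = np.maximum(conc, 0.0)
    return float(conc) if conc.ndim == 0 else conc
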