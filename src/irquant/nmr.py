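"""Serum 1H-NMR processing chain.

Referencing to the 0.00 ppm standard, water-band truncation, probabilistic
quotient normalization (PQN), fixed-window metabolite quantification,
fold-change tables with Welch tests, PCA, and OPLS-DA with label-permutation
validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FoldChangeEntry, MetaboliteAssignment, Spectrum1D
from .stats import benjamini_hochberg, welch_t_test

__all__ = [
    "reference_to_tsp",
    "truncate_water",
    "pqn_normalize",
    "quantify_metabolites",
    "quantify_cohort",
    "fold_change_table",
    "pca_scores",
    "OplsdaModel",
    "oplsda_fit_and_permute",
    "heatmap_matrix",
]

PPM_MIN, PPM_MAX = -1.0, 10.0
WATER_CUT = (4.67, 4.98)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def reference_to_tsp(
    spec: Spectrum1D, search_window: tuple[float, float] = (-0.2, 0.2)
) -> Spectrum1D:
    """Shift the ppm axis so the reference apex inside the window sits at 0.

    Intensities are untouched; only the axis translates.
    """
    lo, hi = sorted(search_window)
    sel = (spec.ppm >= lo) & (spec.ppm <= hi)
    if not sel.any():
        raise ValueError("search window contains no points")
    window_int = spec.intensity[sel]
    window_ppm = spec.ppm[sel]
    apex = int(np.argmax(window_int))
    baseline = float(np.median(spec.intensity))
    if window_int[apex] <= baseline:
        raise ValueError("no detectable reference peak inside the search window")
    shift = float(window_ppm[apex])
    return spec.copy_with(ppm=spec.ppm - shift)


def truncate_water(
    spec: Spectrum1D,
    cut: tuple[float, float] = WATER_CUT,
    domain: tuple[float, float] = (PPM_MIN, PPM_MAX),
) -> Spectrum1D:
    """Drop the residual-water band and restrict to the working ppm domain."""
    lo, hi = sorted(cut)
    dlo, dhi = sorted(domain)
    keep = (spec.ppm >= dlo) & (spec.ppm <= dhi) & ~((spec.ppm >= lo) & (spec.ppm <= hi))
    return spec.copy_with(ppm=spec.ppm[keep], intensity=spec.intensity[keep])


def pqn_normalize(
    cohort: list[Spectrum1D], noise_floor_mult: float = 5.0
) -> tuple[list[Spectrum1D], np.ndarray]:
    """Probabilistic quotient normalization against the cohort median spectrum.

    The reference is the pointwise median across spectra; the per-sample
    factor is the median, over variables where the reference exceeds a noise
    floor (``noise_floor_mult`` times the robust baseline scale of the
    reference), of sample/reference intensity quotients.  Each spectrum is
    divided by its factor.  Factors are returned in cohort order.
    """
    if len(cohort) < 2:
        raise ValueError("PQN needs at least 2 spectra")
    axis = cohort[0].ppm
    for s in cohort[1:]:
        if s.ppm.shape != axis.shape or not np.allclose(s.ppm, axis):
            raise ValueError("all spectra must share one ppm axis")
    mat = np.stack([s.intensity for s in cohort])
    ref = np.median(mat, axis=0)
    # Robust baseline scale: most points are baseline, so the MAD of the
    # reference estimates its noise level.
    mad = np.median(np.abs(ref - np.median(ref)))
    floor = noise_floor_mult * 1.4826 * mad
    eligible = ref > floor
    if not eligible.any():
        # flat or all-noise reference: fall back to the top decile
        eligible = ref >= np.quantile(ref, 0.9)
    if not np.any(ref[eligible] != 0):
        raise ValueError("degenerate (all-zero) reference spectrum")
    quotients = mat[:, eligible] / ref[eligible]
    factors = np.median(quotients, axis=1)
    if np.any(factors <= 0):
        raise ValueError("non-positive normalization factor encountered")
    normalized = [
        s.copy_with(intensity=s.intensity / f) for s, f in zip(cohort, factors)
    ]
    return normalized, factors


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------


def quantify_metabolites(
    spec: Spectrum1D,
    assignments: list[MetaboliteAssignment],
    water_cut: tuple[float, float] = WATER_CUT,
) -> pd.Series:
    """Trapezoidal integral of intensity over shift ± halfwidth per metabolite.

    Windows overlapping the water cut are reduced (with a warning); an empty
    window raises.
    """
    values = {}
    wlo, whi = sorted(water_cut)
    for a in assignments:
        lo, hi = a.shift_ppm - a.window_halfwidth_ppm, a.shift_ppm + a.window_halfwidth_ppm
        if lo < whi and hi > wlo:
            warnings.warn(
                f"integration window for {a.name} overlaps the water cut; reduced",
                stacklevel=2,
            )
        sel = (spec.ppm >= lo) & (spec.ppm <= hi)
        if int(sel.sum()) < 2:
            raise ValueError(f"empty integration window for {a.name} at {a.shift_ppm} ppm")
        values[a.name] = float(np.trapezoid(spec.intensity[sel], spec.ppm[sel]))
    return pd.Series(values, name=spec.sample_id)


def quantify_cohort(
    cohort: list[Spectrum1D], assignments: list[MetaboliteAssignment]
) -> pd.DataFrame:
    """Sample x metabolite quantification table for a whole cohort."""
    rows = [quantify_metabolites(s, assignments) for s in cohort]
    out = pd.DataFrame(rows)
    out.index = [s.sample_id for s in cohort]
    return out


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

#: comparison name -> (first arm, second arm); fold = mean(second)/mean(first)
DEFAULT_COMPARISONS = {
    "veh_sham_vs_veh_IR": ("vehicle/sham", "vehicle/IR"),
    "SCN_sham_vs_SCN_IR": ("SCN/sham", "SCN/IR"),
    "veh_IR_vs_SCN_IR": ("vehicle/IR", "SCN/IR"),
}


def fold_change_table(
    quant: pd.DataFrame,
    design: pd.Series,
    comparisons: dict[str, tuple[str, str]] | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
    shifts: dict[str, float] | None = None,
) -> list[FoldChangeEntry]:
    """Per-metabolite fold changes (second arm / first arm) with Welch tests.

    ``design`` maps sample id -> group label.  ``fdr=True`` applies
    Benjamini-Hochberg within each comparison before flagging significance;
    the default mirrors uncorrected per-metabolite testing.
    """
    comparisons = comparisons or DEFAULT_COMPARISONS
    shifts = shifts or {}
    design = design.reindex(quant.index)
    entries: list[FoldChangeEntry] = []
    for comp, (arm1, arm2) in comparisons.items():
        g1 = quant.loc[design == arm1]
        g2 = quant.loc[design == arm2]
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError(f"comparison {comp} needs >= 2 samples per arm")
        comp_entries = []
        for met in quant.columns:
            m1 = float(g1[met].mean())
            if m1 == 0.0:
                raise ValueError(f"zero mean in denominator arm for {met} ({comp})")
            fold = float(g2[met].mean()) / m1
            res = welch_t_test(g1[met], g2[met], comparison=comp)
            comp_entries.append(
                FoldChangeEntry(
                    metabolite=met,
                    comparison=comp,
                    fold_change=fold,
                    p_value=res.p_value,
                    significant=res.p_value < alpha,
                    shift_ppm=shifts.get(met, math.nan),
                )
            )
        if fdr:
            adj = benjamini_hochberg([e.p_value for e in comp_entries])
            for e, q in zip(comp_entries, adj):
                e.p_value = float(q)
                e.significant = bool(q < alpha)
        entries.extend(comp_entries)
    return entries


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_scores(matrix, n_components: int = 2):
    """Mean-centered PCA via SVD.

    Returns ``(scores, loadings, explained_variance_ratio)`` with orthonormal
    loadings (rows) and non-increasing explained variance.  Signs are fixed
    so the largest-magnitude loading coefficient of each component is
    positive (deterministic output).
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("matrix must be 2-D with >= 2 samples and >= 1 variable")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_components > max(rank, 1):
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    # deterministic sign convention
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = (u * s)[:, :n_components]
    loadings = vt[:n_components]
    var = s**2
    ratio = var[:n_components] / var.sum() if var.sum() > 0 else np.zeros(n_components)
    return scores, loadings, ratio


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def _opls_fit_batch(X: np.ndarray, Y: np.ndarray, n_orthogonal: int):
    """Fit O-PLS (1 predictive component) for a batch of response vectors.

    X: (n, p) centered; Y: (n, B) centered responses.  Returns the pieces
    needed for prediction: per-batch orthogonal loadings/weights and the
    final predictive weight/regression scalar.
    """
    n, p = X.shape
    B = Y.shape[1]
    Xb = np.broadcast_to(X[None], (B, n, p)).copy()
    Yb = Y.T[:, :, None]  # (B, n, 1)
    W_o, P_o = [], []
    for _ in range(n_orthogonal):
        w = np.swapaxes(Xb, 1, 2) @ Yb  # (B, p, 1)
        w = w / np.maximum(np.linalg.norm(w, axis=1, keepdims=True), 1e-300)
        t = Xb @ w  # (B, n, 1)
        tt = np.maximum(np.sum(t * t, axis=1, keepdims=True), 1e-300)
        pl = np.swapaxes(Xb, 1, 2) @ t / tt  # (B, p, 1)
        w_o = pl - (np.sum(w * pl, axis=1, keepdims=True)) * w
        norm = np.linalg.norm(w_o, axis=1, keepdims=True)
        norm = np.maximum(norm, 1e-300)
        w_o = w_o / norm
        t_o = Xb @ w_o
        tt_o = np.maximum(np.sum(t_o * t_o, axis=1, keepdims=True), 1e-300)
        p_o = np.swapaxes(Xb, 1, 2) @ t_o / tt_o
        Xb = Xb - t_o @ np.swapaxes(p_o, 1, 2)
        W_o.append(w_o)
        P_o.append(p_o)
    w = np.swapaxes(Xb, 1, 2) @ Yb
    w = w / np.maximum(np.linalg.norm(w, axis=1, keepdims=True), 1e-300)
    t = Xb @ w
    tt = np.maximum(np.sum(t * t, axis=1, keepdims=True), 1e-300)
    q = np.sum(t * Yb, axis=1, keepdims=True) / tt  # (B, 1, 1)
    return W_o, P_o, w, q, t


def _opls_predict_batch(Xnew: np.ndarray, W_o, P_o, w, q) -> np.ndarray:
    """Predict responses for new rows (shared across the batch)."""
    B = w.shape[0]
    m = Xnew.shape[0]
    Xb = np.broadcast_to(Xnew[None], (B, m, Xnew.shape[1])).copy()
    for w_o, p_o in zip(W_o, P_o):
        t_o = Xb @ w_o
        Xb = Xb - t_o @ np.swapaxes(p_o, 1, 2)
    t = Xb @ w
    return (t * q)[:, :, 0]  # (B, m)


def _q2_loo_batch(X: np.ndarray, Y: np.ndarray, n_orthogonal: int) -> np.ndarray:
    """Leave-one-out Q2 for each column of Y (batched)."""
    n = X.shape[0]
    B = Y.shape[1]
    press = np.zeros(B)
    for i in range(n):
        keep = np.arange(n) != i
        Xtr = X[keep]
        Ytr = Y[keep]
        mx = Xtr.mean(axis=0)
        my = Ytr.mean(axis=0)
        W_o, P_o, w, q, _ = _opls_fit_batch(Xtr - mx, Ytr - my, n_orthogonal)
        pred = _opls_predict_batch((X[i] - mx)[None, :], W_o, P_o, w, q)[:, 0] + my
        press += (Y[i] - pred) ** 2
    tss = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    return 1.0 - press / tss


@dataclass
class OplsdaModel:
    predictive_scores: np.ndarray
    predictive_loading: np.ndarray
    q2: float
    permutation_p: float
    permutation_q2: np.ndarray
    n_orthogonal: int


def oplsda_fit_and_permute(
    matrix,
    labels,
    n_orthogonal: int = 1,
    n_permutations: int = 1000,
    seed: int = 0,
) -> OplsdaModel:
    """OPLS-DA (one predictive + ``n_orthogonal`` orthogonal components).

    Binary class labels are coded ±1; Q2 is estimated by leave-one-out
    cross-validation and validated by random label permutation:
    ``p = (1 + #{Q2_perm >= Q2_obs}) / (1 + n_permutations)``.
    """
    X = np.asarray(matrix, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("OPLS-DA requires exactly two classes")
    if min(int((labels == c).sum()) for c in classes) < 3:
        raise ValueError("each class needs >= 3 samples")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.where(labels == classes[0], -1.0, 1.0)

    Xc = X - X.mean(axis=0)
    yc = (y - y.mean())[:, None]
    W_o, P_o, w, q, t = _opls_fit_batch(Xc, yc, n_orthogonal)
    q2_obs = float(_q2_loo_batch(X, y[:, None], n_orthogonal)[0])

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y) for _ in range(n_permutations)], axis=1)
    q2_perm = _q2_loo_batch(X, perms, n_orthogonal)
    p = (1.0 + int(np.sum(q2_perm >= q2_obs))) / (1.0 + n_permutations)

    return OplsdaModel(
        predictive_scores=t[0, :, 0],
        predictive_loading=w[0, :, 0],
        q2=q2_obs,
        permutation_p=float(p),
        permutation_q2=q2_perm,
        n_orthogonal=n_orthogonal,
    )


# ---------------------------------------------------------------------------
# Heatmap
# ---------------------------------------------------------------------------


def heatmap_matrix(entries: list[FoldChangeEntry], order: list[str] | None = None):
    """Metabolite x comparison fold-change matrix plus a rendered figure.

    Rows follow ``order`` when given, otherwise descending chemical shift
    (falling back to first-seen order for entries without a shift).  The
    figure uses a diverging colormap centered at fold 1.0 (red above, blue
    below).
    """
    if not entries:
        raise ValueError("entries must be non-empty")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm

    df = pd.DataFrame(
        {
            "metabolite": [e.metabolite for e in entries],
            "comparison": [e.comparison for e in entries],
            "fold": [e.fold_change for e in entries],
            "shift": [e.shift_ppm for e in entries],
        }
    )
    mat = df.pivot_table(index="metabolite", columns="comparison", values="fold", sort=False)
    if order is not None:
        mat = mat.reindex(order)
    else:
        shift = df.groupby("metabolite", sort=False)["shift"].first()
        if shift.notna().all():
            mat = mat.reindex(shift.sort_values(ascending=False).index)
    comp_order = list(dict.fromkeys(df["comparison"]))
    mat = mat[comp_order]

    vals = mat.to_numpy(float)
    lo = min(np.nanmin(vals), 1.0 - 1e-6)
    hi = max(np.nanmax(vals), 1.0 + 1e-6)
    norm = TwoSlopeNorm(vmin=lo, vcenter=1.0, vmax=hi)
    fig, ax = plt.subplots(figsize=(4 + 0.6 * mat.shape[1], 0.3 * mat.shape[0] + 2))
    im = ax.imshow(vals, cmap="RdBu_r", norm=norm, aspect="auto")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=30, ha="right")
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="fold change")
    fig.tight_layout()
    return mat, fig
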