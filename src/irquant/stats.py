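"""Statistical contracts used throughout the pipeline.

Welch t-test and Pearson correlation are implemented from the standard
formulas (with scipy distributions for tail probabilities); ANOVA post-hocs
use scipy/statsmodels primitives.  Newman-Keuls is implemented explicitly —
no mainstream library ships it — and annotated as liberal; Tukey HSD is
available as the conservative alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import TestResult

__all__ = [
    "welch_t_test",
    "one_way_anova_nk",
    "two_way_anova_posthoc",
    "pearson_r",
    "sidak_adjust",
    "benjamini_hochberg",
    "PairwiseDecision",
    "AnovaPosthocResult",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------


def welch_t_statistic(
    mean_x, var_x, n_x, mean_y, var_y, n_y
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t statistic and Welch-Satterthwaite df."""
    vx = np.asarray(var_x, float) / n_x
    vy = np.asarray(var_y, float) / n_y
    se2 = vx + vy
    t = (np.asarray(mean_x, float) - np.asarray(mean_y, float)) / np.sqrt(se2)
    df = se2**2 / (vx**2 / (n_x - 1) + vy**2 / (n_y - 1))
    return t, df


def welch_t_test(x, y, comparison: str = "") -> TestResult:
    """Two-tailed unequal-variance t-test (Welch-Satterthwaite df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    t, df = welch_t_statistic(
        x.mean(), x.var(ddof=1), x.size, y.mean(), y.var(ddof=1), y.size
    )
    if not np.isfinite(t):  # identical constant samples: t = 0/0
        t, df = 0.0, float(x.size + y.size - 2)
    p = 2.0 * sps.t.sf(abs(float(t)), float(df))
    return TestResult(
        statistic=float(t),
        df=float(df),
        p_value=min(1.0, float(p)),
        test_name="welch_t",
        comparison=comparison,
    )


# ---------------------------------------------------------------------------
# One-way ANOVA + Newman-Keuls
# ---------------------------------------------------------------------------


@dataclass
class PairwiseDecision:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    significant: bool
    procedure: str


@dataclass
class AnovaPosthocResult:
    omnibus: TestResult | list[TestResult]
    pairwise: list[PairwiseDecision]


def _one_way_f(groups: list[np.ndarray]) -> tuple[float, float, float, int, int]:
    """F statistic, p, pooled MSE and dfs for a one-way layout."""
    k = len(groups)
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    n = int(ns.sum())
    grand = float(np.concatenate(groups).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = k - 1, n - k
    mse = ss_within / df_w
    if mse == 0.0:
        f = 0.0 if ss_between == 0.0 else math.inf
    else:
        f = (ss_between / df_b) / mse
    p = float(sps.f.sf(f, df_b, df_w)) if math.isfinite(f) else 0.0
    return f, p, mse, df_b, df_w


def one_way_anova_nk(
    groups: dict[str, "np.ndarray | list[float]"],
    alpha: float = ALPHA,
    posthoc: str = "newman-keuls",
) -> AnovaPosthocResult:
    """One-way ANOVA with a stepwise Newman-Keuls (or Tukey HSD) post-hoc.

    Newman-Keuls: group means are ordered; a stretch of r means is tested
    against the studentized range at (r, df_error), working from the widest
    stretch inward; every pair inside a non-significant stretch is declared
    non-significant without testing.  Note the procedure does not control the
    family-wise error rate under partial nulls (known liberal behavior);
    ``posthoc='tukey'`` gives the conservative single-ladder alternative.
    """
    if posthoc not in ("newman-keuls", "tukey"):
        raise ValueError("posthoc must be 'newman-keuls' or 'tukey'")
    names = list(groups)
    arrays = [np.asarray(groups[g], float) for g in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    f, p, mse, df_b, df_w = _one_way_f(arrays)
    omnibus = TestResult(f, (float(df_b), float(df_w)), p, "one_way_anova", "omnibus")

    k = len(arrays)
    order = np.argsort([a.mean() for a in arrays])
    sorted_names = [names[i] for i in order]
    sorted_arr = [arrays[i] for i in order]

    decided: dict[frozenset, PairwiseDecision] = {}

    def q_test(i: int, j: int) -> tuple[float, float]:
        span = (j - i + 1) if posthoc == "newman-keuls" else k
        gi, gj = sorted_arr[i], sorted_arr[j]
        se = math.sqrt(mse / 2.0 * (1.0 / gi.size + 1.0 / gj.size))
        q = abs(gj.mean() - gi.mean()) / se if se > 0 else 0.0
        pq = float(sps.studentized_range.sf(q, span, df_w)) if se > 0 else 1.0
        return q, pq

    def mark(i: int, j: int, sig: bool, q: float, pq: float, tested: bool) -> None:
        key = frozenset((i, j))
        if key in decided:
            return
        decided[key] = PairwiseDecision(
            sorted_names[i],
            sorted_names[j],
            q if tested else math.nan,
            pq if tested else math.nan,
            sig,
            posthoc,
        )

    def descend(i: int, j: int) -> None:
        if j <= i:
            return
        key = frozenset((i, j))
        if key in decided:
            return
        q, pq = q_test(i, j)
        if pq < alpha:
            mark(i, j, True, q, pq, True)
            descend(i, j - 1)
            descend(i + 1, j)
        else:
            # whole stretch homogeneous: every inner pair non-significant
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    qa, pa = (q, pq) if (a, b) == (i, j) else (math.nan, math.nan)
                    mark(a, b, False, qa, pa, (a, b) == (i, j))

    if posthoc == "tukey":
        for i in range(k):
            for j in range(i + 1, k):
                q, pq = q_test(i, j)
                mark(i, j, pq < alpha, q, pq, True)
    else:
        descend(0, k - 1)

    pairwise = sorted(decided.values(), key=lambda d: (d.group_a, d.group_b))
    return AnovaPosthocResult(omnibus=omnibus, pairwise=pairwise)


# ---------------------------------------------------------------------------
# Two-way ANOVA + Dunnett / Sidak post-hocs
# ---------------------------------------------------------------------------


def sidak_adjust(p: float, k: int) -> float:
    """Sidak family adjustment of one p-value over k comparisons."""
    if not (0.0 <= p <= 1.0) or k < 1:
        raise ValueError("need p in [0,1] and k >= 1")
    return float(1.0 - (1.0 - p) ** k)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def two_way_anova_posthoc(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    posthoc: str | None = None,
    control_level: str | None = None,
    alpha: float = ALPHA,
) -> AnovaPosthocResult:
    """Two-way ANOVA (type-II SS) with optional Dunnett or Sidak post-hoc.

    Post-hocs compare the levels of ``factor_a`` separately at each level of
    ``factor_b``: Dunnett compares every level against ``control_level``
    (many-to-one); Sidak runs all pairwise Welch tests and adjusts each
    p-value for the total number of comparisons in the family.

    Missing cells are rejected, not imputed.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[value, factor_a, factor_b]].rename(
        columns={value: "y", factor_a: "fa", factor_b: "fb"}
    )
    counts = df.groupby(["fa", "fb"], observed=True).size()
    levels_a = sorted(df["fa"].unique())
    levels_b = sorted(df["fb"].unique())
    if len(counts) != len(levels_a) * len(levels_b):
        missing = {
            (a, b)
            for a in levels_a
            for b in levels_b
            if (a, b) not in counts.index
        }
        raise ValueError(f"missing cells: {sorted(missing)}")

    if float(np.var(df["y"].to_numpy())) == 0.0:
        # degenerate: identical values everywhere -> no effects by definition
        dfr = float(len(df) - len(levels_a) * len(levels_b))
        omnibus = [
            TestResult(0.0, (1.0, dfr), 1.0, "two_way_anova", label)
            for label in (factor_a, factor_b, f"{factor_a}:{factor_b}")
        ]
        return AnovaPosthocResult(omnibus=omnibus, pairwise=[])

    model = smf.ols("y ~ C(fa) * C(fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    labels = {"C(fa)": factor_a, "C(fb)": factor_b, "C(fa):C(fb)": f"{factor_a}:{factor_b}"}
    omnibus = [
        TestResult(
            statistic=float(table.loc[key, "F"]),
            df=(float(table.loc[key, "df"]), float(table.loc["Residual", "df"])),
            p_value=float(table.loc[key, "PR(>F)"]),
            test_name="two_way_anova",
            comparison=label,
        )
        for key, label in labels.items()
    ]

    pairwise: list[PairwiseDecision] = []
    if posthoc is not None:
        if posthoc not in ("dunnett", "sidak"):
            raise ValueError("posthoc must be 'dunnett' or 'sidak'")
        if posthoc == "dunnett":
            if control_level is None or control_level not in levels_a:
                raise ValueError("Dunnett requires a control_level present in factor_a")
            for b in levels_b:
                sub = df[df["fb"] == b]
                others = [a for a in levels_a if a != control_level]
                samples = [sub.loc[sub["fa"] == a, "y"].to_numpy() for a in others]
                control = sub.loc[sub["fa"] == control_level, "y"].to_numpy()
                res = sps.dunnett(*samples, control=control, rng=0)
                for a, stat, p in zip(others, res.statistic, res.pvalue):
                    pairwise.append(
                        PairwiseDecision(
                            f"{a}@{b}",
                            f"{control_level}@{b}",
                            float(stat),
                            float(p),
                            bool(p < alpha),
                            "dunnett",
                        )
                    )
        else:  # sidak
            fams = [
                (a1, a2, b)
                for b in levels_b
                for i, a1 in enumerate(levels_a)
                for a2 in levels_a[i + 1 :]
            ]
            k = len(fams)
            for a1, a2, b in fams:
                sub = df[df["fb"] == b]
                res = welch_t_test(
                    sub.loc[sub["fa"] == a1, "y"], sub.loc[sub["fa"] == a2, "y"]
                )
                p_adj = sidak_adjust(res.p_value, k)
                pairwise.append(
                    PairwiseDecision(
                        f"{a1}@{b}", f"{a2}@{b}", res.statistic, p_adj, p_adj < alpha, "sidak"
                    )
                )

    return AnovaPosthocResult(omnibus=omnibus, pairwise=pairwise)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------


def pearson_r(x, y, comparison: str = "") -> TestResult:
    """Product-moment correlation with a two-tailed p via the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need paired samples of size >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in one of the variables")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(r, float(df), min(1.0, p), "pearson_r", comparison)
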