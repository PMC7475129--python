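"""Group-comparison harness for 2x2 (exposure x diet) study designs.

Metric tables (physiology, SCFAs, neurochemistry, cytokines) are analysed
with a gated decision tree: every group is screened with Shapiro-Wilk
(normality) and the groups jointly with Levene (variance homogeneity);
when both gates pass, a two-way ANOVA with Fisher's-LSD-style unadjusted
pairwise t-tests is used, otherwise Kruskal-Wallis with pairwise
Mann-Whitney U tests.  The four planned pairwise comparisons are judged
against a Bonferroni-adjusted alpha of family_alpha / 4 (0.05/4 = 0.0125).
Outliers are reported via 1.5 x IQR flags but never removed automatically.

Also houses the Benjamini-Hochberg step-up adjustment and a flat
all-against-all Spearman correlation screen (a non-hierarchical analogue
of HAllA-style association testing) thresholded at q < 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_COMPARISONS",
    "PathDecision",
    "TestReport",
    "choose_path",
    "run_group_analysis",
    "bh_adjust",
    "correlation_screen",
]

#: The four planned pairwise comparisons of a Sham/CIH x VEH/PREB design.
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("Sham+VEH", "CIH+VEH"),
    ("CIH+VEH", "CIH+PREB"),
    ("Sham+PREB", "CIH+PREB"),
    ("Sham+VEH", "Sham+PREB"),
)


@dataclass(frozen=True)
class PathDecision:
    path: str  # "parametric" | "nonparametric"
    shapiro_p: dict[str, float]
    levene_p: float
    degenerate: bool = False  # a zero-variance group forced the rank path


@dataclass(frozen=True)
class TestReport:
    metric: str
    path: str
    gates: PathDecision
    omnibus: dict[str, float]  # parametric: p_diet/p_exposure/p_interaction; else p_kruskal
    pairwise_p: dict[tuple[str, str], float]
    adjusted_alpha: float
    significant: dict[tuple[str, str], bool]
    outlier_flags: dict[str, list[int]]


def choose_path(groups: dict[str, np.ndarray], gate_alpha: float = 0.05) -> PathDecision:
    """Parametric iff every group passes Shapiro-Wilk and Levene passes.

    A group with zero variance makes the normality gate undefined; the
    decision falls to the nonparametric path with ``degenerate=True``.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, x in arrays.items():
        if x.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 values")
    shapiro_p: dict[str, float] = {}
    degenerate = False
    for name, x in arrays.items():
        if np.ptp(x) == 0:
            shapiro_p[name] = math.nan
            degenerate = True
        else:
            shapiro_p[name] = float(sps.shapiro(x).pvalue)
    if degenerate:
        return PathDecision("nonparametric", shapiro_p, math.nan, degenerate=True)
    levene_p = float(sps.levene(*arrays.values()).pvalue)
    parametric = all(p >= gate_alpha for p in shapiro_p.values()) and levene_p >= gate_alpha
    return PathDecision("parametric" if parametric else "nonparametric", shapiro_p, levene_p)


def _outlier_flags(groups: dict[str, np.ndarray]) -> dict[str, list[int]]:
    out = {}
    for name, x in groups.items():
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        out[name] = [int(i) for i in np.nonzero((x < lo) | (x > hi))[0]]
    return out


def run_group_analysis(
    table: pd.DataFrame,
    value_col: str = "value",
    metric: str = "",
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS,
    family_alpha: float = 0.05,
    require_omnibus: bool = False,
    gate_alpha: float = 0.05,
) -> TestReport:
    """Analyse one metric of a complete 2x2 design.

    ``table`` needs columns ``factor_exposure`` (Sham|CIH), ``factor_diet``
    (VEH|PREB) and ``value_col``.  The gate decision picks two-way ANOVA +
    pairwise t-tests or Kruskal-Wallis + Mann-Whitney U; the four planned
    comparisons are evaluated at ``family_alpha / len(comparisons)``.  With
    ``require_omnibus=True`` pairwise tests are only flagged significant
    when the omnibus test reaches ``family_alpha`` (LSD-style protection).
    """
    df = table.copy()
    df["group"] = df["factor_exposure"].astype(str) + "+" + df["factor_diet"].astype(str)
    needed = {g for pair in comparisons for g in pair}
    missing = needed - set(df["group"].unique())
    if missing:
        raise ValueError(f"missing design cells: {sorted(missing)}")
    groups = {g: df.loc[df["group"] == g, value_col].to_numpy(dtype=float) for g in sorted(needed)}
    gates = choose_path(groups, gate_alpha=gate_alpha)

    omnibus: dict[str, float] = {}
    pairwise_p: dict[tuple[str, str], float] = {}
    if gates.path == "parametric":
        model = ols(f"{value_col} ~ C(factor_diet) * C(factor_exposure)", data=df).fit()
        tab = anova_lm(model, typ=2)
        omnibus = {
            "p_diet": float(tab.loc["C(factor_diet)", "PR(>F)"]),
            "p_exposure": float(tab.loc["C(factor_exposure)", "PR(>F)"]),
            "p_interaction": float(tab.loc["C(factor_diet):C(factor_exposure)", "PR(>F)"]),
        }
        omnibus_sig = min(omnibus.values()) < family_alpha
        for a, b in comparisons:
            pairwise_p[(a, b)] = float(sps.ttest_ind(groups[a], groups[b]).pvalue)
    else:
        omnibus = {"p_kruskal": float(sps.kruskal(*groups.values()).pvalue)}
        omnibus_sig = omnibus["p_kruskal"] < family_alpha
        for a, b in comparisons:
            pairwise_p[(a, b)] = float(
                sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
            )

    adjusted_alpha = family_alpha / len(comparisons)
    significant = {
        pair: (p < adjusted_alpha) and (omnibus_sig or not require_omnibus)
        for pair, p in pairwise_p.items()
    }
    return TestReport(
        metric=metric,
        path=gates.path,
        gates=gates,
        omnibus=omnibus,
        pairwise_p=pairwise_p,
        adjusted_alpha=adjusted_alpha,
        significant=significant,
        outlier_flags=_outlier_flags(groups),
    )


def bh_adjust(p_values: np.ndarray, q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: monotone q-values and the rejection set."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def correlation_screen(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    q: float = 0.10,
    method: str = "spearman",
) -> pd.DataFrame:
    """Flat all-against-all Spearman screen with BH FDR across all pairs.

    ``features`` and ``targets`` are sample-indexed DataFrames (e.g. CLR
    values transposed, and per-subject physiology).  Constant vectors yield
    a skipped pair (``skipped=True``, no p).  The screen is deliberately
    non-hierarchical; output metadata records this.
    """
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    common = features.index.intersection(targets.index)
    if len(common) < 5:
        raise ValueError("need at least 5 paired observations")
    F, T = features.loc[common], targets.loc[common]
    rows = []
    for fcol in F.columns:
        x = F[fcol].to_numpy(dtype=float)
        for tcol in T.columns:
            y = T[tcol].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append(
                    {"feature": fcol, "target": tcol, "rho": math.nan, "p": math.nan, "skipped": True}
                )
                continue
            rho, p = sps.spearmanr(x, y)
            rows.append({"feature": fcol, "target": tcol, "rho": float(rho), "p": float(p), "skipped": False})
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    qvals = np.full(len(out), math.nan)
    reject = np.zeros(len(out), dtype=bool)
    if tested.any():
        qv, rj = bh_adjust(out.loc[tested, "p"].to_numpy(), q=q)
        qvals[tested.to_numpy()] = qv
        reject[tested.to_numpy()] = rj
    out["q"] = qvals
    out["significant"] = reject
    out.attrs["method"] = "flat all-against-all spearman (non-hierarchical)"
    out.attrs["n_observations"] = int(len(common))
    return out
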