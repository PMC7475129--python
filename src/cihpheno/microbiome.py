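"""Compositional summary statistics for taxon and KO count tables.

Shotgun-metagenomic count tables are compositions: only relative
information is meaningful, so analyses run in centred-log-ratio (CLR)
space.  The module provides prevalence/abundance filtering, the CLR
transform (with an additive pseudocount for zeros), alpha diversity
(Chao1, Shannon, Gini-Simpson), PCA on CLR values (Aitchison geometry),
pairwise PERMANOVA on Aitchison distances, a CLR-space two-group
differential-abundance test with Benjamini-Hochberg FDR control, and
aggregation of KEGG orthologues (KOs) into functional modules (gut-brain /
gut-metabolic modules) by the median-of-steps rule.

The differential-abundance test is a single test on the CLR values per
feature (normality-gated Welch t vs Mann-Whitney U), not a Monte-Carlo
average over Dirichlet instances; its FDR behaviour is verified by
simulation in the test suite.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_adjust

__all__ = [
    "CountTable",
    "ModuleDefinition",
    "filter_features",
    "clr_transform",
    "alpha_diversity",
    "pca_clr",
    "permanova",
    "differential_abundance",
    "aggregate_modules",
]

_KO_RE = re.compile(r"^K\d{5}$")


@dataclass
class CountTable:
    """Feature x sample table of non-negative integer counts with group labels."""

    counts: pd.DataFrame  # features x samples
    groups: pd.Series | None = None  # indexed by sample id

    def __post_init__(self) -> None:
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if c.index.duplicated().any() or c.columns.duplicated().any():
            raise ValueError("feature and sample IDs must be unique")
        totals = c.sum(axis=0)
        if (totals <= 0).any():
            empty = list(totals.index[totals <= 0])
            raise ValueError(f"samples with zero total counts: {empty}")
        if self.groups is not None:
            self.groups = self.groups.reindex(c.columns)
            if self.groups.isna().any():
                raise ValueError("every sample needs a group label")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class ModuleDefinition:
    """A functional module: ordered steps, each a set of alternative KO IDs."""

    module_id: str
    name: str
    steps: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"module {self.module_id} has no steps")
        for step in self.steps:
            for ko in step:
                if not _KO_RE.match(ko):
                    raise ValueError(f"module {self.module_id}: invalid KO id {ko!r}")


def filter_features(
    table: CountTable,
    prevalence: float = 0.05,
    da_abundance: float = 0.005,
) -> tuple[CountTable, pd.Series]:
    """Prevalence filter plus differential-abundance eligibility mask.

    Features present (count > 0) in ``prevalence`` (5%) or fewer of the
    samples are removed.  Among the retained features, those whose relative
    abundance (against the whole-sample total) reaches ``da_abundance``
    (0.5%) in at least one sample are marked eligible for differential
    testing.
    """
    c = table.counts
    prev = (c > 0).mean(axis=1)
    keep = prev > prevalence
    if not keep.any():
        raise ValueError("prevalence filter removed every feature")
    kept = c.loc[keep]
    rel = kept.div(c.sum(axis=0), axis=1)
    da_eligible = (rel >= da_abundance).any(axis=1)
    da_eligible.name = "da_eligible"
    return CountTable(kept, table.groups), da_eligible


def clr_transform(table: CountTable | pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centred log-ratio transform, one composition per sample (column).

    clr_i = ln(x_i) - mean_j ln(x_j) with x = counts + pseudocount.  Each
    sample's CLR values sum to zero, and the transform is invariant to
    per-sample scaling of the composition.
    """
    c = table.counts if isinstance(table, CountTable) else table
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logx = np.log(c.to_numpy(dtype=float) + pseudocount)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=c.index, columns=c.columns)


def _chao1(counts: np.ndarray) -> float:
    pos = counts[counts > 0]
    s_obs = pos.size
    f1 = int(np.sum(pos == 1))
    f2 = int(np.sum(pos == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample Chao1 (bias-corrected), Shannon (nats) and Gini-Simpson.

    Runs on the raw, unfiltered counts — rare features carry the richness
    signal.  Shannon = -sum p ln p over non-zero proportions; Simpson is
    reported as 1 - sum p^2 (the Gini-Simpson probability of interspecific
    encounter); Chao1 = S_obs + f1(f1-1)/(2(f2+1)).
    """
    rows = []
    for sample in table.counts.columns:
        counts = table.counts[sample].to_numpy(dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"sample {sample} is empty")
        p = counts[counts > 0] / total
        rows.append(
            {
                "sample": sample,
                "chao1": _chao1(counts),
                "shannon": float(-np.sum(p * np.log(p))),
                "simpson": float(1.0 - np.sum(p**2)),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def pca_clr(clr: pd.DataFrame, n_components: int = 2):
    """PCA of CLR values in Aitchison geometry.

    Samples (columns of ``clr``) are the observations.  Returns
    ``(scores, loadings, explained_variance_ratio)`` where scores has one
    row per sample and columns PC1..PCk.
    """
    X = clr.to_numpy(dtype=float).T  # samples x features
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for PCA")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if rank < 2:
        raise ValueError("CLR matrix has rank < 2; PCA plane undefined")
    k = min(n_components, rank)
    cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=clr.columns, columns=cols)
    loadings = pd.DataFrame(Vt[:k].T, index=clr.index, columns=cols)
    evr = (s**2 / np.sum(s**2))[:k]
    return scores, loadings, evr


def _pseudo_f_terms(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    """PERMANOVA pseudo-F from a squared-distance matrix and label vector."""
    n = len(labels)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in uniq:
        idx = np.nonzero(labels == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    g = len(uniq)
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def _permanova_single(
    d2: np.ndarray,
    labels: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    method: str,
) -> tuple[float, float, int]:
    uniq = np.unique(labels)
    f_obs = _pseudo_f_terms(d2, labels, uniq)
    n = len(labels)
    n_distinct = math.factorial(n)  # upper bound; exact mode enumerates these
    if method == "exact" or (method == "auto" and n_distinct <= 5040):
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            f_p = _pseudo_f_terms(d2, labels[list(perm)], uniq)
            count += f_p >= f_obs - 1e-12
            total += 1
        p = count / total
        return f_obs, p, total
    hits = 0
    for _ in range(n_perm):
        f_p = _pseudo_f_terms(d2, rng.permutation(labels), uniq)
        hits += f_p >= f_obs - 1e-12
    p = (1 + hits) / (1 + n_perm)
    return f_obs, p, n_perm


def permanova(
    clr: pd.DataFrame,
    labels: pd.Series,
    n_perm: int = 1000,
    pairwise: bool = True,
    seed: int | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """PERMANOVA on Aitchison (Euclidean-in-CLR) distances.

    pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)) from the pairwise
    squared Euclidean distances between CLR sample vectors.  The Monte
    Carlo p-value includes the observed statistic, p = (1 + b)/(1 + n_perm),
    so it is strictly positive and exact under exchangeability.  For small
    problems (``method='auto'``) the permutation distribution is enumerated
    exhaustively.  Groups with fewer than 3 samples are skipped with a
    warning.  With ``pairwise=True`` every group pair is tested.
    """
    labels = labels.reindex(clr.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    rng = np.random.default_rng(seed)
    X = clr.to_numpy(dtype=float).T
    lab = labels.to_numpy()
    counts = pd.Series(lab).value_counts()
    small = [g for g, c in counts.items() if c < 3]
    if small:
        warnings.warn(f"groups with < 3 samples skipped: {small}", stacklevel=2)
    good = [g for g in counts.index if g not in small]
    if len(good) < 2:
        raise ValueError("need at least two groups with >= 3 samples")

    comparisons = (
        list(itertools.combinations(sorted(map(str, good)), 2)) if pairwise else [tuple(sorted(map(str, good)))]
    )
    rows = []
    for comp in comparisons:
        m = np.isin(lab, comp)
        Xs, ls = X[m], lab[m]
        diff = Xs[:, None, :] - Xs[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        f_obs, p, used = _permanova_single(d2, ls, n_perm, rng, method)
        rows.append(
            {
                "comparison": " vs ".join(comp),
                "n": int(m.sum()),
                "pseudo_F": f_obs,
                "p": p,
                "n_permutations": used,
            }
        )
    return pd.DataFrame(rows)


def differential_abundance(
    clr: pd.DataFrame,
    labels: pd.Series,
    da_mask: pd.Series | None = None,
    fdr: float = 0.10,
    gate_alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential abundance in CLR space with BH FDR control.

    Per eligible feature, a Shapiro-Wilk gate on each group selects a Welch
    t-test (both groups plausibly normal) or a Mann-Whitney U test; BH
    step-up at ``fdr`` controls the false discovery rate across features.
    Effect size is the difference of group medians divided by the pooled
    median absolute deviation.
    """
    labels = labels.reindex(clr.columns)
    uniq = sorted(pd.unique(labels.dropna()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    g1 = clr.loc[:, (labels == uniq[0]).to_numpy()]
    g2 = clr.loc[:, (labels == uniq[1]).to_numpy()]
    if g1.shape[1] < 3 or g2.shape[1] < 3:
        raise ValueError("each group needs at least 3 samples")
    features = clr.index if da_mask is None else clr.index[da_mask.reindex(clr.index).fillna(False)]
    if len(features) == 0:
        return pd.DataFrame(
            columns=["feature", "mean_1", "mean_2", "path", "stat", "p", "q", "effect", "reject"]
        ).set_index("feature")

    rows = []
    for f in features:
        x, y = g1.loc[f].to_numpy(), g2.loc[f].to_numpy()
        normal = (
            np.ptp(x) > 0
            and np.ptp(y) > 0
            and stats.shapiro(x).pvalue >= gate_alpha
            and stats.shapiro(y).pvalue >= gate_alpha
        )
        if normal:
            res = stats.ttest_ind(x, y, equal_var=False)
            path = "welch_t"
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            path = "mann_whitney"
        med_diff = float(np.median(x) - np.median(y))
        pooled = np.concatenate([x - np.median(x), y - np.median(y)])
        mad = float(np.median(np.abs(pooled)))
        rows.append(
            {
                "feature": f,
                "mean_1": float(x.mean()),
                "mean_2": float(y.mean()),
                "path": path,
                "stat": float(res.statistic),
                "p": float(res.pvalue),
                "effect": med_diff / mad if mad > 0 else math.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    qvals, reject = bh_adjust(out["p"].to_numpy(), q=fdr)
    out["q"] = qvals
    out["reject"] = reject
    return out


def aggregate_modules(
    ko_table: CountTable | pd.DataFrame,
    definitions: list[ModuleDefinition],
    coverage_min: float = 0.66,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate KO abundances into module abundance and coverage.

    Per module and sample: each step's abundance is the sum of its
    alternative KOs; coverage is the fraction of steps with non-zero
    abundance; module abundance is the median over all step abundances when
    coverage >= ``coverage_min``, otherwise 0.  Modules whose KOs are all
    absent from the table score (0, 0) without error.
    """
    c = ko_table.counts if isinstance(ko_table, CountTable) else ko_table
    abund = pd.DataFrame(0.0, index=[d.module_id for d in definitions], columns=c.columns)
    cover = abund.copy()
    for d in definitions:
        step_sums = np.zeros((len(d.steps), c.shape[1]))
        for i, step in enumerate(d.steps):
            present = [ko for ko in step if ko in c.index]
            if present:
                step_sums[i] = c.loc[present].sum(axis=0).to_numpy()
        cov = (step_sums > 0).mean(axis=0)
        med = np.median(step_sums, axis=0)
        abund.loc[d.module_id] = np.where(cov >= coverage_min, med, 0.0)
        cover.loc[d.module_id] = cov
    return abund, cover
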