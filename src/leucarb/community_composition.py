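"""ASV-table workflows: rarefaction, diversity, composition, group tests.

Count tables (samples x amplicon sequence variants) are rarefied to a
common read depth, summarised by Shannon diversity and the bias-corrected
Chao1 richness estimator, and aggregated into named phylotypes (rare ASVs
pooled at phylum level into "Others").  Group structure across depth layers
is tested with ANOSIM on Bray-Curtis dissimilarities and decomposed with
SIMPER.  For compositional analysis, count zeros are replaced by the
Bayesian-multiplicative method before a centered log-ratio (CLR)
transform, and per-phylotype CLR abundances (averaged within depth layers)
are regressed on eCFs with linear-vs-quadratic AIC selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, f as f_dist

from .php_depth_models import fit_polynomial_models

__all__ = [
    "ASVTable",
    "DiversityMetrics",
    "rarefy",
    "remove_singletons",
    "diversity",
    "aggregate_phylotypes",
    "bray_curtis",
    "anosim",
    "simper",
    "zero_replace",
    "clr",
    "zero_replace_clr",
    "fit_clr_vs_cf",
    "CLRvsCFFit",
]


@dataclass
class ASVTable:
    """Sample x ASV count matrix with taxonomy and sample metadata.

    ``counts``: DataFrame, rows = samples, columns = ASV ids, non-negative
    integers.  ``taxonomy``: Series mapping ASV id -> taxon label (phylum
    or phylotype name).  ``metadata``: DataFrame indexed by sample with at
    least ``depth_m`` and ``station`` columns (optional).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    metadata: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integers")
        missing = set(self.counts.columns) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"taxonomy missing for ASVs: {sorted(missing)[:5]}")

    @property
    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class DiversityMetrics:
    shannon_h: float  # nats
    chao1: float
    observed_asvs: int

    def __post_init__(self) -> None:
        if self.shannon_h < 0:
            raise ValueError("shannon_h must be non-negative")
        if self.chao1 < self.observed_asvs - 1e-9:
            raise ValueError("chao1 cannot fall below observed richness")


def remove_singletons(table: ASVTable) -> ASVTable:
    """Drop ASVs whose total count across the table is exactly one
    (likely PCR/sequencing errors); applied before rarefaction."""
    keep = table.counts.sum(axis=0) > 1
    counts = table.counts.loc[:, keep]
    return ASVTable(counts, table.taxonomy.loc[counts.columns], table.metadata)


def rarefy(table: ASVTable, depth: int, seed: int = 0) -> ASVTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Multivariate-hypergeometric draw per sample, deterministic under
    ``seed``.  A sample with fewer reads than ``depth`` is rejected by name.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, row in table.counts.iterrows():
        total = int(row.sum())
        if total < depth:
            raise ValueError(
                f"sample {sample!r} has {total} reads, below rarefaction depth {depth}"
            )
        if total == depth:
            rows.append(row.to_numpy(dtype=np.int64))
        else:
            rows.append(
                rng.multivariate_hypergeometric(row.to_numpy(dtype=np.int64), depth)
            )
    counts = pd.DataFrame(rows, index=table.counts.index, columns=table.counts.columns)
    return ASVTable(counts, table.taxonomy, table.metadata)


def diversity(sample_counts) -> DiversityMetrics:
    """Shannon H' (natural log) and bias-corrected Chao1 for one sample.

    Chao1 = S_obs + F1(F1-1) / (2(F2+1)) with F1 singleton and F2 doubleton
    counts; this form stays finite when no doubletons occur and reduces to
    S_obs when F1 = 0.
    """
    x = np.asarray(sample_counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("sample has no positive counts")
    p = x / x.sum()
    shannon = float(-(p * np.log(p)).sum())
    shannon = max(shannon, 0.0)  # guard tiny negative round-off
    s_obs = int(x.size)
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return DiversityMetrics(shannon_h=shannon, chao1=chao1, observed_asvs=s_obs)


def aggregate_phylotypes(table: ASVTable, threshold: float = 0.01) -> pd.DataFrame:
    """Pool rare ASVs into "Others"; keep abundant ASVs as named phylotypes.

    ASVs with overall relative abundance >= ``threshold`` keep their own
    column (named by ASV id).  The rest are first summed at phylum level
    (taxonomy label); phylum groups still below the threshold are pooled
    into a single "Others" column.  Column sums are conserved.
    """
    total = table.counts.to_numpy().sum()
    if total == 0:
        raise ValueError("empty count table")
    rel = table.counts.sum(axis=0) / total
    abundant = rel[rel >= threshold].index
    out = table.counts[abundant].copy()

    rare = [c for c in table.counts.columns if c not in set(abundant)]
    if rare:
        by_phylum = table.counts[rare].T.groupby(table.taxonomy.loc[rare]).sum().T
        phylum_rel = by_phylum.sum(axis=0) / total
        named = phylum_rel[phylum_rel >= threshold].index
        for ph in named:
            out[str(ph)] = by_phylum[ph]
        leftover = [c for c in by_phylum.columns if c not in set(named)]
        if leftover:
            out["Others"] = by_phylum[leftover].sum(axis=1)
    return out


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity matrix (values in [0, 1])."""
    d = squareform(pdist(counts.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=counts.index, columns=counts.index)


@dataclass(frozen=True)
class ANOSIMResult:
    r: float
    p_value: float
    n_permutations: int


def _anosim_r(dist: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dist[iu])
    within = labels[iu[0]] == labels[iu[1]]
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    m = n * (n - 1) / 2
    return float((r_b - r_w) / (m / 2.0))


def anosim(
    dist: pd.DataFrame,
    grouping: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
) -> ANOSIMResult:
    """Analysis of similarities on a precomputed dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 distance pairs; the p-value is the proportion of label
    permutations (plus the observed one) with R at least as large.
    Every group needs >= 2 samples.
    """
    labels = np.asarray(grouping)
    d = dist.to_numpy(dtype=float)
    if len(labels) != d.shape[0]:
        raise ValueError("grouping length must match the distance matrix")
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        small = values[counts.argmin()]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    r_obs = _anosim_r(d, labels)
    rng = np.random.default_rng(seed)
    hits = 1  # observed permutation counts itself
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(d, perm) >= r_obs - 1e-12:
            hits += 1
    return ANOSIMResult(r=r_obs, p_value=hits / (n_permutations + 1),
                        n_permutations=n_permutations)


def simper(counts: pd.DataFrame, grouping: Sequence) -> Dict[tuple, pd.DataFrame]:
    """SIMPER decomposition of between-group Bray-Curtis dissimilarity.

    For each pair of groups, the contribution of taxon i to the
    dissimilarity of samples j, k is |x_ij - x_ik| / sum_i(x_ij + x_ik);
    contributions are averaged over all between-group sample pairs.
    Returns, per group pair, a DataFrame with mean contribution and percent
    of the average dissimilarity, sorted descending.
    """
    labels = np.asarray(grouping)
    x = counts.to_numpy(dtype=float)
    groups = np.unique(labels)
    out: Dict[tuple, pd.DataFrame] = {}
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            idx_a = np.flatnonzero(labels == groups[gi])
            idx_b = np.flatnonzero(labels == groups[gj])
            contribs = []
            for a in idx_a:
                for b in idx_b:
                    denom = (x[a] + x[b]).sum()
                    contribs.append(np.abs(x[a] - x[b]) / denom)
            mean_contrib = np.mean(contribs, axis=0)
            total = mean_contrib.sum()  # == average Bray-Curtis dissimilarity
            df = pd.DataFrame(
                {
                    "mean_contribution": mean_contrib,
                    "percent": 100.0 * mean_contrib / total if total > 0 else 0.0,
                },
                index=counts.columns,
            ).sort_values("mean_contribution", ascending=False)
            out[(groups[gi], groups[gj])] = df
    return out


def zero_replace(counts: pd.DataFrame, prior_strength: float = 1.0) -> pd.DataFrame:
    """Bayesian-multiplicative replacement of count zeros.

    Per sample with total n and D parts, a uniform Dirichlet prior of total
    mass ``prior_strength`` (s) gives each zero part its posterior expected
    proportion s/(D(n+s)); non-zero parts are scaled multiplicatively so
    the composition still sums to one.  Returns proportions (rows sum to
    1); rankings among non-zero parts are preserved.
    """
    x = counts.to_numpy(dtype=float)
    if (x.sum(axis=1) <= 0).any():
        bad = counts.index[x.sum(axis=1) <= 0][0]
        raise ValueError(f"sample {bad!r} has no positive counts")
    d = x.shape[1]
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        n = x[i].sum()
        zero = x[i] == 0
        repl = prior_strength / (d * (n + prior_strength))
        out[i, zero] = repl
        out[i, ~zero] = (x[i, ~zero] / n) * (1.0 - repl * zero.sum())
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def clr(proportions: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform: ln(x_i / geometric mean of the row).
    Requires strictly positive entries; rows of the result sum to zero."""
    x = proportions.to_numpy(dtype=float)
    if (x <= 0).any():
        raise ValueError("CLR requires strictly positive entries; replace zeros first")
    logx = np.log(x)
    return pd.DataFrame(
        logx - logx.mean(axis=1, keepdims=True),
        index=proportions.index,
        columns=proportions.columns,
    )


def zero_replace_clr(table: ASVTable, prior_strength: float = 1.0) -> pd.DataFrame:
    """Zero replacement followed by CLR, on the table's counts."""
    return clr(zero_replace(table.counts, prior_strength))


@dataclass(frozen=True)
class CLRvsCFFit:
    phylotype: str
    model: str  # selected: 'linear' | 'quadratic'
    coefficients: tuple
    r2: float
    aic: float
    p_value: float
    linear_aic: float
    quadratic_aic: float


def _model_p(r2: float, n: int, n_pred: int) -> float:
    if r2 >= 1.0:
        return 0.0
    df2 = n - n_pred - 1
    if df2 <= 0:
        return float("nan")
    f_stat = (r2 / n_pred) / ((1 - r2) / df2)
    return float(f_dist.sf(f_stat, n_pred, df2))


def fit_clr_vs_cf(clr_values, ecfs, phylotype: str = "") -> CLRvsCFFit:
    """Linear vs quadratic OLS of layer-averaged CLR abundance on eCF.

    Model selection by the lower AIC (same convention as the depth models);
    reports R^2 and the overall F-test p-value of the selected model.
    Needs >= 4 paired points.
    """
    y = np.asarray(clr_values, dtype=float)
    x = np.asarray(ecfs, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need at least 4 paired (eCF, CLR) points")
    linear, quadratic, selected = fit_polynomial_models(x, y)
    n_pred = 2 if selected.model == "quadratic" else 1
    return CLRvsCFFit(
        phylotype=phylotype,
        model=selected.model,
        coefficients=selected.coefficients,
        r2=selected.r2,
        aic=selected.aic,
        p_value=_model_p(selected.r2, len(x), n_pred),
        linear_aic=linear.aic,
        quadratic_aic=quadratic.aic,
    )
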