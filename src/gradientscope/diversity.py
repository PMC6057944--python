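"""Alpha and beta diversity with the group tests used along the gradient.

Alpha metrics (observed richness, Chao1, Shannon, Simpson) follow QIIME 1
conventions: Shannon in bits (log base 2), classic Chao1 with automatic
bias correction when no doubletons exist.  Beta diversity covers
Bray-Curtis and weighted/unweighted UniFrac, ordinated by classical PCoA
and tested by permutation PERMANOVA (Adonis).  scikit-bio provides the
metric kernels; this module fixes conventions, validates inputs and adapts
the pipeline's domain types.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps
import skbio
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1 as _chao1
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import OrdinationResults, pcoa as _skbio_pcoa

from .core_data import FeatureTable, Phylogeny, SampleMetadata

__all__ = [
    "ALPHA_METRICS",
    "alpha",
    "alpha_frame",
    "AlphaGroupTests",
    "alpha_group_tests",
    "bray_curtis",
    "unifrac",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "significance_stars",
]

ALPHA_METRICS = ("observed", "chao1", "shannon", "simpson")


def _alpha_one(counts: np.ndarray, metric: str) -> float:
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("empty sample (no positive counts)")
    if metric == "observed":
        return float(counts.size)
    if metric == "chao1":
        # classic form S + F1^2/(2 F2); bias-corrected automatically when F2=0
        return float(_chao1(counts.astype(int), bias_corrected=False))
    p = counts / counts.sum()
    if metric == "shannon":
        return float(-(p * np.log2(p)).sum())
    if metric == "simpson":
        return float(1.0 - (p**2).sum())
    raise ValueError(f"unknown alpha metric {metric!r}; choose from {ALPHA_METRICS}")


def alpha(table: FeatureTable, metric: str) -> pd.Series:
    """Per-sample alpha diversity for one metric."""
    return pd.Series(
        {s: _alpha_one(table.data[s].to_numpy(), metric) for s in table.sample_ids},
        name=metric,
    )


def alpha_frame(table: FeatureTable, metrics=ALPHA_METRICS) -> pd.DataFrame:
    """Samples x metrics frame of alpha diversity values."""
    return pd.DataFrame({m: alpha(table, m) for m in metrics})


def significance_stars(p: float) -> str:
    """Figure-convention star bins: *** <0.001, ** <0.01, * <0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class AlphaGroupTests:
    """Omnibus one-way ANOVA plus all pairwise Welch t-tests."""

    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group1, group2, t, df, p, stars
    excluded_groups: list[str]


def alpha_group_tests(values: pd.Series, metadata: SampleMetadata) -> AlphaGroupTests:
    """Test alpha-diversity variation across lifestyles.

    One-way ANOVA over all groups with >= 2 samples; Welch's t-test (unequal
    variances, Welch-Satterthwaite df) for every pair of such groups.
    Groups with a single sample are excluded with a note.
    """
    lifestyles = metadata.lifestyle().loc[values.index]
    groups = {g: values[lifestyles == g].to_numpy() for g in lifestyles.unique()}
    usable = {g: v for g, v in groups.items() if v.size >= 2}
    excluded = sorted(set(groups) - set(usable))
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 samples")
    arrays = list(usable.values())
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = sps.f_oneway(*arrays)
    rows = []
    for g1, g2 in combinations(usable, 2):
        res = sps.ttest_ind(usable[g1], usable[g2], equal_var=False)
        rows.append((g1, g2, float(res.statistic), float(res.df),
                     float(res.pvalue), significance_stars(res.pvalue)))
    pairwise = pd.DataFrame(
        rows, columns=["group1", "group2", "t", "df", "p", "stars"]
    )
    return AlphaGroupTests(float(f_stat), float(p_val), pairwise, excluded)


def bray_curtis(table: FeatureTable) -> skbio.DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) between samples."""
    mat = table.data.to_numpy(dtype=float).T  # samples x features
    if (mat.sum(axis=1) == 0).any():
        raise ValueError("Bray-Curtis undefined for all-zero samples")
    dm = squareform(pdist(mat, metric="braycurtis"))
    return skbio.DistanceMatrix(dm, ids=table.sample_ids)


def unifrac(
    table: FeatureTable,
    tree: Phylogeny,
    weighted: bool = False,
    normalized: bool = False,
) -> skbio.DistanceMatrix:
    """UniFrac distances between samples on a rooted tree.

    Unweighted: fraction of branch length leading only to leaves present in
    exactly one of the two samples.  Weighted: branch lengths weighted by
    the difference in descending relative abundance, optionally normalised
    to [0, 1].
    """
    missing = sorted(set(table.feature_ids) - set(tree.leaf_names))
    if missing:
        raise ValueError(f"features missing from tree: {missing[:5]}")
    counts = table.data.to_numpy().T  # samples x features
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": normalized} if weighted else {}
    return beta_diversity(
        metric,
        counts,
        ids=table.sample_ids,
        taxa=table.feature_ids,
        tree=tree.tree,
        validate=True,
        **kwargs,
    )


def pcoa(dm: skbio.DistanceMatrix, n_axes: int | None = None) -> OrdinationResults:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centres -1/2 J D^2 J and eigendecomposes; coordinates are
    eigenvectors scaled by sqrt(eigenvalue).  Negative eigenvalues are
    reported in the eigen spectrum but excluded from coordinates (no
    Cailliez/Lingoes correction).
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    if n_axes is not None:
        n_pos = int((res.eigvals > 1e-12).sum())
        n_axes = min(n_axes, n_pos)
        res.samples = res.samples.iloc[:, :n_axes]
    return res


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


def permanova(
    dm: skbio.DistanceMatrix,
    metadata: SampleMetadata,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutation multivariate ANOVA (Adonis) of lifestyle on a distance
    matrix.

    Anderson's pseudo-F from among/within sums of squared distances;
    p = (1 + #{permuted F >= observed F}) / (1 + n_perm) with seeded label
    permutations.
    """
    grouping = metadata.lifestyle().loc[list(dm.ids)]
    sizes = grouping.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups of size 1 are not testable: {small}")
    if len(sizes) < 2:
        raise ValueError("need at least two groups")
    if np.all(dm.data == 0):
        # no structure at all: every grouping explains it equally well
        return PermanovaResult(0.0, 1.0, n_perm, len(dm.ids), len(sizes))
    res = _skbio_permanova(
        dm, grouping.to_numpy(), permutations=n_perm, seed=int(seed)
    )
    return PermanovaResult(
        pseudo_f=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        n_permutations=n_perm,
        n_samples=len(dm.ids),
        n_groups=len(sizes),
    )


def kruskal_wallis(values, grouping) -> tuple[float, float, bool]:
    """Kruskal-Wallis H (tie-corrected) with chi-square p, df = groups - 1.

    Returns ``(H, p, all_tied)``; when every observation is identical the
    statistic is undefined and ``(0.0, 1.0, True)`` is returned.
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    samples = [values[grouping == g] for g in pd.unique(grouping)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(values) == 0:
        return 0.0, 1.0, True
    h, p = sps.kruskal(*samples)
    return float(h), float(p), False


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution by enumeration when both samples have <= 10
    observations and no ties straddle the groups; otherwise the normal
    approximation with midrank tie correction and continuity correction.
    Returns ``(W, p)`` where W is the rank-sum statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if mode == "auto":
        mode = "exact" if (x.size <= 10 and y.size <= 10 and not has_ties) else "approx"
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=(method == "asymptotic"))
    w = float(res.statistic + x.size * (x.size + 1) / 2)  # U -> rank sum
    return w, float(res.pvalue)
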