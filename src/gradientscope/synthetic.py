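"""Synthetic cohort generator for the lifestyle-gradient analysis.

Emulates the statistical structure the downstream methods assume: four
ordered populations (captive < semi-captive < semi-wild < wild) with
replicated sampling of individuals, an unidentifiable-individual pool in the
wild group, a subset of taxa whose log-abundance responds linearly to the
latent gradient, phylum labels enabling Firmicutes:Bacteroidetes analysis,
lognormal sequencing-depth variation, Dirichlet-multinomial count noise, and
a chloroplast (plant) component whose share of reads rises with wildness.

Model, for sample *i* of individual *j* at lifestyle level ``s`` in 1..4::

    log-weight of bacterial feature k:  w_k = alpha_k + beta_k * s + u_j
    u_j ~ Normal(0, individual_sd^2),  alpha_k ~ Normal(0, baseline_sd^2)

The default individual effect u_j is a sample-wide scalar (an individual's
overall microbial load / recovery efficiency): it cancels in the softmax,
so under the default model replicate samples satisfy the independence
assumptions of the downstream tests.  Setting
``individual_effect_mode="per_feature"`` draws u_jk once per (individual,
feature) instead, giving replicates of an individual correlated
compositional deviations — the pseudoreplication scenario the
replicate-collapse validation pass exists for.

Bacterial composition is the softmax of the weights, rescaled so chloroplast
features jointly occupy ``chloroplast_fraction_by_level[s]`` of the sample.
Counts are Dirichlet-multinomial with concentration ``p / theta`` (theta=0
degenerates to a pure multinomial) at a lognormal depth.

Gradient features are baseline-centred at the gradient midpoint
(``alpha_k -= beta_k * 2.5``), so a wildness-responsive taxon is rare in
captives and vice versa — the pattern reported for wild-vs-captive primate
guts.  Positive-slope features are labelled Firmicutes and negative-slope
features Bacteroidetes so that the planted gradient propagates to the F:B
ratio with the field's expected direction (higher in the wild).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_data import (
    LIFESTYLES,
    LIFESTYLE_LEVEL,
    UNKNOWN_INDIVIDUAL,
    FeatureTable,
    Phylogeny,
    SampleMetadata,
    TaxonomyMap,
)
import skbio

__all__ = [
    "CohortConfig",
    "CohortGroundTruth",
    "reference_structure",
    "directional_preset",
    "generate_cohort",
    "generate_tree",
    "slope_for_latent_rho",
]

#: Midpoint of the 1..4 lifestyle coding; gradient features are centred here.
_GRADIENT_MIDPOINT = 2.5


def reference_structure() -> dict:
    """Sampling skeleton of the red-shanked douc study that motivates the
    defaults: 111 faecal samples over four populations with unequal
    replication and a pool of unidentifiable wild individuals.

    Returns a dict ``{lifestyle: [(individual_id, n_replicates), ...]}`` plus
    an ``unknown_pool`` entry (wild samples not attributable to a unique
    animal).  Captive: 12 samples / 2 individuals; semi-captive: 15 / 7;
    semi-wild: 18 / 18; wild: 66 samples of which 26 come from 8 identified
    individuals and 40 from the unknown pool.
    """
    return {
        "captive": [("C1", 6), ("C2", 6)],
        "semi-captive": [("SC1", 3)] + [(f"SC{i}", 2) for i in range(2, 8)],
        "semi-wild": [(f"SW{i}", 1) for i in range(1, 19)],
        "wild": [("W1", 4), ("W2", 4)] + [(f"W{i}", 3) for i in range(3, 9)],
        "unknown_pool": 40,
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design the analysis was built around; see
    docs/methods.md for the reasoning behind each value.
    """

    n_features: int = 100
    n_gradient_features: int = 10
    #: Per-unit-lifestyle slope on the log-abundance scale.  ``None`` derives
    #: the slope giving a latent correlation of ``target_rho`` under the
    #: other parameters (see :func:`slope_for_latent_rho`).
    slope_magnitude: float | None = None
    target_rho: float = 0.8
    #: Fraction of gradient features with positive slope (wild-enriched).
    gradient_positive_fraction: float = 0.5
    #: Lifestyle level at which a planted feature's abundance equals the
    #: typical feature's.  At the default midpoint (2.5) planted features
    #: swing symmetrically around typical abundance; towards 4.5 a
    #: wild-enriched feature stays rare everywhere and vanishes in captives
    #: (the "crashes in captivity" regime).  Mirrored for negative slopes.
    gradient_center: float = _GRADIENT_MIDPOINT
    baseline_sd: float = 1.0
    individual_sd: float = 0.3
    #: "scalar": one composition-neutral effect per individual (default);
    #: "per_feature": correlated compositional deviations shared by an
    #: individual's replicates (pseudoreplication scenario).
    individual_effect_mode: str = "scalar"
    #: Dirichlet-multinomial overdispersion; concentration = p / theta.
    #: theta = 0 means pure multinomial sampling.
    overdispersion: float = 0.0
    depth_log_mean: float = math.log(20_000)
    depth_log_sd: float = 0.25
    #: ``{lifestyle: [(individual_id, n_replicates), ...], "unknown_pool": n}``
    group_structure: dict = field(default_factory=reference_structure)
    n_chloroplast_features: int = 5
    chloroplast_fraction_by_level: tuple = (0.001, 0.005, 0.05, 0.10)
    #: Proportions of non-gradient bacterial features per phylum.
    phylum_assignment: dict = field(
        default_factory=lambda: {"Firmicutes": 0.55, "Bacteroidetes": 0.15, "other": 0.30}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gradient_features > self.n_features:
            raise ValueError("n_gradient_features exceeds n_features")
        if min(self.baseline_sd, self.individual_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if any(not (0 <= f < 1) for f in self.chloroplast_fraction_by_level):
            raise ValueError("chloroplast fractions must lie in [0, 1)")
        if len(self.chloroplast_fraction_by_level) != 4:
            raise ValueError("chloroplast_fraction_by_level needs one value per level")
        if sum(self.phylum_assignment.values()) > 1 + 1e-9:
            raise ValueError("phylum_assignment proportions must sum to <= 1")
        for lifestyle in LIFESTYLES:
            groups = self.group_structure.get(lifestyle, [])
            if not groups and not (
                lifestyle == "wild" and self.group_structure.get("unknown_pool", 0)
            ):
                raise ValueError(f"empty group: {lifestyle}")


@dataclass
class CohortGroundTruth:
    """What the generator planted, for recovery testing.

    ``slopes`` has one entry per feature (0 for null features); ``phylum``
    and ``is_chloroplast`` label every feature; ``individual_effects`` maps
    each true individual (including hidden members of the unknown wild pool)
    to its per-feature random-effect vector; ``true_individual`` gives the
    latent individual behind every sample, resolving the UNKNOWN sentinel.
    """

    slopes: pd.Series
    phylum: pd.Series
    is_chloroplast: pd.Series
    individual_effects: dict[str, np.ndarray]
    true_individual: pd.Series
    depths: pd.Series

    @property
    def gradient_features(self) -> list[str]:
        return list(self.slopes.index[self.slopes != 0])


def slope_for_latent_rho(
    rho: float,
    config: "CohortConfig",
) -> float:
    """Slope magnitude giving approximately latent correlation ``rho``
    between a planted feature's log relative abundance and the 1..4 level.

    Uses the variance decomposition of the generative model: signal variance
    ``beta^2 Var(s)`` against individual-effect variance plus multinomial /
    Dirichlet-multinomial counting noise on the log scale for a feature of
    typical abundance.  Approximate by design — recovery only needs the
    realised correlation to land near the target.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    levels = _sample_levels(config.group_structure)
    var_s = float(np.var(levels))
    mean_depth = math.exp(config.depth_log_mean + config.depth_log_sd**2 / 2)
    p_typ = 1.0 / config.n_features
    var_count = (1 - p_typ) / (p_typ * mean_depth)
    if config.overdispersion > 0:
        c = 1.0 / config.overdispersion
        var_count *= (mean_depth + c) / (1 + c)
    # a scalar individual effect cancels in the softmax and adds no noise
    ind_var = (
        config.individual_sd**2
        if config.individual_effect_mode == "per_feature"
        else 0.0
    )
    noise_var = ind_var + var_count
    return rho / math.sqrt(1 - rho**2) * math.sqrt(noise_var / var_s)


def directional_preset(seed: int = 0) -> CohortConfig:
    """Cohort encoding the qualitative direction of a captivity study.

    A large block of wild-enriched taxa (and a smaller captive-enriched
    block) centred near their enriched gradient end, so each taxon crashes
    below detection at the opposing end: alpha diversity and the log F:B
    ratio then fall from wild to captive, and the chloroplast share rises
    with wildness.  Depth is moderate so presence/absence actually varies.
    """
    return CohortConfig(
        n_gradient_features=30,
        gradient_positive_fraction=0.8,
        slope_magnitude=2.0,
        gradient_center=4.5,
        depth_log_mean=math.log(3_000),
        seed=seed,
    )


def _sample_levels(group_structure: dict) -> np.ndarray:
    levels = []
    for lifestyle in LIFESTYLES:
        n = sum(reps for _, reps in group_structure.get(lifestyle, []))
        if lifestyle == "wild":
            n += group_structure.get("unknown_pool", 0)
        levels.extend([LIFESTYLE_LEVEL[lifestyle]] * n)
    return np.asarray(levels)


def _build_metadata(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for lifestyle in LIFESTYLES:
        for ind, reps in config.group_structure.get(lifestyle, []):
            for r in range(1, reps + 1):
                rows.append((f"{ind}.r{r}", ind, lifestyle))
        if lifestyle == "wild":
            for r in range(1, config.group_structure.get("unknown_pool", 0) + 1):
                rows.append((f"WU.r{r}", UNKNOWN_INDIVIDUAL, lifestyle))
    df = pd.DataFrame(rows, columns=["sample_id", "individual_id", "lifestyle"])
    return df.set_index("sample_id")


_PLANT_ORDERS = ("Fabales", "Rosales", "Malpighiales", "Sapindales", "Poales",
                 "Lamiales", "Gentianales", "Myrtales")
_OTHER_PHYLA = ("Proteobacteria", "Verrucomicrobia", "Spirochaetes",
                "Actinobacteria", "Tenericutes", "Euryarchaeota")


def _build_taxonomy(
    feature_ids: list[str],
    chloro_ids: list[str],
    phyla: pd.Series,
) -> TaxonomyMap:
    lineages: dict[str, str] = {}
    for i, fid in enumerate(feature_ids):
        if fid in chloro_ids:
            order = _PLANT_ORDERS[i % len(_PLANT_ORDERS)]
            lineages[fid] = (
                "k__Viridiplantae; p__Streptophyta; c__Magnoliopsida; "
                f"o__{order}; f__; g__Plant{i}; s__"
            )
        else:
            phylum = phyla[fid]
            lineages[fid] = (
                f"k__Bacteria; p__{phylum}; c__; o__; f__; g__Genus{i}; s__"
            )
    return TaxonomyMap.from_lineages(lineages)


def generate_cohort(
    config: CohortConfig,
) -> tuple[FeatureTable, SampleMetadata, TaxonomyMap, CohortGroundTruth]:
    """Draw one cohort; all randomness flows from ``config.seed``.

    Returns the count table, sample metadata, a taxonomy covering every
    feature (bacterial phyla plus Streptophyta lineages for chloroplast
    features), and the planted ground truth.
    """
    rng = np.random.default_rng(config.seed)
    meta_df = _build_metadata(config)
    n_samples = len(meta_df)
    n_bact = config.n_features
    n_chloro = config.n_chloroplast_features

    bact_ids = [f"OTU{i:04d}" for i in range(1, n_bact + 1)]
    chloro_ids = [f"CHLORO{i:02d}" for i in range(1, n_chloro + 1)]
    feature_ids = bact_ids + chloro_ids

    # planted slopes
    slope = (
        config.slope_magnitude
        if config.slope_magnitude is not None
        else slope_for_latent_rho(config.target_rho, config)
    )
    slopes = pd.Series(0.0, index=feature_ids)
    gradient_ids = list(
        rng.choice(bact_ids, size=config.n_gradient_features, replace=False)
    )
    n_pos = int(round(config.gradient_positive_fraction * len(gradient_ids)))
    for k, fid in enumerate(gradient_ids):
        slopes[fid] = slope if k < n_pos else -slope

    # phylum labels: positive-slope -> Firmicutes, negative -> Bacteroidetes,
    # nulls drawn from phylum_assignment
    names = list(config.phylum_assignment)
    probs = np.asarray(list(config.phylum_assignment.values()), dtype=float)
    probs = probs / probs.sum()
    phyla = pd.Series(
        [n if n != "other" else _OTHER_PHYLA[i % len(_OTHER_PHYLA)]
         for i, n in enumerate(rng.choice(names, size=n_bact, p=probs))],
        index=bact_ids,
    )
    for fid in gradient_ids:
        phyla[fid] = "Firmicutes" if slopes[fid] > 0 else "Bacteroidetes"
    phyla = pd.concat([phyla, pd.Series("Streptophyta", index=chloro_ids)])

    # baselines; gradient features get a deterministic baseline centred at
    # the gradient midpoint so the planted effect size is controlled (their
    # abundance passes through the typical feature's at mid-gradient)
    alpha = pd.Series(rng.normal(0.0, config.baseline_sd, n_bact + n_chloro),
                      index=feature_ids)
    # positive-slope features are centred at gradient_center, negative-slope
    # ones at its mirror image, so both signs behave symmetrically
    for fid in gradient_ids:
        center = (
            config.gradient_center if slopes[fid] > 0 else 5.0 - config.gradient_center
        )
        alpha[fid] = -slopes[fid] * center

    # individual random effects, with hidden individuals behind the unknown pool
    identified = sorted(set(meta_df["individual_id"]) - {UNKNOWN_INDIVIDUAL})
    wild_identified = [i for i in identified
                       if (meta_df["individual_id"] == i).any()
                       and meta_df.loc[meta_df["individual_id"] == i, "lifestyle"].iloc[0] == "wild"]
    hidden = [f"WH{i}" for i in range(1, 5)]  # never-identified wild animals
    all_inds = identified + hidden
    if config.individual_effect_mode == "per_feature":
        effects = {
            ind: rng.normal(0.0, config.individual_sd, n_bact) for ind in all_inds
        }
    elif config.individual_effect_mode == "scalar":
        effects = {
            ind: np.full(n_bact, rng.normal(0.0, config.individual_sd))
            for ind in all_inds
        }
    else:
        raise ValueError(
            f"unknown individual_effect_mode {config.individual_effect_mode!r}"
        )

    true_ind = meta_df["individual_id"].copy()
    unknown_mask = true_ind == UNKNOWN_INDIVIDUAL
    pool = wild_identified + hidden
    true_ind[unknown_mask] = rng.choice(pool, size=int(unknown_mask.sum()))

    depths = rng.lognormal(config.depth_log_mean, config.depth_log_sd, n_samples)
    depths = np.maximum(depths.round().astype(np.int64), 1)

    chloro_frac = dict(zip(LIFESTYLES, config.chloroplast_fraction_by_level))
    counts = np.zeros((n_bact + n_chloro, n_samples), dtype=np.int64)
    alpha_b = alpha[bact_ids].to_numpy()
    beta_b = slopes[bact_ids].to_numpy()
    alpha_c = alpha[chloro_ids].to_numpy()
    for j, (sid, row) in enumerate(meta_df.iterrows()):
        s = LIFESTYLE_LEVEL[row["lifestyle"]]
        w = alpha_b + beta_b * s + effects[true_ind[sid]]
        p_bact = np.exp(w - w.max())
        p_bact /= p_bact.sum()
        f = chloro_frac[row["lifestyle"]]
        if n_chloro:
            p_chl = np.exp(alpha_c - alpha_c.max())
            p_chl /= p_chl.sum()
            p = np.concatenate([p_bact * (1 - f), p_chl * f])
        else:
            p = p_bact
        if config.overdispersion > 0:
            conc = p / config.overdispersion
            p = rng.dirichlet(np.maximum(conc, 1e-12))
        counts[:, j] = rng.multinomial(depths[j], p)

    table_df = pd.DataFrame(counts, index=feature_ids, columns=meta_df.index)
    # a sample drawn entirely empty would be degenerate; force one read in
    # the most abundant feature (practically unreachable at realistic depth)
    zero_cols = table_df.sum(axis=0) == 0
    if zero_cols.any():  # pragma: no cover
        table_df.loc[table_df.index[0], zero_cols] = 1

    truth = CohortGroundTruth(
        slopes=slopes,
        phylum=phyla,
        is_chloroplast=pd.Series(
            [fid in chloro_ids for fid in feature_ids], index=feature_ids
        ),
        individual_effects=effects,
        true_individual=true_ind,
        depths=pd.Series(depths, index=meta_df.index),
    )
    tax = _build_taxonomy(feature_ids, chloro_ids, phyla)
    return FeatureTable(table_df), SampleMetadata(meta_df), tax, truth


def _random_newick(ids: list[str], rng: np.random.Generator) -> str:
    """Random bifurcating topology by recursive splitting, Exp(1) lengths."""
    if len(ids) == 1:
        return f"{ids[0]}:{rng.exponential():.6f}"
    ids = list(ids)
    rng.shuffle(ids)
    k = int(rng.integers(1, len(ids)))
    left = _random_newick(sorted(ids[:k]), rng)
    right = _random_newick(sorted(ids[k:]), rng)
    return f"({left},{right}):{rng.exponential():.6f}"


def generate_tree(
    feature_ids,
    seed: int,
    chloroplast_ids=(),
) -> Phylogeny:
    """Random rooted bifurcating tree over ``feature_ids``.

    Branch lengths are Exp(1) draws.  If ``chloroplast_ids`` is non-empty,
    those leaves are constrained to a single clade (plants are monophyletic
    relative to bacteria).
    """
    feature_ids = list(feature_ids)
    if len(feature_ids) < 2:
        raise ValueError("need at least 2 features to build a tree")
    rng = np.random.default_rng(seed)
    chloro = [f for f in feature_ids if f in set(chloroplast_ids)]
    bact = [f for f in feature_ids if f not in set(chloroplast_ids)]
    if chloro and bact:
        if len(chloro) == 1:
            left = f"{chloro[0]}:{rng.exponential():.6f}"
        else:
            left = _random_newick(chloro, rng)
        if len(bact) == 1:
            right = f"{bact[0]}:{rng.exponential():.6f}"
        else:
            right = _random_newick(bact, rng)
        newick = f"({left},{right}):0.0;"
    else:
        body = _random_newick(feature_ids, rng)
        newick = f"{body.rsplit(':', 1)[0]}:0.0;"
    import io

    tree = skbio.TreeNode.read(io.StringIO(newick))
    return Phylogeny(tree)
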