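"""Derived lifestyle markers and the end-to-end pipeline driver.

Two coarse community markers accompany the per-feature gradient scan: the
log Firmicutes:Bacteroidetes ratio (an energy-harvest proxy expected to be
highest in wild animals) and the chloroplast dietary proxy (plant-derived
chloroplast 16S reads in faeces as a quantitative signal of plant
consumption, expected to rise with wildness).  ``run_pipeline`` strings the
whole analysis together over a simulated or loaded cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from . import __version__
from .compositional import (
    CLRMatrix,
    clr_from_fractions,
    clr_transform,
    collapse_replicates,
    filter_features,
    bin_at_genus,
    rarefy,
)
from .core_data import (
    LIFESTYLES,
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    write_feature_table,
    write_metadata,
)
from .diversity import (
    alpha_frame,
    alpha_group_tests,
    bray_curtis,
    kruskal_wallis,
    pcoa,
    permanova,
    unifrac,
    wilcoxon_rank_sum,
)
from .gradient import (
    SelectionThresholds,
    apply_selection,
    extrema_grouping,
    gradient_scan,
    holm_adjust,
    polyserial,
)

__all__ = [
    "FBRatioResult",
    "fb_ratio",
    "DietProxyResult",
    "diet_proxy",
    "make_heatmap_matrix",
    "run_pipeline",
]

#: Coding string attached to every reported rho: lifestyle enters the
#: polyserial fit as captive=1 .. wild=4.
GRADIENT_CODING = "wildness-ascending (captive=1 < semi-captive=2 < semi-wild=3 < wild=4)"


# ---------------------------------------------------------------------------
# Firmicutes : Bacteroidetes ratio
# ---------------------------------------------------------------------------


@dataclass
class FBRatioResult:
    """Per-sample log F:B ratio with omnibus and pairwise group tests."""

    per_sample: pd.DataFrame  # columns: lifestyle, f_sum, b_sum, log_fb, pseudocount
    group_summary: pd.DataFrame  # per lifestyle: n, mean, sd
    kruskal_h: float
    kruskal_p: float
    pairwise: pd.DataFrame  # group1, group2, W, p
    log_base: str = "natural"


def fb_ratio(
    table: FeatureTable,
    tax: TaxonomyMap,
    metadata: SampleMetadata,
    pseudocount_policy: str = "when_zero",
) -> FBRatioResult:
    """Natural log of summed Firmicutes over summed Bacteroidetes counts.

    When either phylum sum is zero in a sample, one count is added to both
    sums (``when_zero`` policy, flagged per sample) so the log stays finite;
    ``always`` applies the pseudocount everywhere, ``never`` raises on zeros.
    Group differences are tested by Kruskal-Wallis across the four
    lifestyles and by all pairwise Wilcoxon rank-sum tests.
    """
    metadata = metadata.align_to(table)
    tax.covers(table.feature_ids)
    phyla = pd.Series(
        {fid: tax.phylum(fid) for fid in table.feature_ids}, name="phylum"
    )
    f_ids = phyla.index[phyla == "Firmicutes"]
    b_ids = phyla.index[phyla == "Bacteroidetes"]
    if len(f_ids) == 0 or len(b_ids) == 0:
        raise ValueError("need at least one Firmicutes and one Bacteroidetes feature")
    f_sum = table.data.loc[f_ids].sum(axis=0).astype(float)
    b_sum = table.data.loc[b_ids].sum(axis=0).astype(float)

    zero = (f_sum == 0) | (b_sum == 0)
    if pseudocount_policy == "never":
        if zero.any():
            raise ValueError("zero phylum sum encountered with pseudocount disabled")
        pseudo = pd.Series(False, index=f_sum.index)
    elif pseudocount_policy == "always":
        f_sum, b_sum = f_sum + 1, b_sum + 1
        pseudo = pd.Series(True, index=f_sum.index)
    elif pseudocount_policy == "when_zero":
        f_sum[zero] += 1
        b_sum[zero] += 1
        pseudo = zero
    else:
        raise ValueError(f"unknown pseudocount policy {pseudocount_policy!r}")

    log_fb = np.log(f_sum / b_sum)
    per_sample = pd.DataFrame(
        {
            "lifestyle": metadata.lifestyle(),
            "f_sum": f_sum,
            "b_sum": b_sum,
            "log_fb": log_fb,
            "pseudocount": pseudo,
        }
    )
    groups = {
        g: per_sample.loc[per_sample["lifestyle"] == g, "log_fb"].to_numpy()
        for g in LIFESTYLES
        if (per_sample["lifestyle"] == g).any()
    }
    summary = pd.DataFrame(
        {
            "n": {g: v.size for g, v in groups.items()},
            "mean": {g: v.mean() for g, v in groups.items()},
            "sd": {g: v.std(ddof=1) if v.size > 1 else np.nan for g, v in groups.items()},
        }
    )
    h, p, _ = kruskal_wallis(
        per_sample["log_fb"].to_numpy(), per_sample["lifestyle"].to_numpy()
    )
    rows = []
    for g1, g2 in combinations(groups, 2):
        w, pw = wilcoxon_rank_sum(groups[g1], groups[g2])
        rows.append((g1, g2, w, pw))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "W", "p"])
    return FBRatioResult(per_sample, summary, h, p, pairwise)


# ---------------------------------------------------------------------------
# Chloroplast dietary proxy
# ---------------------------------------------------------------------------


@dataclass
class DietProxyResult:
    """Chloroplast (plant) read content per sample as a diet signal."""

    per_sample: pd.DataFrame  # lifestyle, chloro_total, bacterial_total, fraction, clr
    class_order_table: pd.DataFrame  # plant class/order counts x samples
    rho: float
    rho_captive_ascending: float
    rho_p: float
    rho_confidence_p: float
    wilcoxon_extrema_p: float
    selected: bool
    coding: str = GRADIENT_CODING
    note: str = ""


def diet_proxy(
    bacterial_table: FeatureTable,
    chloroplast_table: "FeatureTable | pd.DataFrame",
    plant_tax: TaxonomyMap,
    metadata: SampleMetadata,
) -> DietProxyResult:
    """Quantify plant material in faeces from chloroplast reads.

    The chloroplast fraction is chloroplast reads over (chloroplast +
    bacterial) reads per sample.  For gradient testing a two-part
    composition (chloroplast, non-chloroplast) is CLR-transformed — the CLR
    value is 0.5*ln(f/(1-f)) — and fed through the polyserial fit plus the
    extrema Wilcoxon test.  ``rho`` uses the wildness-ascending coding;
    ``rho_captive_ascending`` is its negation, the sign convention under
    which increasing plant matter with wildness appears as a negative
    correlation.  Chloroplast features are also aggregated by plant class
    (or order where the class is uncharacterised) for heatmap display.
    """
    chloro_df = (
        chloroplast_table.data
        if isinstance(chloroplast_table, FeatureTable)
        else chloroplast_table
    )
    missing = set(chloro_df.columns) - set(metadata.sample_ids)
    if missing:
        raise ValueError(f"chloroplast samples missing from metadata: {sorted(missing)[:5]}")
    extra = set(chloro_df.columns) - set(bacterial_table.sample_ids)
    if extra:
        raise ValueError(
            f"chloroplast samples absent from bacterial table: {sorted(extra)[:5]}"
        )
    samples = bacterial_table.sample_ids
    bact_total = bacterial_table.sample_sums().astype(float)
    chloro = chloro_df.reindex(columns=samples, fill_value=0)
    chloro_total = chloro.sum(axis=0).astype(float)
    fraction = chloro_total / (chloro_total + bact_total)

    # class/order aggregation of the plant features
    plant_tax.covers(list(chloro.index))
    labels = []
    for fid in chloro.index:
        lin = plant_tax.lineage(fid)
        cls, order = lin[2], lin[3]
        labels.append(cls if cls else (order if order else "unclassified plant"))
    class_order = chloro.groupby(labels, sort=False).sum()

    meta = metadata.align_to(bacterial_table)
    levels = meta.levels().to_numpy()
    note = ""
    if (fraction == 0).all():
        clr_val = pd.Series(0.0, index=samples)
        rho = rho_p = rho_conf = wx_p = np.nan
        selected = False
        note = "no chloroplast reads observed; gradient test skipped"
    else:
        f = fraction.copy()
        if (f == 0).any():
            delta = 0.65 * f[f > 0].min()
            f = f.mask(f == 0, delta)
            note = "zero chloroplast fractions replaced at detection limit"
        clr_val = 0.5 * np.log(f / (1 - f))
        fit = polyserial(clr_val.to_numpy(), levels)
        rho, rho_p, rho_conf = fit.rho, fit.p_chi2, fit.p_wald
        extrema = extrema_grouping(meta)
        x = clr_val[extrema == "(Semi-)captive"].to_numpy()
        y = clr_val[extrema == "wild"].to_numpy()
        _, wx_p = wilcoxon_rank_sum(x, y)
        thr = SelectionThresholds()
        selected = bool(
            abs(rho) >= thr.min_abs_rho
            and rho_p <= thr.max_adj_p
            and rho_conf <= thr.max_confidence_p
            and wx_p <= thr.max_extrema_p
        )

    per_sample = pd.DataFrame(
        {
            "lifestyle": meta.lifestyle(),
            "chloro_total": chloro_total,
            "bacterial_total": bact_total,
            "fraction": fraction,
            "clr": clr_val,
        }
    )
    return DietProxyResult(
        per_sample=per_sample,
        class_order_table=class_order,
        rho=float(rho) if rho == rho else np.nan,
        rho_captive_ascending=float(-rho) if rho == rho else np.nan,
        rho_p=rho_p,
        rho_confidence_p=rho_conf,
        wilcoxon_extrema_p=wx_p,
        selected=selected,
        note=note,
    )


# ---------------------------------------------------------------------------
# Heatmap matrix
# ---------------------------------------------------------------------------


def make_heatmap_matrix(
    results: pd.DataFrame,
    clr: CLRMatrix,
    mode: str = "taxa",
    cluster_columns: bool = False,
) -> pd.DataFrame | None:
    """Display matrix of the top gradient features.

    Rows are the features passing the display tier (|rho| > 0.6 for taxa,
    > 0.75 for pathways, among selected features), ordered by rho
    (descending); values are CLR abundances, min-max unit-normalised per row
    in pathway mode.  With ``cluster_columns`` samples are ordered by
    average-linkage hierarchical clustering on Euclidean distance over the
    displayed rows.  Returns ``None`` (with no file written by callers) when
    nothing passes the tier.
    """
    shown = results.loc[results["display_tier"].fillna(False)]
    if shown.empty:
        return None
    order = shown["rho"].sort_values(ascending=False).index
    mat = clr.data.loc[order].copy()
    if mode == "pathway":
        lo = mat.min(axis=1)
        span = (mat.max(axis=1) - lo).replace(0, 1.0)
        mat = mat.sub(lo, axis=0).div(span, axis=0)
    if cluster_columns and mat.shape[1] > 2:
        link = linkage(mat.to_numpy().T, method="average", metric="euclidean")
        mat = mat.iloc[:, leaves_list(link)]
    return mat


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Everything one full analysis run produced."""

    table: FeatureTable
    metadata: SampleMetadata
    alpha: pd.DataFrame
    alpha_tests: dict
    beta: dict
    permanova: dict
    clr: CLRMatrix
    gradient: pd.DataFrame
    fb: FBRatioResult
    diet: DietProxyResult | None
    collapsed_gradient: pd.DataFrame
    collapsed_metadata: SampleMetadata
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    config: dict,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis in the canonical order.

    ``config`` either names input files (keys ``table``, ``taxonomy``,
    ``metadata``, optional ``tree``, ``chloroplast_table``) or contains a
    ``simulate`` block of :class:`~gradientscope.synthetic.CohortConfig`
    fields.  Order: bin -> filter -> (rarefy) -> diversity suite -> CLR ->
    gradient scan -> F:B -> diet proxy -> replicate-collapse validation pass
    (Benjamini-Hochberg adjusted).  When ``out_dir`` is given, TSV outputs
    and a JSON manifest are written there.
    """
    from . import core_data as cd
    from . import synthetic

    stage = "input"
    try:
        tree = None
        chloro_table = None
        if "simulate" in config:
            sim_cfg = synthetic.CohortConfig(**config["simulate"])
            table, metadata, tax, truth = synthetic.generate_cohort(sim_cfg)
            chloro_ids = list(truth.is_chloroplast.index[truth.is_chloroplast])
            if chloro_ids:
                chloro_table = table.data.loc[chloro_ids]  # plain frame: zero columns allowed
                table = FeatureTable(table.data.drop(index=chloro_ids))
            if config.get("tree", True):
                tree = synthetic.generate_tree(table.feature_ids, seed=sim_cfg.seed + 1)
        else:
            table = cd.read_feature_table(config["table"])
            tax = cd.read_taxonomy(config["taxonomy"])
            metadata = cd.read_metadata(config["metadata"])
            if config.get("tree"):
                tree = cd.read_newick(config["tree"])
            if config.get("chloroplast_table"):
                chloro_table = cd.read_feature_table(config["chloroplast_table"])
        metadata = metadata.align_to(table)
        n_input_samples = len(table.sample_ids)

        stage = "bin"
        binned = bin_at_genus(table, tax)
        # carry a representative lineage for each bin (phylum lookup for F:B)
        label_to_lineage = {}
        for fid in table.feature_ids:
            from .compositional import binning_label

            lab = binning_label(tax.lineage(fid))
            label_to_lineage.setdefault(lab, tax.lineage(fid))
        binned_tax = TaxonomyMap(
            pd.DataFrame.from_dict(
                {k: list(v) for k, v in label_to_lineage.items()},
                orient="index",
                columns=list(cd.RANKS),
            )
        )

        stage = "filter"
        filtered = filter_features(
            binned,
            min_samples=config.get("min_samples", 3),
            min_mean_rel_abund=config.get("min_mean_rel_abund", 1e-4),
        )

        stage = "rarefy"
        seed = int(config.get("seed", 0))
        rarefied = filtered
        dropped: list[str] = []
        depth = config.get("rarefaction_depth")
        if depth:
            rarefied, dropped = rarefy(filtered, int(depth), seed=seed)
            metadata_r = SampleMetadata(metadata.data.loc[rarefied.sample_ids])
        else:
            metadata_r = metadata

        stage = "alpha"
        alpha_df = alpha_frame(rarefied)
        alpha_tests = {
            m: alpha_group_tests(alpha_df[m], metadata_r) for m in alpha_df.columns
        }

        stage = "beta"
        beta = {"bray_curtis": bray_curtis(rarefied)}
        if tree is not None:
            leafset = set(tree.leaf_names)
            beta_table = table.select_samples(rarefied.sample_ids)
            present = [f for f in beta_table.feature_ids if f in leafset]
            beta_table = beta_table.select_features(present)
            beta["unweighted_unifrac"] = unifrac(beta_table, tree, weighted=False)
            beta["weighted_unifrac"] = unifrac(beta_table, tree, weighted=True)
        ordinations = {name: pcoa(dm, n_axes=3) for name, dm in beta.items()}
        perma = {
            name: permanova(dm, metadata_r, n_perm=config.get("n_perm", 999), seed=seed)
            for name, dm in beta.items()
        }

        stage = "clr"
        clr = clr_transform(
            filtered,
            method=config.get("zero_replacement", "multiplicative"),
            replacement_factor=config.get("replacement_factor", 0.65),
        )

        stage = "gradient"
        gradient = gradient_scan(clr, metadata, mode="taxa")

        stage = "fb_ratio"
        fb = fb_ratio(filtered, binned_tax, metadata)

        stage = "diet_proxy"
        diet = None
        if chloro_table is not None:
            diet_tax = tax if "simulate" in config else cd.read_taxonomy(
                config.get("plant_taxonomy", config["taxonomy"])
            )
            diet = diet_proxy(table, chloro_table, diet_tax, metadata)

        stage = "collapse_validation"
        collapsed_frac, collapsed_meta = collapse_replicates(filtered, metadata)
        collapsed_clr = clr_from_fractions(
            collapsed_frac,
            method=config.get("zero_replacement", "multiplicative"),
            replacement_factor=config.get("replacement_factor", 0.65),
        )
        collapsed_gradient = gradient_scan(
            collapsed_clr, collapsed_meta, mode="taxa", adjust="bh"
        )

    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.get("seed", 0),
        "coding": GRADIENT_CODING,
        "n_input_samples": n_input_samples,
        "n_binned_features": binned.shape[0],
        "n_filtered_features": filtered.shape[0],
        "n_collapsed_samples": len(collapsed_meta.sample_ids),
        "rarefaction_depth": depth,
        "dropped_samples": dropped,
        "n_selected_features": int(gradient["selected"].sum()),
        "permanova": {k: {"pseudo_F": v.pseudo_f, "p": v.p_value} for k, v in perma.items()},
    }

    result = PipelineResult(
        table=table,
        metadata=metadata,
        alpha=alpha_df,
        alpha_tests=alpha_tests,
        beta=beta,
        permanova=perma,
        clr=clr,
        gradient=gradient,
        fb=fb,
        diet=diet,
        collapsed_gradient=collapsed_gradient,
        collapsed_metadata=collapsed_meta,
        manifest=manifest,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_table(table, out / "feature_table.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        alpha_df.to_csv(out / "alpha_diversity.tsv", sep="\t")
        gradient.to_csv(out / "gradient_scan.tsv", sep="\t")
        collapsed_gradient.to_csv(out / "gradient_scan_collapsed.tsv", sep="\t")
        fb.per_sample.to_csv(out / "fb_ratio.tsv", sep="\t")
        for name, dm in beta.items():
            cd.write_distance_matrix(dm, out / f"beta_{name}.tsv")
        for name, ordn in ordinations.items():
            ordn.samples.to_csv(out / f"pcoa_{name}.tsv", sep="\t")
        if diet is not None:
            diet.per_sample.to_csv(out / "diet_proxy.tsv", sep="\t")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return result
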