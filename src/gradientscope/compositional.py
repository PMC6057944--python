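"""Compositional preprocessing: taxonomic binning, abundance filtering,
zero replacement + centred log-ratio transform, rarefaction, the
arcsine-square-root display transform, and replicate collapse.

Counts live on a simplex once depths are divided out, so standard
statistics only apply after a log-ratio transform.  The pipeline order is
bin -> filter -> CLR; replicate collapse operates on relative abundances
(before CLR) for the pseudoreplication-robustness validation pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import (
    RANKS,
    RANK_PREFIXES,
    UNKNOWN_INDIVIDUAL,
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
)

__all__ = [
    "CLRMatrix",
    "bin_at_genus",
    "filter_features",
    "clr_transform",
    "clr_from_fractions",
    "rarefy",
    "collapse_replicates",
    "arcsine_sqrt",
]


def binning_label(lineage: tuple[str, ...]) -> str:
    """Label a lineage resolves to: the genus if characterised, otherwise the
    full prefix path down to the lowest characterised rank.

    A family-resolved bin keeps its whole path (``k__...;f__Ruminococcaceae``)
    so it can never collide with a genus bin or with a homonymous rank in a
    different clade.
    """
    genus = lineage[RANKS.index("genus")]
    if genus:
        return f"g__{genus}"
    lowest = max((i for i, lab in enumerate(lineage[:-1]) if lab), default=None)
    if lowest is None:
        return "unclassified"
    return ";".join(
        RANK_PREFIXES[i] + lineage[i] for i in range(lowest + 1) if lineage[i]
    )


def bin_at_genus(table: FeatureTable, tax: TaxonomyMap) -> FeatureTable:
    """Sum counts of features sharing a genus (or, where the genus is
    uncharacterised, sharing their lowest characterised rank).

    Output feature order follows first appearance in the input.
    """
    tax.covers(table.feature_ids)
    labels = [binning_label(tax.lineage(fid)) for fid in table.feature_ids]
    grouped = table.data.groupby(labels, sort=False).sum()
    return FeatureTable(grouped)


def filter_features(
    table: FeatureTable,
    min_samples: int = 3,
    min_mean_rel_abund: float = 1e-4,
) -> FeatureTable:
    """Retain features present (count > 0) in at least ``min_samples``
    samples AND whose mean per-sample relative abundance is at least
    ``min_mean_rel_abund`` (0.01% by default).  Both conditions required;
    input feature order preserved.
    """
    presence = (table.data > 0).sum(axis=1) >= min_samples
    mean_rel = table.relative_abundance().mean(axis=1) >= min_mean_rel_abund
    keep = presence & mean_rel
    if not keep.any():
        raise ValueError(
            f"all {table.shape[0]} features removed by the filter "
            f"(min_samples={min_samples}, min_mean_rel_abund={min_mean_rel_abund})"
        )
    return FeatureTable(table.data.loc[keep])


@dataclass
class CLRMatrix:
    """Centred log-ratio transformed table.

    ``data`` is features x samples with each sample column summing to zero;
    ``zero_replacement`` records the imputed detection limit (the fraction
    substituted for zeros) per sample, NaN where no replacement was needed;
    ``method``/``replacement_factor`` record how zeros were handled.
    """

    data: pd.DataFrame
    zero_replacement: pd.Series
    method: str = "multiplicative"
    replacement_factor: float = 0.65

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=0).to_numpy()
        if self.data.shape[1] and np.abs(sums).max() > 1e-9:
            raise ValueError("CLR columns must sum to zero")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def _replace_zeros(
    frac: np.ndarray, method: str, factor: float
) -> tuple[np.ndarray, float]:
    """Return a zero-free composition and the imputed detection limit."""
    zero = frac == 0
    if not zero.any():
        return frac, np.nan
    nonzero_min = frac[~zero].min()
    if method == "multiplicative":
        # impute delta for each zero, shrink non-zero parts multiplicatively
        delta = factor * nonzero_min
        out = frac * (1 - delta * zero.sum())
        out[zero] = delta
        return out, delta
    if method == "additive":
        delta = factor * nonzero_min
        out = frac + delta
        return out / out.sum(), delta
    if method == "none":
        raise ValueError("sample contains zeros and zero replacement is disabled")
    raise ValueError(f"unknown zero-replacement method {method!r}")


def clr_from_fractions(
    fractions: pd.DataFrame,
    method: str = "multiplicative",
    replacement_factor: float = 0.65,
) -> CLRMatrix:
    """CLR of a features x samples relative-abundance table.

    Per sample: replace zeros (see ``method``), then subtract the mean log
    from each log fraction.  Columns of the result sum to zero.
    """
    values = fractions.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("fractions must be non-negative")
    out = np.empty_like(values)
    deltas = np.full(values.shape[1], np.nan)
    for j in range(values.shape[1]):
        col = values[:, j]
        total = col.sum()
        if total <= 0:
            raise ValueError(f"sample {fractions.columns[j]!r} has zero total")
        col = col / total
        if (col > 0).sum() < 2:
            raise ValueError(
                f"sample {fractions.columns[j]!r} has fewer than two non-zero "
                "features; CLR is undefined"
            )
        col, deltas[j] = _replace_zeros(col, method, replacement_factor)
        logc = np.log(col)
        out[:, j] = logc - logc.mean()
    return CLRMatrix(
        data=pd.DataFrame(out, index=fractions.index, columns=fractions.columns),
        zero_replacement=pd.Series(deltas, index=fractions.columns),
        method=method,
        replacement_factor=replacement_factor,
    )


def clr_transform(
    table: FeatureTable,
    method: str = "multiplicative",
    replacement_factor: float = 0.65,
) -> CLRMatrix:
    """CLR of a count table (counts are converted to fractions per sample)."""
    return clr_from_fractions(
        table.data.astype(float), method=method, replacement_factor=replacement_factor
    )


def rarefy(
    table: FeatureTable, depth: int, seed: int
) -> tuple[FeatureTable, list[str]]:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped; their ids are
    returned alongside the rarefied table.  A sample whose total equals
    ``depth`` is returned unchanged.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_sums()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if not keep:
        raise ValueError(f"all samples have fewer than {depth} reads")
    cols = {}
    for s in keep:
        col = table.data[s].to_numpy()
        cols[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(cols, index=table.feature_ids, columns=keep)
    return FeatureTable(df.astype(np.int64)), dropped


def collapse_replicates(
    table: FeatureTable, metadata: SampleMetadata
) -> tuple[pd.DataFrame, SampleMetadata]:
    """Collapse replicate samples per individual into averaged profiles.

    Every sample is converted to relative abundances, then all samples of a
    (lifestyle, individual) pair are averaged into one profile; all samples
    with the UNKNOWN individual sentinel within a lifestyle collapse to a
    single profile.  Guards against pseudoreplication from unequal sampling
    of individuals.  Returns a real-valued fraction table (columns sum to 1)
    and the collapsed metadata.
    """
    metadata = metadata.align_to(table)
    frac = table.relative_abundance()
    keys = [
        (row["lifestyle"], row["individual_id"]) for _, row in metadata.data.iterrows()
    ]
    collapsed: dict[str, np.ndarray] = {}
    meta_rows = []
    seen: list[tuple[str, str]] = []
    for key in keys:
        if key in seen:
            continue
        seen.append(key)
        lifestyle, ind = key
        mask = [k == key for k in keys]
        collapsed_id = f"{lifestyle}:{ind}"
        collapsed[collapsed_id] = frac.loc[:, mask].mean(axis=1).to_numpy()
        meta_rows.append((collapsed_id, ind, lifestyle))
    out = pd.DataFrame(collapsed, index=table.feature_ids)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "individual_id", "lifestyle"]
    ).set_index("sample_id")
    return out, SampleMetadata(meta)


def arcsine_sqrt(fractions) -> np.ndarray:
    """Variance-stabilising display transform asin(sqrt(p)) for p in [0, 1]."""
    arr = np.asarray(fractions, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("arcsine-sqrt transform requires values in [0, 1]")
    return np.arcsin(np.sqrt(arr))
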