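"""Domain types and file I/O for the gradient analysis pipeline.

The pipeline moves five kinds of objects around: an integer feature-by-sample
count table, per-sample metadata carrying the ordered lifestyle factor, a
GreenGenes-style taxonomy map, a rooted phylogeny (for UniFrac), and square
distance matrices.  Everything is plain text: TSV tables and Newick trees.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "LIFESTYLES",
    "LIFESTYLE_LEVEL",
    "UNKNOWN_INDIVIDUAL",
    "RANKS",
    "RANK_PREFIXES",
    "FormatError",
    "FeatureTable",
    "SampleMetadata",
    "TaxonomyMap",
    "Phylogeny",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "read_distance_matrix",
    "write_distance_matrix",
]

#: Ordered lifestyle levels, captive end first.  The analysis treats these as
#: a discretisation of a latent "wildness" continuum, coded 1..4.
LIFESTYLES: tuple[str, ...] = ("captive", "semi-captive", "semi-wild", "wild")
LIFESTYLE_LEVEL: dict[str, int] = {name: i + 1 for i, name in enumerate(LIFESTYLES)}

#: Sentinel individual id for samples that cannot be attributed to a unique
#: animal (the unidentified wild pool).
UNKNOWN_INDIVIDUAL = "unknown"

RANKS: tuple[str, ...] = (
    "kingdom", "phylum", "class", "order", "family", "genus", "species",
)
RANK_PREFIXES: tuple[str, ...] = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Feature-by-sample count matrix.

    ``data`` is a features x samples DataFrame of non-negative integers with
    unique feature ids on the index and unique sample ids on the columns.
    Every sample column must have a positive total.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (values < 0).any():
            raise FormatError("negative counts are not allowed")
        totals = values.sum(axis=0)
        if df.shape[1] and (totals == 0).any():
            empty = df.columns[totals == 0].tolist()
            raise FormatError(f"samples with zero total counts: {empty}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample fractions (columns sum to 1)."""
        return self.data / self.data.sum(axis=0)

    def select_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(sample_ids)])

    def select_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(feature_ids)])


def _coerce_counts(df: pd.DataFrame, atol: float = 1e-9) -> pd.DataFrame:
    """Round float cells that are within ``atol`` of an integer; reject others.

    Tolerates TSV float formatting ("3.0") without admitting relative
    abundances as counts.
    """
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("non-numeric value in count table")
    rounded = np.rint(values)
    if np.abs(values - rounded).max(initial=0.0) > atol:
        raise FormatError("count table contains non-integer values")
    return pd.DataFrame(rounded.astype(np.int64), index=df.index, columns=df.columns)


def read_feature_table(path) -> FeatureTable:
    """Read a TSV count table: first column feature ids, header sample ids.

    Leading lines starting with ``#`` are treated as comments.
    """
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty table")
    header = lines[0].rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{path}: duplicate sample ids in header: {dup}")
    try:
        df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    try:
        return FeatureTable(_coerce_counts(df))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_feature_table(table: FeatureTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample metadata: individual id and ordered lifestyle level.

    ``data`` is indexed by sample id with columns ``individual_id`` (string,
    possibly the :data:`UNKNOWN_INDIVIDUAL` sentinel) and ``lifestyle`` (one
    of :data:`LIFESTYLES`).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"individual_id", "lifestyle"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        bad = sorted(set(df["lifestyle"]) - set(LIFESTYLES))
        if bad:
            raise FormatError(
                f"unknown lifestyle labels {bad}; accepted labels are {list(LIFESTYLES)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def lifestyle(self) -> pd.Series:
        return self.data["lifestyle"]

    def levels(self) -> pd.Series:
        """Numeric lifestyle coding, captive=1 .. wild=4 (wildness-ascending)."""
        return self.data["lifestyle"].map(LIFESTYLE_LEVEL)

    def individual(self) -> pd.Series:
        return self.data["individual_id"]

    def align_to(self, table: FeatureTable) -> "SampleMetadata":
        """Reorder to the table's samples; raise on any mismatch."""
        table_ids = set(table.sample_ids)
        meta_ids = set(self.data.index)
        if table_ids != meta_ids:
            raise FormatError(
                "sample sets differ between table and metadata: "
                f"table-only={sorted(table_ids - meta_ids)[:5]}, "
                f"metadata-only={sorted(meta_ids - table_ids)[:5]}"
            )
        return SampleMetadata(self.data.loc[table.sample_ids])


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata must have a sample_id column")
    df = df.set_index("sample_id")
    try:
        return SampleMetadata(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Parse a GreenGenes lineage string into 7 rank labels.

    Rank prefixes (``k__`` .. ``s__``) are stripped; missing trailing ranks
    are padded with empty labels, so ``"k__Bacteria; p__Firmicutes"`` yields
    ``("Bacteria", "Firmicutes", "", "", "", "", "")``.
    """
    parts = [p.strip() for p in lineage.split(";")] if lineage.strip() else []
    if len(parts) > len(RANKS):
        raise FormatError(f"lineage has more than {len(RANKS)} ranks: {lineage!r}")
    labels: list[str] = []
    for i, part in enumerate(parts):
        if part == "":
            labels.append("")
            continue
        prefix = RANK_PREFIXES[i]
        if not part.startswith(prefix):
            raise FormatError(
                f"rank {i + 1} of lineage {lineage!r} does not start with {prefix!r}"
            )
        labels.append(part[len(prefix):])
    labels.extend([""] * (len(RANKS) - len(labels)))
    return tuple(labels)


def format_lineage(labels) -> str:
    """Inverse of :func:`parse_lineage`: restore rank prefixes."""
    return "; ".join(p + l for p, l in zip(RANK_PREFIXES, labels))


@dataclass
class TaxonomyMap:
    """Feature id -> 7-rank lineage lookup.

    ``data`` is indexed by feature id with one column per rank in
    :data:`RANKS`; empty strings mark uncharacterised ranks.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(RANKS):
            raise FormatError(f"taxonomy columns must be {list(RANKS)}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate feature ids in taxonomy")

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        try:
            return tuple(self.data.loc[feature_id])
        except KeyError:
            raise KeyError(f"feature {feature_id!r} missing from taxonomy") from None

    def rank(self, feature_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.lineage(feature_id)[RANKS.index(rank)]

    def phylum(self, feature_id: str) -> str:
        return self.rank(feature_id, "phylum")

    def covers(self, feature_ids) -> None:
        """Raise if any feature id lacks a lineage (lookup must be total)."""
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"features missing from taxonomy: {missing[:5]}")

    @classmethod
    def from_lineages(cls, mapping: dict[str, str]) -> "TaxonomyMap":
        rows = {fid: parse_lineage(lin) for fid, lin in mapping.items()}
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
        return cls(df)


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["feature_id", "lineage"], dtype=str)
    if df["lineage"].isna().any():
        raise FormatError(f"{path}: taxonomy rows must have two columns")
    return TaxonomyMap.from_lineages(dict(zip(df["feature_id"], df["lineage"])))


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        for fid, row in tax.data.iterrows():
            fh.write(f"{fid}\t{format_lineage(tuple(row))}\n")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """Rooted tree over (a superset of) the feature ids, for UniFrac."""

    tree: skbio.TreeNode = field(repr=False)

    def __post_init__(self) -> None:
        names = [t.name for t in self.tree.tips()]
        if len(names) != len(set(names)):
            raise FormatError("duplicate leaf names in tree")
        for node in self.tree.traverse(include_self=True):
            if node.length is not None and node.length < 0:
                raise FormatError("negative branch length in tree")

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.traverse(include_self=True))

    def to_newick(self) -> str:
        return str(self.tree).strip()


def read_newick(path) -> Phylogeny:
    tree = skbio.TreeNode.read(str(path), format="newick")
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


def write_distance_matrix(dm: skbio.DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="#sample_id"
    )


def read_distance_matrix(path) -> skbio.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: distance matrix ids differ between axes")
    data = df.to_numpy(dtype=float)
    # symmetrise tiny round-trip asymmetries, reject real ones
    if np.abs(data - data.T).max(initial=0.0) > 1e-12:
        raise FormatError(f"{path}: distance matrix is not symmetric")
    data = (data + data.T) / 2.0
    np.fill_diagonal(data, 0.0)
    return skbio.DistanceMatrix(data, ids=list(df.index))
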