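"""Count tables, sample metadata, taxonomy and trees, plus standard amplicon preprocessing.

The on-disk dialect for count tables follows the common amplicon convention:
taxa as rows, samples as columns, tab-separated, first header cell
``taxon_id``.  In memory the orientation is samples x taxa (a pandas
DataFrame with sample ids as the index), which is what every downstream
computation wants.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CountTable",
    "SampleMetadata",
    "TaxonomyTable",
    "CountTableFormatError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "read_tree",
    "filter_low_count_taxa",
    "rarefy",
    "aggregate_to_genus",
    "relative_abundance",
]

METADATA_COLUMNS = [
    "sample_id",
    "sample_type",
    "population",
    "site",
    "timepoint",
    "treatment",
    "jar",
]

SAMPLE_TYPES = {"polyp", "water"}
TREATMENTS = {"native", "foreign", "none"}

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus"]


class CountTableFormatError(ValueError):
    """Raised for malformed count-table input (bad cell, duplicate id, empty table)."""


@dataclass(frozen=True)
class CountTable:
    """Samples x taxa table of non-negative integer read counts.

    Invariants enforced at construction: unique sample and taxon ids,
    integer counts >= 0, and a positive read total for every sample.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0:
            raise CountTableFormatError("no samples")
        if df.shape[1] == 0:
            raise CountTableFormatError("no taxa")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise CountTableFormatError(f"duplicate sample id(s): {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise CountTableFormatError(f"duplicate taxon id(s): {dups}")
        if not np.issubdtype(df.to_numpy().dtype, np.integer):
            raise CountTableFormatError("counts must be integers")
        if (df.to_numpy() < 0).any():
            raise CountTableFormatError("negative counts")
        zero = df.sum(axis=1) == 0
        if zero.any():
            raise CountTableFormatError(
                f"zero-sum sample(s): {df.index[zero].tolist()}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def taxon_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, sample_ids: Iterable[str], drop_empty_taxa: bool = False) -> "CountTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown sample id(s): {sorted(missing)}")
        sub = self.data.loc[ids]
        if drop_empty_taxa:
            sub = sub.loc[:, sub.sum(axis=0) > 0]
        return CountTable(sub)


def read_count_table(path: str | Path | io.TextIOBase) -> CountTable:
    """Read a taxa-by-samples TSV (header ``taxon_id`` then sample ids) into a CountTable."""
    raw = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise CountTableFormatError("no samples")
    samples = [str(c).strip() for c in raw.iloc[0, 1:]]
    if len(set(samples)) != len(samples):
        raise CountTableFormatError("duplicate sample column in header")
    taxa = [str(t).strip() for t in raw.iloc[1:, 0]]
    if len(set(taxa)) != len(taxa):
        dups = sorted({t for t in taxa if taxa.count(t) > 1})
        raise CountTableFormatError(f"duplicate taxon id(s): {dups}")
    body = raw.iloc[1:, 1:]
    values = np.empty(body.shape, dtype=np.int64)
    for i in range(body.shape[0]):
        for j in range(body.shape[1]):
            cell = body.iat[i, j]
            try:
                values[i, j] = int(str(cell).strip())
            except (TypeError, ValueError):
                raise CountTableFormatError(
                    f"non-integer cell at taxon {taxa[i]!r}, sample {samples[j]!r}: {cell!r}"
                ) from None
    mat = pd.DataFrame(values.T, index=samples, columns=taxa)
    return CountTable(mat)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write the taxa-as-rows TSV dialect read back by :func:`read_count_table`."""
    out = table.data.T.copy()
    out.index.name = "taxon_id"
    out.columns.name = None
    out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample design factors: type (polyp/water), population, site, week, treatment, jar."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ("sample_id", "sample_type") if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required column(s): {missing}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        bad = set(df["sample_type"]) - SAMPLE_TYPES
        if bad:
            raise ValueError(f"unknown sample_type value(s): {sorted(bad)}")
        if "treatment" in df.columns:
            bad = set(df["treatment"].dropna()) - TREATMENTS
            if bad:
                raise ValueError(f"unknown treatment value(s): {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("sample_id")

    def covers(self, table: CountTable) -> bool:
        return set(table.sample_ids) <= set(self.sample_ids)

    def subset(self, mask: pd.Series) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[mask.to_numpy()].reset_index(drop=True))


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "timepoint" in df.columns:
        df["timepoint"] = df["timepoint"].astype("Int64")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class TaxonomyTable:
    """taxon_id -> rank labels (kingdom..genus); empty strings mark unassigned ranks."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "taxon_id" not in self.data.columns:
            raise ValueError("taxonomy missing taxon_id column")
        if self.data["taxon_id"].duplicated().any():
            raise ValueError("duplicate taxon_id in taxonomy")

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("taxon_id")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return TaxonomyTable(df)


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree; validates unique tips and non-negative branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    return tree


def filter_low_count_taxa(table: CountTable, min_total: int = 50) -> CountTable:
    """Drop taxa whose dataset-wide total count is below ``min_total``.

    The default of 50 is the conventional low-count ASV filter applied to the
    whole dataset before any per-sample normalisation.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.taxon_sums() >= min_total
    if not keep.any():
        raise CountTableFormatError("empty table after filtering")
    return CountTable(table.data.loc[:, keep])


def rarefy(
    table: CountTable,
    depth: int | None = None,
    seed: int | np.random.Generator = 0,
) -> CountTable:
    """Subsample every sample without replacement to a common depth.

    ``depth=None`` uses the minimum sample sum (the "minimum number of reads
    for the experiment" convention). Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    if depth is None:
        depth = int(sums.min())
    if depth <= 0:
        raise ValueError("depth must be positive")
    short = sums[sums < depth]
    if len(short):
        raise ValueError(
            f"sample(s) with fewer than {depth} reads: {dict(short)}"
        )
    out = np.empty(table.data.shape, dtype=np.int64)
    counts = table.counts
    for i in range(counts.shape[0]):
        row = counts[i]
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return CountTable(pd.DataFrame(out, index=table.data.index, columns=table.data.columns))


def aggregate_to_genus(
    table: CountTable,
    taxonomy: TaxonomyTable,
    unassigned: str = "pseudo_genus",
) -> CountTable:
    """Sum ASV counts into genus-level counts.

    ASVs with an empty genus label are pooled into ``unclassified_<family>``
    pseudo-genera (``unassigned="pseudo_genus"``, the default) or dropped
    (``unassigned="drop"``). Read totals are conserved exactly under the
    default.
    """
    tax = taxonomy.indexed()
    missing = set(table.taxon_ids) - set(tax.index)
    if missing:
        raise KeyError(f"taxa missing from taxonomy: {sorted(missing)[:5]}")
    labels = {}
    for t in table.taxon_ids:
        genus = str(tax.at[t, "genus"]) if "genus" in tax.columns else ""
        if genus:
            labels[t] = genus
        elif unassigned == "drop":
            labels[t] = None
        else:
            family = str(tax.at[t, "family"]) if "family" in tax.columns else ""
            labels[t] = f"unclassified_{family or 'unknown'}"
    kept = [t for t in table.taxon_ids if labels[t] is not None]
    grouped = table.data[kept].T.groupby(by=lambda t: labels[t]).sum().T
    return CountTable(grouped)


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample relative abundances; each row sums to 1."""
    sums = table.sample_sums()
    if (sums == 0).any():
        raise ValueError("zero-sum sample")
    return table.data.div(sums, axis=0)
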