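"""OTU count tables with sample metadata, taxonomy, and pre-network filters.

The pipeline's universal currency is the :class:`OTUTable`: a samples x OTUs
count matrix joined with per-sample metadata (site, fraction, date,
temperature) and a per-OTU guild label separating the two predatory clades
(Bdellovibrionales, Bacteriovoracales) from candidate prey. Tables exist in
two modes: ``raw_counts`` (reads) and ``relative`` (rows sum to one).

All file interfaces are tab-separated text: a counts matrix with sample ids
in the first column and OTU ids in the header, a two-column taxonomy table
(otu id, semicolon-delimited SILVA-style lineage), and a metadata table with
``sample_id``, ``site``, ``fraction``, ``date`` and optional ``temperature``
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "Taxonomy",
    "GUILDS",
    "GRAM_POSITIVE_PHYLA",
    "read_otu_table",
    "write_otu_table",
    "relativize",
    "filter_min_reads",
    "filter_gram_positive",
    "split_by_group",
]

GUILDS = ("predator_bd", "predator_bx", "prey_candidate")

#: Phyla removed from the prey-candidate pool before screening. BALOs prey
#: exclusively on gram-negative cells, so correlations with these clades can
#: only be indirect.
GRAM_POSITIVE_PHYLA = frozenset({"Actinobacteria", "Firmicutes"})

#: Order-level markers used to assign predator guilds from a lineage.
_PREDATOR_ORDERS = {"Bdellovibrionales": "predator_bd", "Bacteriovoracales": "predator_bx"}

_RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus")

_METADATA_REQUIRED = ("site", "fraction", "date")


@dataclass(frozen=True)
class Taxonomy:
    """Per-OTU lineages parsed from semicolon-delimited strings.

    ``lineages`` maps otu id -> tuple of ranks (domain ... genus); missing
    ranks are stored as the explicit string ``"unclassified"``. The verbatim
    source string is retained in ``source``.
    """

    lineages: dict[str, tuple[str, ...]]
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for otu, lineage in self.lineages.items():
            if len(lineage) == 0:
                raise ValueError(f"empty lineage for OTU {otu!r}")

    @classmethod
    def from_strings(cls, strings: dict[str, str]) -> "Taxonomy":
        lineages = {}
        for otu, raw in strings.items():
            ranks = [r.strip() for r in str(raw).strip().rstrip(";").split(";")]
            ranks = [r if r else "unclassified" for r in ranks]
            if not ranks:
                raise ValueError(f"empty lineage for OTU {otu!r}")
            # pad to the six canonical ranks
            while len(ranks) < len(_RANK_NAMES):
                ranks.append("unclassified")
            lineages[otu] = tuple(ranks)
        return cls(lineages=lineages, source=dict(strings))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Taxonomy":
        df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "lineage"], dtype=str)
        dup = df["otu_id"][df["otu_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate OTU id in taxonomy: {dup.iloc[0]!r}")
        return cls.from_strings(dict(zip(df["otu_id"], df["lineage"])))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for otu, lineage in self.lineages.items():
                raw = self.source.get(otu, ";".join(lineage))
                fh.write(f"{otu}\t{raw}\n")

    def rank(self, otu_id: str, rank: str) -> str:
        idx = _RANK_NAMES.index(rank)
        lineage = self.lineages[otu_id]
        return lineage[idx] if idx < len(lineage) else "unclassified"

    def phylum(self, otu_id: str) -> str:
        return self.rank(otu_id, "phylum")

    def guild_of(self, otu_id: str) -> str:
        """Guild from the order rank: predatory clades vs prey candidate."""
        lineage = self.lineages.get(otu_id, ())
        for rank in lineage:
            if rank in _PREDATOR_ORDERS:
                return _PREDATOR_ORDERS[rank]
        return "prey_candidate"

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass
class OTUTable:
    """Samples x OTUs abundance matrix with metadata and guild labels.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns are OTU ids. Non-negative.
    sample_meta
        DataFrame indexed by sample id with columns ``site``, ``fraction``
        (``floc``/``liquor``), ``date`` (datetime) and optionally
        ``temperature`` (deg C; NaN where not recorded).
    guild
        Series mapping otu id -> one of ``predator_bd``, ``predator_bx``,
        ``prey_candidate``.
    mode
        ``"raw_counts"`` or ``"relative"``. In relative mode every sample
        row sums to 1 (+/- 1e-9).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    guild: pd.Series
    mode: str = "raw_counts"
    #: False for a column subset of a relative table: entries are still
    #: proportions of the whole sample, but rows no longer sum to one.
    complete: bool = True

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if self.mode not in ("raw_counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate OTU id: {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative abundance in counts matrix")
        missing_meta = self.counts.index.difference(self.sample_meta.index)
        if len(missing_meta):
            raise ValueError(f"sample {missing_meta[0]!r} present in counts but absent from metadata")
        for col in _METADATA_REQUIRED:
            if col not in self.sample_meta.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        missing_guild = self.counts.columns.difference(self.guild.index)
        if len(missing_guild):
            raise ValueError(f"OTU {missing_guild[0]!r} has no guild label")
        bad = set(self.guild.loc[self.counts.columns]) - set(GUILDS)
        if bad:
            raise ValueError(f"unknown guild label(s): {sorted(bad)}")
        if self.mode == "relative" and self.complete:
            totals = self.counts.sum(axis=1).to_numpy()
            if not np.allclose(totals, 1.0, atol=1e-9, rtol=0):
                raise ValueError("relative-mode rows must sum to 1 +/- 1e-9")

    # -- views ------------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def guild_otus(self, *guilds: str) -> list[str]:
        keep = set(guilds)
        labels = self.guild.loc[self.counts.columns]
        return [o for o, g in labels.items() if g in keep]

    def subset_otus(self, otu_ids) -> "OTUTable":
        otu_ids = [o for o in self.counts.columns if o in set(otu_ids)]
        if self.mode == "relative":
            return _relative_subset(self, otu_ids)
        return OTUTable(
            counts=self.counts[otu_ids].copy(),
            sample_meta=self.sample_meta,
            guild=self.guild.loc[otu_ids],
            mode="raw_counts",
        )

    def subset_samples(self, sample_ids) -> "OTUTable":
        keep = [s for s in self.counts.index if s in set(sample_ids)]
        return OTUTable(
            counts=self.counts.loc[keep].copy(),
            sample_meta=self.sample_meta.loc[keep].copy(),
            guild=self.guild,
            mode=self.mode,
            complete=self.complete,
        )

    def predators(self) -> "OTUTable":
        return self.subset_otus(self.guild_otus("predator_bd", "predator_bx"))

    def prey(self) -> "OTUTable":
        return self.subset_otus(self.guild_otus("prey_candidate"))

    def time_ordered(self) -> "OTUTable":
        """Samples sorted by date, ties broken by sample id."""
        meta = self.sample_meta.loc[self.counts.index]
        order = sorted(self.counts.index, key=lambda s: (meta.at[s, "date"], s))
        return OTUTable(
            counts=self.counts.loc[order],
            sample_meta=self.sample_meta.loc[order],
            guild=self.guild,
            mode=self.mode,
            complete=self.complete,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OTUTable):
            return NotImplemented
        return (
            self.mode == other.mode
            and self.counts.equals(other.counts)
            and self.guild.loc[self.counts.columns].equals(other.guild.loc[other.counts.columns])
            and self.sample_meta.loc[self.counts.index].reset_index(drop=True).equals(
                other.sample_meta.loc[other.counts.index].reset_index(drop=True)
            )
        )


def _relative_subset(table: OTUTable, otu_ids: list[str]) -> OTUTable:
    # proportions relative to the whole sample are retained, not renormalized
    return OTUTable(
        counts=table.counts[otu_ids].copy(),
        sample_meta=table.sample_meta,
        guild=table.guild.loc[otu_ids],
        mode="relative",
        complete=False,
    )


# -- I/O -------------------------------------------------------------------


def read_otu_table(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
) -> tuple[OTUTable, Taxonomy]:
    """Load counts + taxonomy + metadata TSVs into a joined raw-count table.

    Guild labels are derived from the taxonomy: OTUs whose lineage contains
    the order Bdellovibrionales or Bacteriovoracales become predators, all
    others prey candidates.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate sample id in {counts_path}: {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate OTU id in {counts_path}: {dup!r}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        for j, col in enumerate(counts.columns):
            bad = pd.to_numeric(counts[col], errors="coerce")
            if bad.isna().any():
                row = counts.index[int(np.where(bad.isna())[0][0])]
                raise ValueError(
                    f"non-numeric count in {counts_path} at sample {row!r}, OTU {col!r}"
                )
        counts = counts.astype(float)

    taxonomy = Taxonomy.read_tsv(taxonomy_path)

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ValueError(f"metadata {metadata_path} lacks a sample_id column")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id in {metadata_path}: {dup!r}")
    meta = meta.set_index("sample_id")
    meta["date"] = pd.to_datetime(meta["date"])
    if "temperature" not in meta.columns:
        meta["temperature"] = np.nan
    meta["temperature"] = pd.to_numeric(meta["temperature"], errors="coerce")

    guild = pd.Series({o: taxonomy.guild_of(o) for o in counts.columns}, name="guild")
    table = OTUTable(counts=counts, sample_meta=meta, guild=guild, mode="raw_counts")
    return table, taxonomy


def write_otu_table(
    table: OTUTable,
    counts_path: str | Path,
    metadata_path: str | Path,
    taxonomy: Taxonomy | None = None,
    taxonomy_path: str | Path | None = None,
) -> None:
    """Write a table (and optionally its taxonomy) back to TSV files."""
    table.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
    meta = table.sample_meta.loc[table.counts.index].copy()
    meta["date"] = pd.to_datetime(meta["date"]).dt.strftime("%Y-%m-%d")
    meta.to_csv(metadata_path, sep="\t", index_label="sample_id")
    if taxonomy is not None and taxonomy_path is not None:
        taxonomy.write_tsv(taxonomy_path)


# -- transforms and filters -----------------------------------------------


def relativize(table: OTUTable) -> OTUTable:
    """Convert reads to relative abundances (each row / its total).

    Mirrors relativization to sampling effort: every entry is divided by the
    number of reads obtained from that sample.
    """
    if table.mode != "raw_counts":
        raise ValueError("relativize expects a raw_counts table")
    totals = table.counts.sum(axis=1)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"zero-total sample(s), cannot relativize: {zero}")
    rel = table.counts.div(totals, axis=0)
    return OTUTable(counts=rel, sample_meta=table.sample_meta, guild=table.guild, mode="relative")


def filter_min_reads(table: OTUTable, threshold: int = 10, per_sample: bool = False) -> OTUTable:
    """Drop OTUs with no more than ``threshold`` reads in the series.

    The abundance filter is strict (> threshold): an OTU totalling exactly
    ``threshold`` reads is removed. By default the filter sums reads over the
    whole site-fraction time series; ``per_sample=True`` instead requires
    more than ``threshold`` reads in every sample.
    """
    if table.mode != "raw_counts":
        raise ValueError("filter_min_reads is defined on read counts, not relative abundances")
    if per_sample:
        keep_mask = (table.counts > threshold).all(axis=0)
    else:
        keep_mask = table.counts.sum(axis=0) > threshold
    keep = list(table.counts.columns[keep_mask])
    return OTUTable(
        counts=table.counts[keep].copy(),
        sample_meta=table.sample_meta,
        guild=table.guild.loc[keep] if keep else table.guild.iloc[0:0],
        mode="raw_counts",
    )


def filter_gram_positive(table: OTUTable, taxonomy: Taxonomy) -> OTUTable:
    """Remove gram-positive prey candidates (Actinobacteria, Firmicutes).

    Obligate gram-negative predators cannot prey on these clades, so any
    negative correlation with them would be indirect. Predator OTUs are
    never removed; prey with an unresolved phylum are conservatively kept.
    """
    drop = set()
    for otu in table.counts.columns:
        if table.guild.at[otu] != "prey_candidate":
            continue
        if otu in taxonomy and taxonomy.phylum(otu) in GRAM_POSITIVE_PHYLA:
            drop.add(otu)
    keep = [o for o in table.counts.columns if o not in drop]
    return OTUTable(
        counts=table.counts[keep].copy(),
        sample_meta=table.sample_meta,
        guild=table.guild.loc[keep] if keep else table.guild.iloc[0:0],
        mode=table.mode,
        complete=table.complete and not (table.mode == "relative" and drop),
    )


def split_by_group(table: OTUTable, keys: tuple[str, ...] | list[str]) -> dict[tuple, OTUTable]:
    """Partition samples by metadata keys (subset of site/fraction).

    Returns a dict mapping the key tuple -> sub-table with samples in time
    order (date, then sample id). Empty groups are never emitted; the union
    of the outputs is exactly the input sample set.
    """
    keys = list(keys)
    allowed = {"site", "fraction"}
    bad = set(keys) - allowed
    if bad:
        raise ValueError(f"invalid grouping key(s) {sorted(bad)}; allowed: {sorted(allowed)}")
    meta = table.sample_meta.loc[table.counts.index]
    out: dict[tuple, OTUTable] = {}
    for key_vals, sub_meta in meta.groupby(keys, sort=True, observed=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        sub = table.subset_samples(list(sub_meta.index)).time_ordered()
        out[key_vals] = sub
    return out
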