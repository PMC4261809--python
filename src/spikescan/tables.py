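"""Count-table handling: I/O, depth filtering, rarefaction, relative
abundance, rank aggregation, and the replicate-derived reliability cutoff.

The canonical processing order is fixed:

    depth filter -> rarefy -> relative abundance -> rank aggregation -> cutoff

Counts are integer reads per taxon per sample. Lineages use QIIME-style
rank prefixes (``p__Bacteroidetes;g__Bacteroides;s__dorei_vulgatus``);
levels that cannot be resolved carry an explicit ``unclassified`` label and
aggregate into an ``unclassified-<parent>`` bucket rather than being dropped.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("phylum", "genus", "species")
_RANK_PREFIX = {"phylum": "p__", "genus": "g__", "species": "s__"}
_RANK_DEPTH = {"phylum": 1, "genus": 2, "species": 3}

METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "age_days",
    "group",
    "platform",
    "replicate_group",
)


class TableError(ValueError):
    """Raised for malformed or inconsistent tables."""


@dataclass
class TaxonCountTable:
    """Integer read counts, taxa x samples, with a lineage per taxon."""

    counts: pd.DataFrame  # index: taxon_id, columns: sample_id, dtype int
    lineage: pd.Series  # index: taxon_id -> lineage string

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lineage.index):
            self.lineage = self.lineage.reindex(self.counts.index)
        if self.lineage.isna().any():
            missing = list(self.lineage[self.lineage.isna()].index)
            raise TableError(f"taxa without lineage: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise TableError("negative counts")
        if self.counts.columns.duplicated().any():
            dupes = list(self.counts.columns[self.counts.columns.duplicated()])
            raise TableError(f"duplicate sample ids: {dupes}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "TaxonCountTable":
        return TaxonCountTable(self.counts.loc[:, list(sample_ids)].copy(), self.lineage.copy())

    def copy(self) -> "TaxonCountTable":
        return TaxonCountTable(self.counts.copy(), self.lineage.copy())


@dataclass
class RelativeAbundanceTable:
    """Per-sample fractions in [0, 1]; each column sums to 1."""

    fractions: pd.DataFrame
    lineage: pd.Series
    rarefaction_depth: int | None = None

    def __post_init__(self) -> None:
        if not self.fractions.index.equals(self.lineage.index):
            self.lineage = self.lineage.reindex(self.fractions.index)
        sums = self.fractions.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise TableError("relative abundance columns must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.columns)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.fractions.index)


@dataclass
class CutoffReport:
    """Replicate-dispersion profile and the abundance-reliability cutoff."""

    bin_centers: np.ndarray
    dispersion: np.ndarray  # mean within-replicate-group CV per bin
    smoothed: np.ndarray  # monotone (non-increasing in abundance) envelope
    cutoff: float
    dispersion_threshold: float
    n_groups: int


# ---------------------------------------------------------------------------
# lineage helpers


def rank_label(lineage: str, rank: str) -> str:
    """Label of ``lineage`` truncated at ``rank``.

    Unresolved levels yield ``unclassified-<parent label>`` so that mass is
    retained under an explicit bucket.
    """
    if rank not in _RANK_DEPTH:
        raise TableError(f"unknown rank {rank!r}; expected one of {RANKS}")
    parts = lineage.split(";")
    depth = _RANK_DEPTH[rank]
    kept = parts[:depth]
    if len(kept) < depth or not kept[-1] or kept[-1].endswith("__") or kept[-1].split("__", 1)[-1] in ("", "unclassified"):
        parent = ";".join(kept[:-1]) if len(kept) > 1 else (kept[0] if kept else "root")
        return f"unclassified-{parent}"
    return ";".join(kept)


# ---------------------------------------------------------------------------
# I/O

_PROVENANCE_PREFIX = "# "


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str})


def write_counts(table: TaxonCountTable, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write taxa-by-sample counts as TSV (taxon_id, lineage, samples...)."""
    out = table.counts.copy()
    out.insert(0, "lineage", table.lineage)
    out.index.name = "taxon_id"
    buf = io.StringIO()
    for line in header_lines:
        buf.write(_PROVENANCE_PREFIX + line.rstrip("\n") + "\n")
    out.to_csv(buf, sep="\t")
    Path(path).write_text(buf.getvalue())


def read_counts(path: str | Path) -> TaxonCountTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "taxon_id" not in df.columns or "lineage" not in df.columns:
        raise TableError(f"{path}: expected 'taxon_id' and 'lineage' columns")
    df = df.set_index("taxon_id")
    lineage = df.pop("lineage").astype(str)
    counts = df
    bad = [c for c in counts.columns if not np.issubdtype(counts[c].dtype, np.number)]
    if bad:
        raise TableError(f"{path}: non-numeric count columns {bad}")
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise TableError(f"{path}: non-integer counts")
    return TaxonCountTable(counts.astype(np.int64), lineage)


def write_metadata(metadata: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    buf = io.StringIO()
    for line in header_lines:
        buf.write(_PROVENANCE_PREFIX + line.rstrip("\n") + "\n")
    metadata.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise TableError(f"metadata missing columns: {missing}")
    if metadata["sample_id"].duplicated().any():
        dupes = list(metadata.loc[metadata["sample_id"].duplicated(), "sample_id"])
        raise TableError(f"duplicate sample ids in metadata: {dupes}")
    if (metadata["age_days"] < 0).any():
        raise TableError("negative ages in metadata")
    bad_groups = set(metadata["group"]) - {"case", "control"}
    if bad_groups:
        raise TableError(f"unknown group labels: {sorted(bad_groups)}")
    return metadata


def read_tables(counts_path: str | Path, metadata_path: str | Path) -> tuple[TaxonCountTable, pd.DataFrame]:
    """Read and reconcile a count table with its sample metadata.

    Samples present in the counts but absent from the metadata are a hard
    error naming the offenders; metadata rows without counts are dropped
    with a warning (they may simply have failed sequencing).
    """
    table = read_counts(counts_path)
    metadata = validate_metadata(pd.read_csv(metadata_path, sep="\t", comment="#"))
    meta_ids = set(metadata["sample_id"])
    count_ids = set(table.sample_ids)
    orphans = sorted(count_ids - meta_ids)
    if orphans:
        raise TableError(f"samples missing metadata: {orphans}")
    extra = sorted(meta_ids - count_ids)
    if extra:
        warnings.warn(f"metadata rows without counts dropped: {extra}", stacklevel=2)
        metadata = metadata[metadata["sample_id"].isin(count_ids)].reset_index(drop=True)
    return table, metadata


# ---------------------------------------------------------------------------
# pipeline operations


def filter_low_depth(table: TaxonCountTable, min_reads: int = 10_000) -> tuple[TaxonCountTable, list[str]]:
    """Drop samples with strictly fewer than ``min_reads`` total reads."""
    totals = table.sample_totals()
    keep = totals[totals >= min_reads].index
    excluded = sorted(set(table.sample_ids) - set(keep))
    if len(keep) == 0:
        raise TableError("no samples survive depth filter")
    return table.subset_samples([s for s in table.sample_ids if s in set(keep)]), excluded


def rarefy(table: TaxonCountTable, depth: int = 10_000, seed: int = 0) -> TaxonCountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    A single multivariate-hypergeometric draw per sample; deterministic for
    a given seed. Samples already at the target depth pass through unchanged.
    """
    totals = table.sample_totals()
    shallow = totals[totals < depth]
    if len(shallow):
        raise TableError(
            f"samples below rarefaction depth {depth}: {sorted(shallow.index)}; filter first"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    arr = table.counts.to_numpy()
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return TaxonCountTable(counts, table.lineage.copy())


def to_relative(table: TaxonCountTable, rarefaction_depth: int | None = None) -> RelativeAbundanceTable:
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise TableError(f"zero-total samples: {sorted(zero.index)}")
    fractions = table.counts / totals
    return RelativeAbundanceTable(fractions, table.lineage.copy(), rarefaction_depth)


def aggregate_rank(table: TaxonCountTable | RelativeAbundanceTable, rank: str):
    """Sum counts/fractions over taxa sharing the lineage label at ``rank``."""
    values = table.counts if isinstance(table, TaxonCountTable) else table.fractions
    labels = table.lineage.map(lambda lin: rank_label(lin, rank))
    grouped = values.groupby(labels.values).sum()
    grouped.index.name = "taxon_id"
    lineage = pd.Series(grouped.index, index=grouped.index, name="lineage")
    if isinstance(table, TaxonCountTable):
        return TaxonCountTable(grouped, lineage)
    return RelativeAbundanceTable(grouped, lineage, table.rarefaction_depth)


def derive_cutoff(
    rel_table: RelativeAbundanceTable,
    metadata: pd.DataFrame,
    dispersion_threshold: float = 0.35,
    n_bins: int = 20,
) -> CutoffReport:
    """Derive the minimum reliably-measurable abundance from replicates.

    Within each technical-replicate group the coefficient of variation of a
    taxon's relative abundance rises sharply as abundance falls. Pairs of
    (mean within-group abundance, within-group CV) are binned on a log-spaced
    abundance grid, the per-bin mean CV is smoothed to be non-increasing in
    abundance, and the cutoff is the smallest abundance whose smoothed CV is
    at or below ``dispersion_threshold``.
    """
    groups = metadata.dropna(subset=["replicate_group"])
    groups = groups[groups["replicate_group"].astype(str) != ""]
    group_map: dict[str, list[str]] = {}
    for gid, sub in groups.groupby("replicate_group"):
        ids = [s for s in sub["sample_id"] if s in set(rel_table.sample_ids)]
        if len(ids) >= 2:
            group_map[str(gid)] = ids
    if len(group_map) < 5:
        raise TableError(f"need >= 5 replicate groups with >= 2 members, got {len(group_map)}")

    means, cvs = [], []
    frac = rel_table.fractions
    for ids in group_map.values():
        block = frac[ids].to_numpy()
        m = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        ok = m > 0
        means.append(m[ok])
        cvs.append(sd[ok] / m[ok])
    mean_arr = np.concatenate(means)
    cv_arr = np.concatenate(cvs)

    lo, hi = mean_arr.min(), mean_arr.max()
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    edges[-1] *= 1 + 1e-12
    centers = np.sqrt(edges[:-1] * edges[1:])
    dispersion = np.full(n_bins, np.nan)
    idx = np.digitize(mean_arr, edges) - 1
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            dispersion[b] = cv_arr[sel].mean()

    # monotone non-increasing envelope over abundance (running max from the top)
    filled = dispersion.copy()
    valid = ~np.isnan(filled)
    smoothed = filled.copy()
    running = -np.inf
    for b in range(n_bins - 1, -1, -1):
        if valid[b]:
            running = max(running, filled[b])
            smoothed[b] = running
    passing = [b for b in range(n_bins) if valid[b] and smoothed[b] <= dispersion_threshold]
    if not passing:
        raise TableError(
            "no abundance bin meets the dispersion threshold "
            f"{dispersion_threshold}; raise the threshold or add replicates"
        )
    cutoff = float(centers[min(passing)])
    return CutoffReport(centers, dispersion, smoothed, cutoff, dispersion_threshold, len(group_map))


def apply_cutoff(
    rel_table: RelativeAbundanceTable, cutoff: float = 0.01
) -> tuple[RelativeAbundanceTable, int]:
    """Retain taxa whose median relative abundance is at least ``cutoff``.

    Returns the filtered table and ``m_total``, the pre-filter taxon count:
    the FDR correction downstream must account for every taxon that existed
    before the reliability filter, not only those it retained.
    """
    if not 0 <= cutoff <= 1:
        raise TableError("cutoff must lie in [0, 1]")
    m_total = rel_table.fractions.shape[0]
    medians = rel_table.fractions.median(axis=1)
    keep = medians[medians >= cutoff].index
    if len(keep) == 0:
        kept = rel_table.fractions.iloc[:0]
    else:
        kept = rel_table.fractions.loc[keep]
    # re-closure is NOT applied: retained fractions keep their original scale
    out = RelativeAbundanceTable.__new__(RelativeAbundanceTable)
    out.fractions = kept
    out.lineage = rel_table.lineage.reindex(kept.index)
    out.rarefaction_depth = rel_table.rarefaction_depth
    return out, m_total
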