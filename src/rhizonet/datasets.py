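"""Core tables (abundance, taxonomy, sample metadata) and their filters.

All tables are thin wrappers around pandas DataFrames read from tab-delimited
text. The abundance table is kept in a canonical samples x taxa orientation
with non-negative integer counts; relative abundances are derived on demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rhizonet.errors import EmptyResultError, ParseError, ValidationError

logger = logging.getLogger(__name__)

DOMESTICATION_LEVELS = ("wild", "traditional", "modern")
FERTILIZATION_LEVELS = ("unfertilized", "fertilized")
UNCLASSIFIED = "Unclassified"


@dataclass(frozen=True)
class FilterConfig:
    """Sample- and taxon-level filtering thresholds.

    ``min_reads`` retains samples with read depth >= the value (inclusive);
    ``min_mean_rel_abund`` retains taxa whose mean relative abundance across
    the retained samples is >= the value (inclusive).
    """

    min_reads: int = 10_000
    min_mean_rel_abund: float = 0.001

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValidationError("min_reads must be >= 0")
        if not (0.0 <= self.min_mean_rel_abund < 1.0):
            raise ValidationError("min_mean_rel_abund must be in [0, 1)")


class AbundanceTable:
    """Samples x taxa matrix of non-negative integer counts."""

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if values.size and (values < 0).any():
            raise ValidationError("counts must be non-negative")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValidationError("counts must be integers")
        self._counts = counts.astype(np.int64)

    @property
    def counts(self) -> pd.DataFrame:
        return self._counts

    @property
    def sample_ids(self) -> list[str]:
        return list(self._counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self._counts.columns)

    @property
    def n_samples(self) -> int:
        return self._counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self._counts.shape[1]

    @property
    def read_depths(self) -> pd.Series:
        """Per-sample total read count (row sums)."""
        return self._counts.sum(axis=1)

    def to_relative(self) -> pd.DataFrame:
        """Per-sample relative abundances; rows sum to 1.

        Raises if any sample has zero depth, naming the offender.
        """
        depths = self.read_depths
        zero = depths[depths == 0]
        if len(zero):
            raise ValidationError(
                f"cannot normalize zero-depth sample(s): {list(zero.index)}"
            )
        return self._counts.div(depths, axis=0)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self._counts.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return AbundanceTable(self._counts.loc[list(sample_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, AbundanceTable) and self._counts.equals(other._counts)

    def __repr__(self) -> str:
        return f"AbundanceTable({self.n_samples} samples x {self.n_taxa} taxa)"


class TaxonomyTable:
    """Taxon lineages; at minimum a phylum label per taxon.

    Missing or empty phylum entries fall back to ``Unclassified``.
    """

    def __init__(self, lineage: pd.DataFrame):
        if "phylum" not in lineage.columns:
            raise ValidationError("taxonomy table requires a 'phylum' column")
        if lineage.index.has_duplicates:
            raise ValidationError("duplicate taxon ids in taxonomy table")
        lineage = lineage.copy()
        phylum = lineage["phylum"].astype("object")
        phylum = phylum.where(phylum.notna() & (phylum != ""), UNCLASSIFIED)
        lineage["phylum"] = phylum
        self._lineage = lineage

    @property
    def lineage(self) -> pd.DataFrame:
        return self._lineage

    def phylum_of(self, taxon_id: str) -> str:
        if taxon_id in self._lineage.index:
            return str(self._lineage.loc[taxon_id, "phylum"])
        return UNCLASSIFIED

    def phyla(self, taxon_ids) -> pd.Series:
        return pd.Series({t: self.phylum_of(t) for t in taxon_ids}, name="phylum")


class SampleMetadata:
    """Sample design factors: domestication group x fertilization."""

    def __init__(self, frame: pd.DataFrame):
        required = {"domestication_group", "fertilization"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if frame.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        bad_group = set(frame["domestication_group"]) - set(DOMESTICATION_LEVELS)
        if bad_group:
            raise ValidationError(
                f"unknown domestication_group level(s): {sorted(bad_group)}"
            )
        bad_fert = set(frame["fertilization"]) - set(FERTILIZATION_LEVELS)
        if bad_fert:
            raise ValidationError(f"unknown fertilization level(s): {sorted(bad_fert)}")
        self._frame = frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def samples_where(self, group: str | None = None, fertilization: str | None = None):
        """Sample ids matching the given factor levels (None = any)."""
        mask = pd.Series(True, index=self._frame.index)
        if group is not None:
            mask &= self._frame["domestication_group"] == group
        if fertilization is not None:
            mask &= self._frame["fertilization"] == fertilization
        return list(self._frame.index[mask])

    def require(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self._frame.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")


# ---------------------------------------------------------------------------
# I/O


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # pandas silently renames duplicate header fields; check them ourselves
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    body = header[1:]
    if len(set(body)) != len(body):
        dups = sorted({h for h in body if body.count(h) > 1})
        raise ValidationError(f"duplicate taxon ids: {dups} in {path}")
    return pd.read_csv(path, sep="\t", index_col=0, compression="infer")


def read_abundance(path, orientation: str = "samples-as-rows") -> AbundanceTable:
    """Read a TSV count table into canonical samples x taxa orientation."""
    if orientation not in ("samples-as-rows", "taxa-as-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    frame = _read_tsv(path)
    try:
        frame = frame.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        # locate the first offending cell for a useful message
        for col in frame.columns:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna()
            if bad.any():
                row = frame.index[bad.argmax()]
                raise ParseError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}"
                ) from exc
        raise ParseError(f"non-numeric data in {path}") from exc
    if orientation == "taxa-as-rows":
        frame = frame.T
    table = AbundanceTable(frame)
    logger.info("read %s: %d samples x %d taxa", path, table.n_samples, table.n_taxa)
    return table


def write_abundance(table: AbundanceTable, path) -> None:
    table.counts.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    return TaxonomyTable(_read_tsv(path))


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(_read_tsv(path))


def read_gene_presence(path) -> pd.DataFrame:
    """Taxon x EC table of predicted gene copy numbers (or 0/1 indicators)."""
    frame = _read_tsv(path).apply(pd.to_numeric)
    if (frame.to_numpy() < 0).any():
        raise ValidationError("gene-presence values must be non-negative")
    return frame


# ---------------------------------------------------------------------------
# Filters


def filter_samples(table: AbundanceTable, cfg: FilterConfig) -> AbundanceTable:
    """Retain samples with read depth >= cfg.min_reads, preserving order."""
    depths = table.read_depths
    keep = depths.index[depths >= cfg.min_reads]
    if len(keep) == 0:
        raise EmptyResultError(
            f"all {table.n_samples} samples fall below min_reads={cfg.min_reads}"
        )
    if len(keep) < table.n_samples:
        logger.info(
            "filter_samples: retained %d/%d samples (min_reads=%d)",
            len(keep), table.n_samples, cfg.min_reads,
        )
    return AbundanceTable(table.counts.loc[keep])


def filter_taxa(table: AbundanceTable, cfg: FilterConfig) -> AbundanceTable:
    """Retain taxa whose mean relative abundance >= cfg.min_mean_rel_abund.

    Relative abundances are computed against full per-sample depths, so
    dropping taxa does not renormalize the survivors.
    """
    if table.n_samples == 0 or table.n_taxa == 0:
        raise EmptyResultError("cannot filter an empty table")
    mean_rel = table.to_relative().mean(axis=0)
    keep = mean_rel.index[mean_rel >= cfg.min_mean_rel_abund]
    if len(keep) == 0:
        raise EmptyResultError(
            f"all {table.n_taxa} taxa fall below "
            f"min_mean_rel_abund={cfg.min_mean_rel_abund}"
        )
    if len(keep) < table.n_taxa:
        logger.info(
            "filter_taxa: retained %d/%d taxa (min_mean_rel_abund=%g)",
            len(keep), table.n_taxa, cfg.min_mean_rel_abund,
        )
    return AbundanceTable(table.counts[keep])
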