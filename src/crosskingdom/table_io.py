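"""Abundance-table I/O, validation, filtering, and cross-kingdom alignment.

Internal orientation is samples x taxa (statistics are per-sample-row); the
on-disk TSV convention is the common amplicon layout of taxa rows by sample
columns, transposed at the boundary.  BIOM support targets the v1.0 JSON
dialect so tables stay plain text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class TableValidationError(ValueError):
    """Raised when an abundance table violates its structural invariants."""


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a QIIME-style rank-prefixed lineage string into {rank: name}.

    Unassigned ranks (empty after the prefix) are preserved as ''.
    """
    out: dict[str, str] = {}
    for part in lineage.split(";"):
        part = part.strip()
        for prefix, rank in zip(_RANK_PREFIXES, _RANK_NAMES):
            if part.startswith(prefix):
                out[rank] = part[len(prefix):]
                break
    return out


@dataclass(frozen=True)
class AbundanceTable:
    """Samples x taxa abundance matrix for one kingdom.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative abundances; index = sample ids, columns = taxon ids.
    kingdom : str
        ``"bacteria"`` or ``"fungi"``.
    taxonomy : dict, optional
        Taxon id -> rank-prefixed lineage string.
    """

    data: pd.DataFrame
    kingdom: str
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kingdom not in ("bacteria", "fungi"):
            raise TableValidationError(f"unknown kingdom {self.kingdom!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(set(idx[idx.duplicated()]))
            raise TableValidationError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(set(cols[cols.duplicated()]))
            raise TableValidationError(f"duplicate taxon ids: {dups}")
        values = self.data.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                bad = np.argwhere(~np.vectorize(_is_number)(values))
                r, c = bad[0]
                raise TableValidationError(
                    f"non-numeric value at sample {idx[r]!r}, taxon {cols[c]!r}"
                )
            if not np.isfinite(values).all():
                r, c = np.argwhere(~np.isfinite(values))[0]
                raise TableValidationError(
                    f"non-finite value at sample {idx[r]!r}, taxon {cols[c]!r}"
                )
            if (values < 0).any():
                r, c = np.argwhere(values < 0)[0]
                raise TableValidationError(
                    f"negative value {values[r, c]} at sample {idx[r]!r}, taxon {cols[c]!r}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select_samples(self, sample_ids) -> "AbundanceTable":
        return replace(self, data=self.data.loc[list(sample_ids)])

    def select_taxa(self, taxon_ids) -> "AbundanceTable":
        keep = list(taxon_ids)
        taxonomy = {t: self.taxonomy[t] for t in keep if t in self.taxonomy}
        return replace(self, data=self.data[keep], taxonomy=taxonomy)

    def collapse_rank(self, rank: str) -> "AbundanceTable":
        """Sum counts within identical names at ``rank`` of the lineage.

        Taxa with an unassigned name at the rank are grouped under
        ``unassigned_<rank>``.
        """
        if rank not in _RANK_NAMES:
            raise ValueError(f"unknown rank {rank!r}; expected one of {_RANK_NAMES}")
        groups: dict[str, list[str]] = {}
        for taxon in self.taxon_ids:
            name = parse_lineage(self.taxonomy.get(taxon, "")).get(rank, "")
            label = name if name else f"unassigned_{rank}"
            groups.setdefault(label, []).append(taxon)
        collapsed = pd.DataFrame(
            {label: self.data[cols].sum(axis=1) for label, cols in groups.items()}
        )
        return AbundanceTable(collapsed, self.kingdom)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample metadata with a two-level primary group factor."""

    frame: pd.DataFrame
    group_column: str = "group"

    def __post_init__(self) -> None:
        if self.group_column not in self.frame.columns:
            raise TableValidationError(f"metadata lacks column {self.group_column!r}")
        if self.frame.index.has_duplicates:
            dups = sorted(set(self.frame.index[self.frame.index.duplicated()]))
            raise TableValidationError(f"duplicate sample ids in metadata: {dups}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def groups(self) -> pd.Series:
        return self.frame[self.group_column]

    def group_levels(self) -> list[str]:
        return sorted(self.groups.unique())

    def validate_two_groups(self) -> None:
        levels = self.group_levels()
        if len(levels) != 2:
            raise TableValidationError(
                f"expected exactly two group levels, found {levels}"
            )

    def select_samples(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)], self.group_column)


# -- readers / writers ---------------------------------------------------------

def read_table(path, format: str = "tsv", kingdom: str = "bacteria",
               taxonomy_path=None) -> AbundanceTable:
    """Read an abundance table (taxa rows x sample columns on disk).

    ``format`` is ``"tsv"`` or ``"biom"`` (BIOM v1.0 JSON).
    """
    if format == "tsv":
        # pandas mangles duplicate headers on read, so check the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            dups = sorted({h for h in header if header.count(h) > 1})
            raise TableValidationError(f"duplicate sample columns in {path}: {dups}")
        raw = pd.read_csv(path, sep="\t", index_col=0)
        if raw.index.has_duplicates:
            dups = sorted(set(raw.index[raw.index.duplicated()]))
            raise TableValidationError(f"duplicate taxon rows in {path}: {dups}")
        data = raw.T
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
    elif format == "biom":
        data = _read_biom_json(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else {}
    return AbundanceTable(data, kingdom, taxonomy)


def write_table(table: AbundanceTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        out = table.data.T
        out.index.name = "taxon"
        out.to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_biom_json(path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    return pd.DataFrame(mat.T, index=samples, columns=taxa)


def _write_biom_json(table: AbundanceTable, path) -> None:
    mat = table.counts().T  # taxa x samples
    rows, cols = np.nonzero(mat)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "crosskingdom",
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": [int(mat.shape[0]), int(mat.shape[1])],
        "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": [[int(r), int(c), float(mat[r, c])] for r, c in zip(rows, cols)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_taxonomy(path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", index_col=0, header=0)
    return dict(zip(frame.index.astype(str), frame.iloc[:, 0].astype(str)))


def write_taxonomy(taxonomy: dict[str, str], path) -> None:
    frame = pd.DataFrame({"lineage": pd.Series(taxonomy)})
    frame.index.name = "taxon"
    frame.to_csv(path, sep="\t")


def read_metadata(path, group_column: str = "group") -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return SampleMetadata(frame, group_column)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# -- transformations and filters ----------------------------------------------

def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample proportions (each row sums to 1)."""
    totals = table.data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise TableValidationError(
            f"zero-sum samples cannot be normalized: {list(zero.index)}"
        )
    return replace(table, data=table.data.div(totals, axis=0))


def filter_major_genera(table: AbundanceTable, threshold: float = 0.01) -> AbundanceTable:
    """Keep taxa whose mean relative abundance across samples is >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    props = relative_abundance(table)
    # inclusive boundary, robust to summation round-off at exactly-threshold
    keep = props.data.mean(axis=0) >= threshold - 1e-12
    return table.select_taxa(props.data.columns[keep])


def filter_prevalence(table: AbundanceTable, min_fraction: float) -> AbundanceTable:
    """Keep taxa detected (count > 0) in strictly more than ``min_fraction``
    of samples."""
    if not 0 < min_fraction < 1:
        raise ValueError(f"min_fraction must be in (0, 1), got {min_fraction}")
    prevalence = (table.data > 0).mean(axis=0)
    keep = prevalence > min_fraction
    if not keep.any():
        logger.warning(
            "prevalence filter at %.2f removed all %d taxa", min_fraction, table.n_taxa
        )
    return table.select_taxa(table.data.columns[keep])


def align_kingdoms(bact: AbundanceTable, fungi: AbundanceTable,
                   meta: SampleMetadata) -> tuple[AbundanceTable, AbundanceTable, SampleMetadata]:
    """Restrict both tables and the metadata to their common samples.

    Common samples keep the bacterial table's order; extras are dropped with
    a log message.
    """
    common = [s for s in bact.sample_ids
              if s in set(fungi.sample_ids) and s in set(meta.sample_ids)]
    if not common:
        raise TableValidationError("no samples shared by both tables and metadata")
    for name, obj in (("bacterial", bact), ("fungal", fungi), ("metadata", meta)):
        dropped = set(obj.sample_ids) - set(common)
        if dropped:
            logger.info("align_kingdoms: dropping %d %s-only samples: %s",
                        len(dropped), name, sorted(dropped))
    return (bact.select_samples(common), fungi.select_samples(common),
            meta.select_samples(common))
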