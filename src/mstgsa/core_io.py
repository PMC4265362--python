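"""Input/output and the core containers for count-based gene set analysis.

The toolkit works on plain tab-separated text: an integer gene-by-sample
count matrix, a two-column gene-length table, a two-column phenotype label
table, and gene set collections in the GMT format used by MSigDB.  Samples
are always columns; all downstream geometry treats the samples of a gene
set as points in R^p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mstgsa")

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "PhenotypeLabels",
    "read_counts",
    "read_gmt",
    "read_labels",
    "filter_gene_sets",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Integer gene-by-sample read counts with per-gene lengths.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows).
    counts
        Non-negative integer matrix of shape ``(n_genes, n_samples)``.
    sample_ids
        Ordered, unique sample identifiers (columns).
    gene_lengths
        Gene lengths in base pairs, aligned with ``gene_ids``; all positive.

    ``library_sizes`` (per-sample total mapped counts) is always derived as
    the column sums of ``counts``.
    """

    gene_ids: np.ndarray
    counts: np.ndarray
    sample_ids: np.ndarray
    gene_lengths: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValueError("sample_ids length does not match counts columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if len(self.gene_lengths) != self.counts.shape[0]:
            raise ValueError("gene_lengths length does not match counts rows")
        if np.any(self.gene_lengths <= 0):
            raise ValueError("gene lengths must be positive")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with optional per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate gene IDs within set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.sets.items()}


@dataclass
class PhenotypeLabels:
    """Assignment of each sample to one of exactly two phenotype groups.

    The first group (in sorted label order, or the order given via
    ``group_order``) plays the role of X with n1 members; the second is Y
    with n2 members.
    """

    sample_ids: np.ndarray
    labels: np.ndarray
    group_order: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels must have equal length")
        uniq = sorted(set(self.labels))
        if len(uniq) != 2:
            raise ValueError(f"exactly two distinct labels required, got {uniq}")
        if self.group_order is None:
            self.group_order = (uniq[0], uniq[1])
        elif sorted(self.group_order) != uniq:
            raise ValueError("group_order does not match the labels present")

    @property
    def x_mask(self) -> np.ndarray:
        """Boolean mask selecting the first group's samples."""
        return self.labels == self.group_order[0]

    @property
    def n1(self) -> int:
        return int(self.x_mask.sum())

    @property
    def n2(self) -> int:
        return int(len(self.labels) - self.n1)

    @property
    def n(self) -> int:
        return len(self.labels)

    def require_testable(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError(
                f"each group needs at least 2 samples (n1={self.n1}, n2={self.n2})"
            )


# ---------------------------------------------------------------------------
# readers


def read_counts(path: str, lengths_path: str) -> CountMatrix:
    """Read a count TSV and a gene-length TSV into a :class:`CountMatrix`.

    The count file has a header row of sample IDs and gene IDs in the first
    column; all remaining cells must be non-negative integers.  The length
    file maps gene ID to length in base pairs (optional header).  A gene
    present in the counts but missing from the length table is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = df.index.to_numpy(dtype=object)
    samples = df.columns.to_numpy(dtype=object)
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"malformed count {cell!r} at gene {genes[i]!r}, sample {col!r}"
                ) from None
            if value < 0:
                raise ValueError(
                    f"negative count {value} at gene {genes[i]!r}, sample {col!r}"
                )
            counts[i, j] = value

    lengths = _read_lengths(lengths_path)
    missing = [g for g in genes if g not in lengths]
    if missing:
        raise KeyError(f"gene length missing for: {', '.join(map(repr, missing[:10]))}")
    gene_lengths = np.array([lengths[g] for g in genes], dtype=np.int64)
    return CountMatrix(genes, counts, samples, gene_lengths)


def _read_lengths(path: str) -> dict[str, int]:
    table = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: gene length table needs two columns")
    # tolerate an optional header line
    rows = table.itertuples(index=False)
    out: dict[str, int] = {}
    for k, row in enumerate(rows):
        gene, value = str(row[0]), str(row[1])
        try:
            length = int(value)
        except ValueError:
            if k == 0:
                continue  # header
            raise ValueError(f"{path}: malformed length {value!r} for {gene!r}") from None
        if length <= 0:
            raise ValueError(f"{path}: non-positive length {length} for {gene!r}")
        out[gene] = length
    return out


def read_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within one line are dropped (first occurrence kept) with
    a logged warning; duplicate set names are an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            dupes = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dupes += 1
                    continue
                seen.add(g)
                genes.append(g)
            if dupes:
                logger.warning(
                    "%s:%d: set %r contains %d duplicated gene ID(s); deduplicated",
                    path, lineno, name, dupes,
                )
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def read_labels(path: str) -> PhenotypeLabels:
    """Read a two-column TSV of (sample ID, group label)."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: label table needs two columns")
    return PhenotypeLabels(
        table.iloc[:, 0].to_numpy(dtype=object),
        table.iloc[:, 1].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# gene set filtering


def filter_gene_sets(
    sets: GeneSetCollection,
    measured: list[str] | np.ndarray,
    min_size: int = 10,
    max_size: int = 500,
) -> GeneSetCollection:
    """Restrict sets to measured genes, then apply the size window.

    Each set is first intersected with the measured gene universe (genes not
    present in the data are discarded), and only then retained if its
    remaining size p satisfies ``min_size <= p <= max_size`` (defaults 10 and
    500, both inclusive).  The operation is idempotent.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    universe = set(measured)
    kept: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for name, genes in sets.sets.items():
        present = [g for g in genes if g in universe]
        if min_size <= len(present) <= max_size:
            kept[name] = present
            if name in sets.descriptions:
                descriptions[name] = sets.descriptions[name]
    return GeneSetCollection(kept, descriptions)


# ---------------------------------------------------------------------------
# results table

RESULT_COLUMNS = [
    "set", "size", "statistic", "pvalue",
    "method", "normalization", "n_permutations", "seed",
]


def write_results(results: pd.DataFrame, path: str) -> None:
    """Write a per-set results table as TSV with a stable column order.

    Row order is preserved from the input, so re-running on the same input
    produces a byte-identical file.
    """
    df = pd.DataFrame(results)
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[RESULT_COLUMNS + [c for c in df.columns if c not in RESULT_COLUMNS]]
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
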