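"""Count-matrix, group-vector and batch-metadata I/O.

The universal input is a gene x sample read-count matrix as delimited text:
a header row of sample names and a first column of gene identifiers (the
``read.csv(..., header=T, row.names=1)`` convention).  Batch metadata
(machine / run / flowcell / lane) is parsed from Illumina read names taken
from FASTQ or BAM files; the core only ever sees an iterator of read-name
strings, so BAM support is a thin adapter.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GroupAssignment",
    "BatchAnnotation",
    "read_count_matrix",
    "write_count_matrix",
    "parse_group_vector",
    "parse_read_name",
    "extract_batch_info",
    "read_names_from_fastq",
    "read_names_from_bam",
    "write_result_table",
]


@dataclass(frozen=True)
class CountMatrix:
    """Nonnegative integer gene x sample table.

    ``data`` holds genes on the index and samples on the columns, in input
    order.  Construction validates the invariants: integral nonnegative
    counts, unique gene and sample identifiers, at least 2 of each.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValueError(
                f"count matrix needs >= 2 genes and >= 2 samples, got {df.shape}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("count matrix contains non-numeric values")
        bad = (values < 0) | (values != np.floor(values)) | ~np.isfinite(values)
        if bad.any():
            rows, cols = np.nonzero(bad)
            offenders = [
                f"(gene {df.index[r]!r}, sample {df.columns[c]!r}) = {values[r, c]}"
                for r, c in zip(rows[:5], cols[:5])
            ]
            raise ValueError(
                "counts must be nonnegative integers; offending cells: "
                + "; ".join(offenders)
            )
        object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[list(gene_ids)])


@dataclass(frozen=True)
class GroupAssignment:
    """Per-sample binary phenotype labels (0 = reference, 1 = comparison)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if not np.isin(labels, (0, 1)).all():
            bad = sorted(set(labels.tolist()) - {0, 1})
            raise ValueError(f"group labels must be 0 or 1, got {bad}")
        if len(set(labels.tolist())) < 2:
            raise ValueError("both groups must be present in the group vector")
        for g in (0, 1):
            n = int((labels == g).sum())
            if n < 2:
                raise ValueError(f"group {g} has {n} sample(s); >= 2 required")
            if n < 3:
                warnings.warn(
                    f"group {g} has only {n} samples; at least 3 per group "
                    "is recommended for stable dispersion estimation",
                    UserWarning,
                    stacklevel=2,
                )
        object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def indices(self, group: int) -> np.ndarray:
        return np.nonzero(self.labels == group)[0]

    def swapped(self) -> "GroupAssignment":
        return GroupAssignment(1 - self.labels)


@dataclass
class BatchAnnotation:
    """Per-sample sequencing batch labels parsed from read names.

    Each mapping goes sample id -> label; samples whose read names could not
    be parsed are simply absent from the per-factor mapping.
    """

    machine_name: dict[str, str] = field(default_factory=dict)
    run_id: dict[str, str] = field(default_factory=dict)
    flowcell_id: dict[str, str] = field(default_factory=dict)
    lane_id: dict[str, str] = field(default_factory=dict)

    FACTORS = ("machine_name", "run_id", "flowcell_id", "lane_id")

    def factor(self, name: str) -> dict[str, str]:
        if name not in self.FACTORS:
            raise KeyError(f"unknown batch factor {name!r}")
        return getattr(self, name)

    def validate_against(self, counts: CountMatrix) -> None:
        known = set(counts.sample_ids)
        for name in self.FACTORS:
            unknown = set(self.factor(name)) - known
            if unknown:
                raise ValueError(
                    f"batch factor {name}: sample ids not in count matrix: "
                    f"{sorted(unknown)}"
                )


def _sniff_delimiter(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_count_matrix(path: str | Path, delimiter: str | None = None) -> CountMatrix:
    """Read a delimited count matrix (header of sample names, first column
    of gene identifiers).

    The delimiter is auto-detected between comma and tab from the header
    line unless given explicitly.
    """
    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            delimiter = _sniff_delimiter(fh.readline())
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene identifiers {dups}")
    for col in df.columns:
        nonnum = pd.to_numeric(df[col], errors="coerce")
        bad = nonnum.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-numeric count at gene {gene!r}, sample {col!r}"
            )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_count_matrix(counts: CountMatrix, path: str | Path, delimiter: str = ",") -> None:
    counts.data.to_csv(path, sep=delimiter, index_label="gene")


def parse_group_vector(spec: str | Path, n_samples: int) -> GroupAssignment:
    """Parse a comma-separated 0/1 string (or a file holding one).

    ``n_samples`` is the number of samples in the count matrix the vector
    must align with.
    """
    text = str(spec)
    p = Path(text)
    if ("," not in text and not set(text) <= {"0", "1"}) and p.is_file():
        text = p.read_text()
    tokens = [t.strip() for t in text.replace("\n", ",").split(",") if t.strip()]
    if len(tokens) != n_samples:
        raise ValueError(
            f"group vector has {len(tokens)} entries but the matrix has "
            f"{n_samples} samples"
        )
    bad = [t for t in tokens if t not in ("0", "1")]
    if bad:
        raise ValueError(f"group labels must be 0 or 1, got {bad}")
    return GroupAssignment(np.array([int(t) for t in tokens]))


def parse_read_name(name: str) -> dict[str, str]:
    """Parse one Illumina read name into batch fields.

    Accepts the Casava >= 1.8 convention
    ``instrument:run:flowcell:lane:tile:x:y`` and falls back to the pre-1.8
    ``instrument:lane:tile:x:y`` layout when fewer colon fields are present.
    A leading ``@`` is tolerated and everything after the first whitespace is
    ignored (FASTQ vs BAM query-name dialects).  Unparseable names yield an
    empty dict.
    """
    name = name.strip().split()[0] if name.strip() else ""
    if name.startswith("@"):
        name = name[1:]
    fields = name.split(":")
    if len(fields) >= 7:
        return {
            "machine_name": fields[0],
            "run_id": fields[1],
            "flowcell_id": fields[2],
            "lane_id": fields[3],
        }
    if len(fields) == 5:
        return {"machine_name": fields[0], "lane_id": fields[1]}
    return {}


def extract_batch_info(
    read_name_streams: Mapping[str, Iterable[str]],
) -> BatchAnnotation:
    """Build a :class:`BatchAnnotation` from per-sample read-name iterables.

    The first parseable read name defines the sample's batch; later names
    that disagree are logged, never fatal.  Samples whose stream is empty or
    entirely unparseable get all fields absent plus a warning.
    """
    ann = BatchAnnotation()
    for sample, stream in read_name_streams.items():
        first: dict[str, str] | None = None
        for raw in stream:
            parsed = parse_read_name(raw)
            if not parsed:
                continue
            if first is None:
                first = parsed
                for key, value in parsed.items():
                    ann.factor(key)[sample] = value
            elif parsed != first:
                logger.warning(
                    "sample %s: read name %r disagrees with the first "
                    "parseable name; keeping the first",
                    sample,
                    raw,
                )
                break
        if first is None:
            warnings.warn(
                f"sample {sample}: no parseable read names; batch fields "
                "recorded as absent",
                UserWarning,
                stacklevel=2,
            )
    return ann


def read_names_from_fastq(path: str | Path, limit: int = 100) -> Iterator[str]:
    """Yield up to ``limit`` read names from a FASTQ file (plain or gzip)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i // 4 >= limit:
                break
            if i % 4 == 0:
                yield line.rstrip("\n")


def read_names_from_bam(path: str | Path, limit: int = 100) -> Iterator[str]:
    """Yield up to ``limit`` query names from a BAM/SAM file (needs pysam)."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for i, read in enumerate(bam.fetch(until_eof=True)):
            if i >= limit:
                break
            yield read.query_name


def write_result_table(rank_table, method_results, path: str | Path) -> None:
    """Write the final tabular report.

    One row per gene: gene id; per engine log2FC (empty where the engine
    reports none), raw score, FDR-adjusted score, rank; final column the
    rank sum.  Rows sorted ascending by rank sum (ties by gene id).
    """
    genes = list(rank_table.gene_ids)
    gene_set = set(genes)
    for res in method_results:
        if set(res.gene_ids) != gene_set:
            raise ValueError(
                f"gene set of method {res.method_name!r} does not match the "
                "rank table"
            )
    frame = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for res in method_results:
        m = res.method_name
        per_gene = res.table.reindex(genes)
        if res.has_fold_change:
            frame[f"{m}_log2fc"] = per_gene["log2_fold_change"]
        else:
            frame[f"{m}_log2fc"] = ""
        frame[f"{m}_raw"] = per_gene["raw_score"]
        frame[f"{m}_fdr"] = per_gene["fdr_score"]
        frame[f"{m}_rank"] = rank_table.ranks[m].reindex(genes)
    frame["rank_sum"] = rank_table.rank_sums.reindex(genes)
    frame = frame.sort_index(kind="mergesort").sort_values(
        "rank_sum", kind="mergesort"
    )
    frame.to_csv(path, sep="\t", float_format="%.6g")
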