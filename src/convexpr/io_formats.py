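"""Readers and writers for every on-disk format the pipeline touches.

All formats are plain TSV. Count matrices are per-species files; gene tables
are BED-like with 0-based half-open coordinates; hit tables follow the
12-column BLAST tabular ("outfmt 6") dialect; CpG reports are a bismark-style
cytosine-report subset with 1-based positions; term maps are GMT-like.

Coordinate conventions are converted exactly once, at read time: gene tables
stay 0-based half-open, CpG report positions stay 1-based (downstream code
converts when intersecting with promoter intervals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GeneRecord",
    "HitRecord",
    "CpGRecord",
    "TermMap",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_table",
    "write_gene_table",
    "read_hit_table",
    "write_hit_table",
    "read_cpg_report",
    "write_cpg_report",
    "read_term_map",
    "write_term_map",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer gene x sample counts for one species and tissue."""

    species: str
    tissue: str
    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (genes, samples), integer, >= 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError(f"duplicate gene IDs in {self.species}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError(f"duplicate sample IDs in {self.species}")
        if len(self.sample_ids) < 2:
            raise ValidationError(
                f"species {self.species} needs at least 2 biological replicates, "
                f"got {len(self.sample_ids)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.sample_ids),
        )


@dataclass(frozen=True)
class GeneRecord:
    """One isoform of one gene, BED-like 0-based half-open coordinates."""

    gene_id: str
    isoform_id: str
    chrom: str
    start: int
    end: int
    strand: str
    protein_length: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"{self.gene_id}/{self.isoform_id}: start {self.start} >= end {self.end}"
            )
        if self.start < 0:
            raise ValidationError(f"{self.gene_id}: negative start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.gene_id}/{self.isoform_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if self.protein_length < 1:
            raise ValidationError(
                f"{self.gene_id}/{self.isoform_id}: protein_length must be >= 1"
            )

    @property
    def length(self) -> int:
        """Genomic span in bp (end - start)."""
        return self.end - self.start


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column BLAST tabular hit table."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: evalue < 0")
        if self.bit_score < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: bit_score < 0")


@dataclass(frozen=True)
class CpGRecord:
    """Per-cytosine methylated / unmethylated read counts, 1-based position."""

    sample_id: str
    chrom: str
    position: int
    strand: str
    count_methylated: int
    count_unmethylated: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"CpG position must be >= 1, got {self.position}")
        if self.count_methylated < 0 or self.count_unmethylated < 0:
            raise ValidationError(
                f"negative read count at {self.chrom}:{self.position}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"CpG strand must be '+' or '-', got {self.strand!r}")


@dataclass
class TermMap:
    """Term id -> member gene ids, GMT-like."""

    terms: dict[str, set[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def add(self, term_id: str, term_name: str, members: set[str]) -> None:
        if term_id in self.terms:
            raise ValidationError(f"duplicate term_id {term_id}")
        if not members:
            raise ValidationError(f"term {term_id} has no members")
        self.terms[term_id] = set(members)
        self.names[term_id] = term_name

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(path, species: str, tissue: str) -> CountMatrix:
    """Read a TSV count matrix (first column gene IDs, header sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                values[i, j] = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {raw!r} at gene "
                    f"{df.index[i]!r}, sample {col!r}"
                ) from None
    return CountMatrix(
        species=species,
        tissue=tissue,
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=values,
    )


def write_count_matrix(matrix: CountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["gene_id", "isoform_id", "chrom", "start", "end", "strand", "protein_length"]


def read_gene_table(path) -> list[GeneRecord]:
    """Read a BED-like gene/isoform table (0-based half-open coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _GENE_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {_GENE_COLUMNS}, got {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        try:
            start, end, plen = int(row.start), int(row.end), int(row.protein_length)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer coordinate: {exc}") from None
        records.append(
            GeneRecord(
                gene_id=row.gene_id,
                isoform_id=row.isoform_id,
                chrom=row.chrom,
                start=start,
                end=end,
                strand=row.strand,
                protein_length=plen,
            )
        )
    return records


def write_gene_table(records: list[GeneRecord], path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=_GENE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def read_hit_table(path, evalue_cutoff: float = 1e-5) -> list[HitRecord]:
    """Read a 12-column BLAST tabular file, keeping hits with evalue <= cutoff."""
    records: list[HitRecord] = []
    n_total = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            n_total += 1
            try:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if rec.evalue <= evalue_cutoff:
                records.append(rec)
    if n_total == 0:
        logger.warning("%s: empty hit table", path)
    logger.info(
        "%s: retained %d/%d hits at E-value cutoff %g",
        path, len(records), n_total, evalue_cutoff,
    )
    return records


def write_hit_table(records: list[HitRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.percent_identity:.2f}\t"
                f"{r.alignment_length}\t{r.mismatches}\t{r.gap_opens}\t"
                f"{r.q_start}\t{r.q_end}\t{r.s_start}\t{r.s_end}\t"
                f"{r.evalue:.3g}\t{r.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# CpG reports
# ---------------------------------------------------------------------------

_CPG_COLUMNS = ["chrom", "position", "strand", "count_methylated", "count_unmethylated"]


def read_cpg_report(path, sample_id: str) -> list[CpGRecord]:
    """Read a bismark-style cytosine report subset (5 columns, 1-based)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _CPG_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {_CPG_COLUMNS}, got {list(df.columns)}"
        )
    records = []
    seen: set[tuple[str, int, str]] = set()
    for row in df.itertuples(index=False):
        try:
            pos = int(row.position)
            m = int(row.count_methylated)
            u = int(row.count_unmethylated)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer field: {exc}") from None
        key = (row.chrom, pos, row.strand)
        if key in seen:
            raise ValidationError(
                f"{path}: duplicate cytosine {row.chrom}:{pos}({row.strand}) "
                f"for sample {sample_id}"
            )
        seen.add(key)
        records.append(
            CpGRecord(
                sample_id=sample_id,
                chrom=row.chrom,
                position=pos,
                strand=row.strand,
                count_methylated=m,
                count_unmethylated=u,
            )
        )
    return records


def write_cpg_report(records: list[CpGRecord], path) -> None:
    df = pd.DataFrame(
        [
            (r.chrom, r.position, r.strand, r.count_methylated, r.count_unmethylated)
            for r in records
        ],
        columns=_CPG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# term maps
# ---------------------------------------------------------------------------

def read_term_map(path) -> TermMap:
    """Read a GMT-like TSV: term_id, term_name, then one member per column."""
    tm = TermMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: need term_id, term_name and >= 1 member"
                )
            members = {f for f in fields[2:] if f}
            if not members:
                raise ValidationError(f"{path}:{lineno}: term {fields[0]} empty")
            tm.add(fields[0], fields[1], members)
    return tm


def write_term_map(term_map: TermMap, path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(term_map.terms):
            members = "\t".join(sorted(term_map.terms[term_id]))
            fh.write(f"{term_id}\t{term_map.names[term_id]}\t{members}\n")
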