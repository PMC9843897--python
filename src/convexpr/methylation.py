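"""Promoter methylation: strand-aware 1 kb promoters, coverage-filtered
promoter methylation levels and two-group differential methylation.

The promoter of a gene spans the 1,000 bp upstream of its transcription
start site. In 0-based half-open coordinates: on the + strand the TSS is
``start`` and the promoter is [start - 1000, start), clipped at 0; on the
- strand the TSS is ``end - 1`` and the promoter is [end, end + 1000).

A CpG passes coverage iff its depth (mC + C) is strictly greater than
``min_depth_exclusive`` reads; a promoter is reported for a sample iff at
least ``min_cpg`` CpGs pass, and its level is sum(mC) / sum(mC + C) over
passing CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import CpGRecord, GeneRecord

__all__ = [
    "PromoterRegion",
    "promoter_regions",
    "promoter_methylation",
    "differential_methylation",
]

PROMOTER_SPAN = 1000


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 < self.end - self.start <= PROMOTER_SPAN):
            raise ValidationError(
                f"promoter of {self.gene_id} has length {self.end - self.start}"
            )


def promoter_regions(
    genes: list[GeneRecord], span: int = PROMOTER_SPAN
) -> list[PromoterRegion]:
    """One promoter per gene record (callers pass representative isoforms)."""
    out = []
    for g in genes:
        if g.strand == "+":
            start, end = max(0, g.start - span), g.start
            if end <= start:  # gene starts at the contig edge
                continue
        else:
            start, end = g.end, g.end + span
        out.append(
            PromoterRegion(gene_id=g.gene_id, chrom=g.chrom, start=start, end=end, strand=g.strand)
        )
    return out


def promoter_methylation(
    cpgs: list[CpGRecord],
    promoters: list[PromoterRegion],
    min_cpg: int = 2,
    min_depth_exclusive: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(gene, sample) promoter methylation levels.

    Returns (reported, excluded): ``reported`` has columns gene_id,
    sample_id, level, n_cpg_passing, total_mC, total_C; ``excluded`` lists
    promoter/sample pairs that failed the CpG-count filter with a reason.
    CpG report positions are 1-based and promoters 0-based half-open, so a
    CpG at position p overlaps [start, end) iff start < p <= end.
    """
    by_sample: dict[str, dict[str, list[CpGRecord]]] = {}
    for rec in cpgs:
        by_sample.setdefault(rec.sample_id, {}).setdefault(rec.chrom, []).append(rec)
    arrays: dict[str, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    for sample_id, chroms in by_sample.items():
        arrays[sample_id] = {}
        for chrom, recs in chroms.items():
            recs.sort(key=lambda r: r.position)
            pos = np.array([r.position for r in recs])
            mc = np.array([r.count_methylated for r in recs])
            uc = np.array([r.count_unmethylated for r in recs])
            arrays[sample_id][chrom] = (pos, mc, uc)

    reported_rows, excluded_rows = [], []
    for sample_id in sorted(arrays):
        per_chrom = arrays[sample_id]
        for prom in promoters:
            entry = per_chrom.get(prom.chrom)
            if entry is None:
                excluded_rows.append(
                    (prom.gene_id, sample_id, 0, "no CpG data on contig")
                )
                continue
            pos, mc, uc = entry
            lo = np.searchsorted(pos, prom.start, side="right")  # pos > start
            hi = np.searchsorted(pos, prom.end, side="right")  # pos <= end
            depth = mc[lo:hi] + uc[lo:hi]
            passing = depth > min_depth_exclusive
            n_pass = int(passing.sum())
            if n_pass < min_cpg:
                excluded_rows.append(
                    (
                        prom.gene_id,
                        sample_id,
                        n_pass,
                        f"fewer than {min_cpg} CpGs with depth > {min_depth_exclusive}",
                    )
                )
                continue
            total_mc = int(mc[lo:hi][passing].sum())
            total_c = int(uc[lo:hi][passing].sum())
            reported_rows.append(
                (
                    prom.gene_id,
                    sample_id,
                    total_mc / (total_mc + total_c),
                    n_pass,
                    total_mc,
                    total_c,
                )
            )
    reported = pd.DataFrame(
        reported_rows,
        columns=["gene_id", "sample_id", "level", "n_cpg_passing", "total_mC", "total_C"],
    )
    excluded = pd.DataFrame(
        excluded_rows, columns=["gene_id", "sample_id", "n_cpg_passing", "reason"]
    )
    return reported, excluded


def differential_methylation(
    levels_a: pd.DataFrame,
    levels_b: pd.DataFrame,
    equal_var: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Welch two-sided t-test of per-sample promoter levels, group A vs B.

    Inputs are promoter-methylation tables (gene_id, sample_id, level) for
    the two groups. Promoters with fewer than 2 reported samples in either
    group are skipped with a reason. Zero variance in both groups with equal
    means yields t = 0, p = 1.
    """
    ga = {g: sub["level"].to_numpy(dtype=float) for g, sub in levels_a.groupby("gene_id")}
    gb = {g: sub["level"].to_numpy(dtype=float) for g, sub in levels_b.groupby("gene_id")}
    rows, skipped = [], []
    for gene in sorted(set(ga) | set(gb)):
        a = ga.get(gene, np.empty(0))
        b = gb.get(gene, np.empty(0))
        if len(a) < 2 or len(b) < 2:
            skipped.append((gene, len(a), len(b), "fewer than 2 reported samples in a group"))
            continue
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            if a.mean() == b.mean():
                rows.append((gene, 0.0, 1.0, len(a), len(b)))
            else:
                rows.append((gene, np.inf if a.mean() > b.mean() else -np.inf, 0.0, len(a), len(b)))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append((gene, float(t), float(p), len(a), len(b)))
    results = pd.DataFrame(rows, columns=["gene_id", "t", "p_value", "n_a", "n_b"])
    skipped_df = pd.DataFrame(skipped, columns=["gene_id", "n_a", "n_b", "reason"])
    return results, skipped_df
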