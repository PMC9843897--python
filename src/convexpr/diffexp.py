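"""Two-group negative-binomial exact test with common dispersion.

The test conditions on the per-gene total after rescaling all samples to a
common (geometric-mean) library size and rounding. Under H0 both groups
share one mean; the group-A sum is NB(n_a * mu, phi / n_a) and likewise for
B, so the conditional probability of each split of the total is the product
of two NB pmfs. The two-sided p-value sums the probabilities of all splits
no more likely than the observed one. phi = 0 degenerates to Poisson.

Fold changes are log2((mean_A + 0.5) / (mean_B + 0.5)) on the rescaled
values; the 0.5 pseudo-count bounds fold changes for all-zero groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "estimate_common_dispersion",
    "exact_test_nb",
    "bh_adjust",
    "call_degs",
    "de_table",
]


def _group_pmf(s: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """pmf of a sum of i.i.d. NB counts with total mean ``mean`` and
    per-observation dispersion already folded in (variance mean + phi*mean^2)."""
    if phi <= 0:
        return stats.poisson.pmf(s, mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return stats.nbinom.pmf(s, r, p)


def estimate_common_dispersion(
    matrix: pd.DataFrame | np.ndarray,
    groups: list[list[int]] | tuple[list[int], list[int]],
    lib_sizes=None,
) -> float:
    """Common NB dispersion by method of moments.

    Counts are normalized to the mean library size; within every group the
    per-gene moment estimate phi_g = max(0, (s^2 - mu) / mu^2) is computed
    and pooled across groups weighted by degrees of freedom; the common
    value is the median over genes with positive means in all groups.
    """
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    for g in groups:
        if len(g) < 2:
            raise ValidationError("each group needs >= 2 samples to estimate dispersion")
    lib = np.asarray(lib_sizes, dtype=float) if lib_sizes is not None else x.sum(axis=0)
    if np.any(lib <= 0):
        raise ValidationError("library sizes must be > 0")
    xn = x / lib * lib.mean()

    phi_num = np.zeros(x.shape[0])
    phi_den = 0.0
    usable = np.ones(x.shape[0], dtype=bool)
    for g in groups:
        sub = xn[:, g]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        usable &= mu > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = (s2 - mu) / mu**2
        phi_g = np.where(mu > 0, np.maximum(phi_g, 0.0), 0.0)
        df = len(g) - 1
        phi_num += df * phi_g
        phi_den += df
    if not usable.any():
        return 0.0
    return float(np.median(phi_num[usable] / phi_den))


def exact_test_nb(
    counts_a,
    counts_b,
    phi: float,
    lib_sizes_a,
    lib_sizes_b,
) -> pd.DataFrame:
    """Per-gene (log2FC, p_value) for group A vs group B.

    ``counts_*`` are genes x samples (integers or non-negative reals such as
    RPK values); ``lib_sizes_*`` are the effective library sizes used to put
    all samples on the geometric-mean library scale before rounding.
    """
    if phi < 0:
        raise ValidationError(f"dispersion must be >= 0, got {phi}")
    a = counts_a.to_numpy(dtype=float) if isinstance(counts_a, pd.DataFrame) else np.asarray(counts_a, dtype=float)
    b = counts_b.to_numpy(dtype=float) if isinstance(counts_b, pd.DataFrame) else np.asarray(counts_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("counts must be non-negative")
    lib_a = np.asarray(lib_sizes_a, dtype=float)
    lib_b = np.asarray(lib_sizes_b, dtype=float)
    if np.any(lib_a <= 0) or np.any(lib_b <= 0):
        raise ValidationError("library sizes must be > 0")
    n_a, n_b = a.shape[1], b.shape[1]
    n_star = np.exp(np.mean(np.log(np.concatenate([lib_a, lib_b]))))
    pa = np.rint(a * (n_star / lib_a)).astype(np.int64)
    pb = np.rint(b * (n_star / lib_b)).astype(np.int64)

    sum_a = pa.sum(axis=1)
    sum_b = pb.sum(axis=1)
    n_genes = a.shape[0]
    pvals = np.ones(n_genes)
    lfc = np.log2((pa.mean(axis=1) + 0.5) / (pb.mean(axis=1) + 0.5))

    for i in range(n_genes):
        total = sum_a[i] + sum_b[i]
        if total == 0:
            continue
        mu = total / (n_a + n_b)
        s = np.arange(total + 1)
        # sums of n i.i.d. NB(mu, phi) are NB(n*mu, phi/n)
        prob = _group_pmf(s, n_a * mu, phi / n_a) * _group_pmf(s[::-1], n_b * mu, phi / n_b)
        denom = prob.sum()
        if denom <= 0:
            continue
        observed = prob[sum_a[i]]
        pvals[i] = min(1.0, prob[prob <= observed * (1 + 1e-10)].sum() / denom)

    index = counts_a.index if isinstance(counts_a, pd.DataFrame) else pd.RangeIndex(n_genes)
    return pd.DataFrame({"log2FC": lfc, "p_value": pvals}, index=index)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be 1-D")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class DEGSets:
    up: set[str]
    down: set[str]


def call_degs(
    de: pd.DataFrame, lfc_threshold: float = 1.0, fdr_threshold: float = 0.05
) -> DEGSets:
    """Split a DE table (columns log2FC, fdr) into up / down DEG sets."""
    up = de.index[(de["log2FC"] >= lfc_threshold) & (de["fdr"] < fdr_threshold)]
    down = de.index[(de["log2FC"] <= -lfc_threshold) & (de["fdr"] < fdr_threshold)]
    return DEGSets(up=set(up), down=set(down))


def de_table(
    counts_a,
    counts_b,
    phi: float,
    lib_sizes_a,
    lib_sizes_b,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full DE result: log2FC, p, BH fdr and a direction column."""
    de = exact_test_nb(counts_a, counts_b, phi, lib_sizes_a, lib_sizes_b)
    de["fdr"] = bh_adjust(de["p_value"].to_numpy())
    direction = np.where(
        (de["log2FC"] >= lfc_threshold) & (de["fdr"] < fdr_threshold),
        "up",
        np.where(
            (de["log2FC"] <= -lfc_threshold) & (de["fdr"] < fdr_threshold),
            "down",
            "ns",
        ),
    )
    de["direction"] = direction
    return de
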