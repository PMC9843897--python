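"""GeTMM normalization: gene-length-corrected counts scaled by TMM factors.

The TMM factor of a sample s against a reference r is

    f_s = 2 ** ( sum_g w_g M_g / sum_g w_g )

over genes kept after doubly trimming by the log-ratio M_g and the absolute
intensity A_g, where

    M_g = log2( (y_gs / N_s) / (y_gr / N_r) )
    A_g = 0.5 * log2( (y_gs / N_s) * (y_gr / N_r) )
    w_g = (1 - p_gs) / p_gs + (1 - p_gr) / p_gr,   p = y / N

Genes with a zero in either sample are excluded. The inverse-asymptotic-
variance weights are computed from library-relative proportions p rather
than raw counts, which makes every factor exactly invariant to rescaling a
sample's counts (and coincides with the count-scale weights whenever the
two library sizes are equal). Factors are rescaled so that their geometric
mean is exactly 1. GeTMM applies this machinery to the reads-per-kilobase
(RPK) matrix and divides each RPK column by its factor-adjusted library
size, times 1e6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TMMParams",
    "NormalizedMatrix",
    "filter_low_expressed",
    "rpk",
    "tmm_factors",
    "getmm_normalize",
    "coefficient_of_variation",
]


@dataclass
class TMMParams:
    logratio_trim: float = 0.30
    abs_trim: float = 0.05
    reference_sample: str = "auto"
    weighted: bool = True

    def __post_init__(self) -> None:
        for name, v in (("logratio_trim", self.logratio_trim), ("abs_trim", self.abs_trim)):
            if not (0 <= v < 0.5):
                raise ValidationError(f"{name} must be in [0, 0.5), got {v}")


@dataclass
class NormalizedMatrix:
    """GeTMM expression values on orthologue rows, per-million scale."""

    values: pd.DataFrame  # genes x samples, float
    scaling_factors: pd.Series  # per-sample TMM factor, geometric mean 1
    library_sizes: pd.Series  # per-sample RPK library size (pre-factor)

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValidationError("normalized values must be finite and >= 0")
        f = self.scaling_factors.to_numpy(dtype=float)
        if np.any(f <= 0):
            raise ValidationError("scaling factors must be > 0")
        if abs(np.exp(np.mean(np.log(f))) - 1.0) > 1e-9:
            raise ValidationError("scaling factors must have geometric mean 1")


def filter_low_expressed(
    matrix: pd.DataFrame, species_of: dict[str, str]
) -> pd.DataFrame:
    """Keep rows with count > 0 in every sample of every species.

    Since each sample belongs to exactly one species, the strict reading
    reduces to: every sample strictly positive. ``species_of`` is still
    validated so mislabelled designs fail loudly rather than silently.
    """
    unknown = [s for s in matrix.columns if s not in species_of]
    if unknown:
        raise ConfigurationError(f"samples with no species label: {unknown}")
    if matrix.empty:
        return matrix.copy()
    keep = (matrix.to_numpy() > 0).all(axis=1)
    out = matrix.loc[keep].copy()
    logger.info("expression filter: kept %d/%d genes", len(out), len(matrix))
    return out


def rpk(counts: pd.DataFrame, gene_lengths) -> pd.DataFrame:
    """Reads per kilobase: counts / (length / 1000).

    ``gene_lengths`` is a per-gene vector or a genes x samples frame (for
    cross-species matrices where the same orthologue has a different length
    in each species).
    """
    lengths = np.asarray(gene_lengths, dtype=float)
    if lengths.ndim == 1:
        if len(lengths) != len(counts):
            raise ValidationError("gene_lengths length does not match matrix rows")
        lengths = lengths[:, None]
    elif lengths.shape != counts.shape:
        raise ValidationError("gene_lengths matrix shape does not match counts")
    if np.any(lengths <= 0):
        raise ValidationError("gene lengths must be > 0")
    return counts / (lengths / 1000.0)


def _choose_reference(matrix: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Sample whose 75th-percentile relative expression is closest to the mean."""
    with np.errstate(invalid="ignore"):
        f75 = np.array(
            [np.quantile(matrix[:, j] / lib_sizes[j], 0.75) for j in range(matrix.shape[1])]
        )
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _trim_keep(values: np.ndarray, trim: float) -> np.ndarray:
    """Mask keeping the central (1 - 2*trim) fraction by value thresholds.

    Thresholds are compared with a small tolerance so that exact ties at the
    boundary are kept on both sides; this makes trimming stable under float
    rescaling of the inputs (rank-based trimming is not, because rescaling
    can break exact ties).
    """
    n = len(values)
    k = int(np.floor(n * trim))
    s = np.sort(values)
    lo, hi = s[k], s[n - k - 1]
    tol = 1e-9 * (np.abs(values).max() + 1.0)
    return (values >= lo - tol) & (values <= hi + tol)


def _tmm_one(
    y_s: np.ndarray,
    y_r: np.ndarray,
    n_s: float,
    n_r: float,
    params: TMMParams,
) -> float:
    ok = (y_s > 0) & (y_r > 0)
    if not ok.any():
        return 1.0
    ys, yr = y_s[ok], y_r[ok]
    m = np.log2((ys / n_s) / (yr / n_r))
    a = 0.5 * np.log2((ys / n_s) * (yr / n_r))
    # degenerate: all ratios identical -> that common ratio
    if np.allclose(np.max(m), np.min(m), rtol=0, atol=1e-10):
        return float(2 ** np.mean(m))
    keep = _trim_keep(m, params.logratio_trim) & _trim_keep(a, params.abs_trim)
    if not keep.any():
        return 1.0
    if params.weighted:
        p_s, p_r = ys / n_s, yr / n_r
        w = (1 - p_s) / p_s + (1 - p_r) / p_r
        w = np.where(w <= 0, np.finfo(float).tiny, w)
        return float(2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))
    return float(2 ** np.mean(m[keep]))


def tmm_factors(matrix, params: TMMParams | None = None) -> np.ndarray:
    """Per-sample TMM scaling factors, geometric mean rescaled to 1."""
    params = params or TMMParams()
    if isinstance(matrix, pd.DataFrame):
        columns = list(matrix.columns)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        columns = list(range(x.shape[1]))
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("need a matrix with >= 2 samples")
    if np.any(x < 0):
        raise ValidationError("matrix must be non-negative")
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        bad = [columns[j] for j in np.where(lib <= 0)[0]]
        raise ValidationError(f"samples with all-zero counts: {bad}")
    if params.reference_sample == "auto":
        ref = _choose_reference(x, lib)
    else:
        if params.reference_sample not in columns:
            raise ConfigurationError(
                f"reference sample {params.reference_sample!r} not in matrix"
            )
        ref = columns.index(params.reference_sample)
    factors = np.array(
        [
            1.0 if j == ref else _tmm_one(x[:, j], x[:, ref], lib[j], lib[ref], params)
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def getmm_normalize(
    counts: pd.DataFrame,
    gene_lengths,
    params: TMMParams | None = None,
) -> NormalizedMatrix:
    """GeTMM: TMM factors on the RPK matrix, per-million on adjusted libraries.

    value[g, s] = RPK[g, s] / (sum_g RPK[g, s] * f_s) * 1e6
    """
    rpk_matrix = rpk(counts, gene_lengths)
    factors = tmm_factors(rpk_matrix, params)
    lib = rpk_matrix.sum(axis=0)
    values = rpk_matrix / (lib * factors) * 1e6
    return NormalizedMatrix(
        values=values,
        scaling_factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        library_sizes=pd.Series(lib, index=counts.columns, name="rpk_library_size"),
    )


def coefficient_of_variation(matrix: pd.DataFrame) -> pd.Series:
    """Per-gene CV = sd / mean across samples (sample sd, n-1 denominator).

    Rows with zero mean are excluded (a warning is logged).
    """
    means = matrix.mean(axis=1)
    zero = means == 0
    if zero.any():
        logger.warning("CV: excluding %d zero-mean rows", int(zero.sum()))
    kept = matrix.loc[~zero]
    return kept.std(axis=1, ddof=1) / kept.mean(axis=1)
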