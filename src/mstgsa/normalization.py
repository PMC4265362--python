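"""Count normalizations feeding the multivariate tests.

Four chains are provided, each ending in a linear-scale matrix that can be
passed through ``log_transform`` (log2(1+x)) before testing:

* ``rpkm`` — reads per kilobase per million mapped reads,
  ``1e9 * Y_ij / (L_i * N_j)`` with gene length ``L_i`` (bp) and library
  size ``N_j``.
* ``tmm_rpkm`` — trimmed-mean-of-M-values scaling factors rescale the
  library sizes, then RPKM.  TMM corrects for library composition; RPKM
  afterwards accounts for gene length.
* ``qqn_rpkm`` — quantile normalization (every sample's order statistics
  replaced by the across-sample mean order statistics), then length and
  depth scaling as in RPKM.
* ``voomlike_rpkm`` — offset log-CPM (log2((Y+0.5)/(N+1)*1e6)) back-
  transformed to linear scale and followed by RPKM.  Precision weights are
  deliberately not computed; only the depth normalization is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core_io import CountMatrix

__all__ = [
    "ExpressionMatrix",
    "rpkm",
    "tmm_factors",
    "tmm_rpkm",
    "quantile_normalize",
    "qqn_rpkm",
    "voomlike_rpkm",
    "log_transform",
    "normalize",
    "NORMALIZATIONS",
]


@dataclass
class ExpressionMatrix:
    """Real-valued normalized expression, genes x samples."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    provenance: str
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.log_transformed and np.any(self.values < 0):
            raise ValueError("log-transformed values must be non-negative")

    def subset(self, genes: list[str]) -> "ExpressionMatrix":
        """Rows for the given genes, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing[:10]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            np.asarray(genes, dtype=object),
            self.sample_ids,
            self.values[rows, :],
            self.provenance,
            self.log_transformed,
        )


def _check_libsizes(cm: CountMatrix) -> np.ndarray:
    lib = cm.library_sizes
    if np.any(lib <= 0):
        raise ValueError("every sample needs a positive library size")
    return lib.astype(float)


def rpkm(cm: CountMatrix) -> ExpressionMatrix:
    """Reads per kilobase of gene per million mapped reads."""
    lib = _check_libsizes(cm)
    values = 1e9 * cm.counts / (cm.gene_lengths[:, None].astype(float) * lib[None, :])
    return ExpressionMatrix(cm.gene_ids, cm.sample_ids, values, "rpkm")


# ---------------------------------------------------------------------------
# TMM


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """Scaling factor of one sample against the reference.

    Doubly trimmed (by gene-wise log-ratio M and by average log abundance A),
    weighted mean of M, with inverse asymptotic-variance weights; genes with
    a zero count in either sample are excluded.
    """
    keep = (obs > 0) & (ref > 0)
    o = obs[keep].astype(float)
    r = ref[keep].astype(float)
    if o.size == 0:
        return 1.0
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    var = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2):
        return 1.0
    w = 1.0 / var[keep2]
    f = float(np.sum(w * m[keep2]) / np.sum(w))
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    cm: CountMatrix,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """Per-sample TMM scaling factors, geometric-mean centred to 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the across-sample mean upper quartile.  Trim fractions follow
    the published defaults: 30% two-sided on M, 5% two-sided on A.
    """
    if cm.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    lib = cm.library_sizes.astype(float)
    if np.any(cm.counts.sum(axis=0) == 0):
        raise ValueError("TMM undefined for a sample with all-zero counts")
    uq = np.array([np.quantile(cm.counts[:, j] / lib[j], 0.75) for j in range(cm.n_samples)])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = cm.counts[:, ref_idx]
    factors = np.array([
        _tmm_pair(cm.counts[:, j], ref, lib[j], lib[ref_idx], logratio_trim, sum_trim)
        for j in range(cm.n_samples)
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def tmm_rpkm(cm: CountMatrix) -> ExpressionMatrix:
    """TMM-rescaled effective library sizes, then RPKM."""
    factors = tmm_factors(cm)
    lib = _check_libsizes(cm) * factors
    values = 1e9 * cm.counts / (cm.gene_lengths[:, None].astype(float) * lib[None, :])
    return ExpressionMatrix(cm.gene_ids, cm.sample_ids, values, "tmm_rpkm")


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Replace each column's order statistics by the mean order statistics.

    Ties within a column receive the mean of the corresponding mean-order-
    statistics (mid-rank convention), so the map is well defined and
    permutation-equivariant per column.
    """
    values = np.asarray(values, dtype=float)
    n_genes = values.shape[0]
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n_genes + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j])  # mid-ranks for ties
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return out


def qqn_rpkm(cm: CountMatrix) -> ExpressionMatrix:
    """Quantile normalization across samples, then RPKM-style scaling.

    Length scaling uses 1e3/L_i; depth scaling uses 1e6 over the post-QQN
    column sums (all equal after quantile normalization up to tie effects).
    """
    if cm.n_samples < 2:
        raise ValueError("quantile normalization needs at least two samples")
    q = quantile_normalize(cm.counts.astype(float))
    colsums = q.sum(axis=0)
    if np.any(colsums <= 0):
        raise ValueError("post-QQN column sum must be positive")
    values = 1e9 * q / (cm.gene_lengths[:, None].astype(float) * colsums[None, :])
    return ExpressionMatrix(cm.gene_ids, cm.sample_ids, values, "qqn_rpkm")


# ---------------------------------------------------------------------------
# voom-like chain


def offset_log_cpm(counts: np.ndarray, library_sizes: np.ndarray) -> np.ndarray:
    """log2 counts-per-million with the standard 0.5 / 1 offsets."""
    return np.log2(
        (counts + 0.5) / (library_sizes[None, :].astype(float) + 1.0) * 1e6
    )


def voomlike_rpkm(cm: CountMatrix) -> ExpressionMatrix:
    """Depth-normalized log-CPM, back-transformed to linear scale, then RPKM.

    The back-transform ``2^x * (N_j + 1) / 1e6 - 0.5`` (floored at 0) is the
    exact inverse of the offset log-CPM, so this chain differs from plain
    RPKM only through the floor; it exists so the study can run the same
    pipeline shape users of log-CPM workflows would run, without precision
    weights.
    """
    lib = _check_libsizes(cm)
    x = offset_log_cpm(cm.counts, cm.library_sizes)
    linear = np.maximum(2.0 ** x * (lib[None, :] + 1.0) / 1e6 - 0.5, 0.0)
    values = 1e9 * linear / (cm.gene_lengths[:, None].astype(float) * lib[None, :])
    return ExpressionMatrix(cm.gene_ids, cm.sample_ids, values, "voomlike_rpkm")


# ---------------------------------------------------------------------------


def log_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(1 + x), the outlier-damping transform applied before
    the multivariate tests."""
    if np.any(em.values < 0):
        raise ValueError("log_transform requires non-negative values")
    return ExpressionMatrix(
        em.gene_ids,
        em.sample_ids,
        np.log2(1.0 + em.values),
        em.provenance + "+log2(1+x)",
        log_transformed=True,
    )


NORMALIZATIONS = {
    "rpkm": rpkm,
    "tmm": tmm_rpkm,
    "qqn": qqn_rpkm,
    "voom": voomlike_rpkm,
}


def normalize(cm: CountMatrix, method: str = "rpkm", log: bool = True) -> ExpressionMatrix:
    """Apply one of the four named chains, optionally followed by log2(1+x)."""
    try:
        fn = NORMALIZATIONS[method]
    except KeyError:
        raise ValueError(
            f"unknown normalization {method!r}; choose from {sorted(NORMALIZATIONS)}"
        ) from None
    em = fn(cm)
    return log_transform(em) if log else em
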