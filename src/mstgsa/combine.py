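"""Gene-level GSA: combine per-gene P-values into one gene-set P-value.

A pluggable univariate test produces one P-value per gene; the set-level
score is ``T = sum_i H(p_i)`` where the transform H is either

* Fisher (FM): ``H(p) = -2 ln p``,
* Stouffer (SM): ``H(p) = Phi^{-1}(1 - p)``, or
* the Gamma method (GM): ``H(p) = G^{-1}_{w,1}(1 - p)``, the inverse CDF
  of a Gamma(shape=w, scale=1).

GM's shape w sets the soft truncation threshold (STT), the P-value whose
transformed contribution equals w; ``w = G^{-1}_{w,1}(1 - STT)`` links the
two.  w = 1 recovers Fisher (up to the factor 2, so identical rankings)
with STT = 1/e; w -> infinity approaches Stouffer with STT = 0.5.  Small w
(the study default w = 0.0137, i.e. STT = 0.05) makes the combined score
sensitive almost exclusively to very small gene-level P-values.

Because genes within a set are correlated, the set-level P-value is never
taken from the parametric null of T; it is estimated by sample permutation,
re-running the univariate test inside every permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .core_io import PhenotypeLabels
from .mst_tests import TestOutcome, _permutation_masks, _pvalue_from_null
from .normalization import ExpressionMatrix

__all__ = [
    "CombinerSpec",
    "fisher_T",
    "stouffer_T",
    "gamma_T",
    "stt_to_shape",
    "shape_to_stt",
    "default_gene_test",
    "welch_pvalues",
    "combine_and_permute",
    "gene_level_gsa",
]


def fisher_T(p: np.ndarray) -> float:
    """Fisher's combined score T = sum -2 ln p_i."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("Fisher combination needs P-values in (0, 1]")
    return float(np.sum(-2.0 * np.log(p)))


def stouffer_T(p: np.ndarray) -> float:
    """Stouffer's combined score T = sum Phi^{-1}(1 - p_i)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("Stouffer combination needs P-values in (0, 1)")
    return float(np.sum(stats.norm.ppf(1.0 - p)))


def gamma_T(p: np.ndarray, shape: float) -> float:
    """Gamma-method combined score T = sum G^{-1}_{w,1}(1 - p_i)."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("gamma combination needs P-values in (0, 1)")
    return float(np.sum(stats.gamma.ppf(1.0 - p, a=shape)))


def shape_to_stt(shape: float) -> float:
    """STT implied by a gamma shape w, via G_{w,1}(w) = 1 - STT."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    return float(1.0 - stats.gamma.cdf(shape, a=shape))


def stt_to_shape(stt: float, rtol: float = 1e-6) -> float:
    """Solve the soft-truncation fixed point w = G^{-1}_{w,1}(1 - STT).

    Equivalently the root of ``G_{w,1}(w) = 1 - STT`` in w, found by
    bracketing and bisection (Brent).  Strictly increasing in STT on the
    valid domain (0, 0.5); STT -> 0.5 is the Stouffer limit w -> infinity,
    hence out of domain.
    """
    if not 0.0 < stt < 0.5:
        raise ValueError("STT must lie strictly between 0 and 0.5")

    def h(w: float) -> float:
        return stats.gamma.cdf(w, a=w) - (1.0 - stt)

    lo = 1e-12
    hi = 1.0
    while h(hi) > 0:  # expand until the root is bracketed
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket the STT fixed point")
    return float(brentq(h, lo, hi, rtol=rtol))


@dataclass
class CombinerSpec:
    """Which transform to use; for GM, shape w and STT (mutually derivable)."""

    method: str = "GM"
    shape: float | None = None
    stt: float | None = None

    def __post_init__(self) -> None:
        self.method = self.method.upper()
        if self.method not in ("FM", "SM", "GM"):
            raise ValueError("method must be one of FM, SM, GM")
        if self.method != "GM":
            if self.shape is not None or self.stt is not None:
                raise ValueError("shape/stt apply to the GM method only")
            return
        if self.shape is None and self.stt is None:
            self.stt = 0.05
        if self.shape is None:
            self.shape = stt_to_shape(self.stt)
        elif self.stt is None:
            self.stt = shape_to_stt(self.shape)
        else:
            implied = stt_to_shape(self.stt)
            if abs(implied - self.shape) > 1e-6 * max(1.0, abs(self.shape)):
                raise ValueError(
                    f"inconsistent GM spec: stt={self.stt} implies shape "
                    f"{implied:.6g}, got {self.shape:.6g}"
                )

    def score(self, p: np.ndarray) -> float:
        if self.method == "FM":
            return fisher_T(p)
        if self.method == "SM":
            return stouffer_T(p)
        return gamma_T(p, self.shape)


# ---------------------------------------------------------------------------
# built-in univariate test


def welch_pvalues(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Two-sided unequal-variance t-test P-values, one per row.

    Vectorized over genes; equivalent to ``scipy.stats.ttest_ind`` with
    ``equal_var=False`` (Welch-Satterthwaite degrees of freedom).
    """
    x = values[:, mask]
    y = values[:, ~mask]
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    se2 = vx / n1 + vy / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / (vx**2 / (n1**2 * (n1 - 1)) + vy**2 / (n2**2 * (n2 - 1)))
    t = np.where(np.isfinite(t), t, 0.0)  # zero-variance, zero-difference rows
    df = np.where(np.isfinite(df), df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.maximum(p, np.finfo(float).tiny)


def default_gene_test(em: ExpressionMatrix, labels: PhenotypeLabels) -> np.ndarray:
    """Per-gene two-sample Welch t-test on log-transformed expression.

    This is the built-in stand-in for any RNA-Seq-specific univariate test;
    the combining machinery accepts any callable with this signature.
    """
    if not em.log_transformed:
        raise ValueError("default_gene_test expects log-transformed expression")
    labels.require_testable()
    return welch_pvalues(em.values, labels.x_mask)


# ---------------------------------------------------------------------------
# permutation-combined set-level test


def combine_and_permute(
    em: ExpressionMatrix,
    set_genes: list[str],
    labels: PhenotypeLabels,
    spec: CombinerSpec,
    gene_test=None,
    B: int = 1000,
    seed: int = 0,
    ties: str = "add-one",
) -> TestOutcome:
    """Set-level permutation P-value for a combined gene-level score.

    The univariate test is re-run on every one of the B label permutations
    (gene-level P-values are never frozen), the combined score T recomputed,
    and the upper-tail permutation P-value returned.  Gene-level P-values
    are floored at 1/(B+1) and capped just below 1 before the SM/GM
    transforms, which are undefined at the endpoints.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    labels.require_testable()
    sub = em.subset(list(set_genes))
    if gene_test is None:
        test_fn = lambda mask: welch_pvalues(sub.values, mask)  # noqa: E731
    else:
        def test_fn(mask):
            lab = PhenotypeLabels(
                labels.sample_ids,
                np.where(mask, labels.group_order[0], labels.group_order[1]),
                labels.group_order,
            )
            return np.asarray(gene_test(sub, lab), dtype=float)

    floor = 1.0 / (B + 1)
    cap = 1.0 - 1e-12

    def score(mask: np.ndarray) -> float:
        p = np.clip(test_fn(mask), floor, cap)
        return spec.score(p)

    mask = labels.x_mask
    observed = score(mask)
    rng = np.random.default_rng(seed)
    masks = _permutation_masks(rng, labels.n, labels.n1, B)
    null = np.array([score(masks[b]) for b in range(B)], dtype=float)
    p = _pvalue_from_null(observed, null, "upper", ties)
    return TestOutcome(observed, p, B, "upper", seed, ties)


def gene_level_gsa(
    em: ExpressionMatrix,
    sets,
    labels: PhenotypeLabels,
    spec: CombinerSpec,
    gene_test=None,
    B: int = 1000,
    seed: int = 0,
    ties: str = "add-one",
):
    """Run :func:`combine_and_permute` over a whole collection; returns a
    results table in collection order."""
    import pandas as pd

    from .core_io import RESULT_COLUMNS
    from .mst_tests import set_seed_for

    rows = []
    for name, genes in sets:
        outcome = combine_and_permute(
            em, genes, labels, spec, gene_test, B, set_seed_for(seed, name), ties
        )
        rows.append({
            "set": name,
            "size": len(genes),
            "statistic": outcome.statistic,
            "pvalue": outcome.pvalue,
            "method": spec.method,
            "normalization": em.provenance,
            "n_permutations": B,
            "seed": seed,
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
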