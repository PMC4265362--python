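"""Orchestration of the comparative study and pathway-bias diagnostics.

``run_type1_table`` and ``run_power_curves`` sweep the simulation grid
(test x normalization x N x p, and test x gamma x FC) with per-cell
caching keyed by a digest of the full cell configuration, so interrupted
grids resume without recomputation.  ``pathway_bias_summary`` reports, for
the pathways a results table detects, the three bias diagnostics: pathway
size, fraction of DE genes (built-in gene test + Benjamini-Hochberg FDR),
and mean gene length, together with a Wilcoxon rank-sum comparison of the
detected pathways' mean gene lengths against all pathways'.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from statsmodels.stats.multitest import multipletests

from .combine import default_gene_test
from .core_io import GeneSetCollection, PhenotypeLabels
from .normalization import ExpressionMatrix
from .simulate import NBParamPool, SimulationDesign, estimate_power, estimate_type1

__all__ = [
    "StudyConfig",
    "run_type1_table",
    "run_power_curves",
    "BiasSummary",
    "pathway_bias_summary",
    "overlap_counts",
]


@dataclass
class StudyConfig:
    """Flat configuration for the simulation study grids."""

    tests: tuple[str, ...] = ("N", "WW", "KS")
    normalizations: tuple[str, ...] = ("rpkm", "qqn", "tmm", "voom")
    sample_sizes: tuple[int, ...] = (20, 40, 60)
    set_sizes: tuple[int, ...] = (16, 60, 100)
    fc_values: tuple[float, ...] = (1.2, 1.5, 2.0, 2.5, 3.0)
    gamma_values: tuple[float, ...] = (1 / 8, 1 / 4, 1 / 2)
    n_sets: int = 1000
    B: int = 1000
    alpha: float = 0.05
    seed: int = 0
    pool_size: int = 10_000
    pool_path: str | None = None
    ties: str = "strict"
    cache_dir: str | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in mapping.items() if k in known}
        for key in ("tests", "normalizations", "sample_sizes", "set_sizes",
                    "fc_values", "gamma_values"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        extra = {k: v for k, v in mapping.items() if k not in known}
        return cls(**kwargs, extra=extra)


def _pool_for(config: StudyConfig) -> NBParamPool:
    from .simulate import read_pool, synth_param_pool

    if config.pool_path:
        return read_pool(config.pool_path)
    return synth_param_pool(config.pool_size, config.seed)


def _cell_digest(kind: str, cell: dict) -> str:
    payload = json.dumps({"kind": kind, **cell}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cached(cache_dir: str | None, key: str, compute):
    if cache_dir is None:
        return compute()
    path = Path(cache_dir) / f"{key}.json"
    if path.exists():
        return json.loads(path.read_text())["value"]
    value = compute()
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"value": value}))
    return value


def run_type1_table(config: StudyConfig, out_path: str | None = None) -> pd.DataFrame:
    """Type I error over the (test x normalization x N x p) grid.

    Per-set P-values are thresholded at ``config.alpha``; the per-cell seed
    is a deterministic function of the cell, so the table is a pure
    function of the configuration.
    """
    pool = _pool_for(config)
    rows = []
    for N in config.sample_sizes:
        for p in config.set_sizes:
            for test in config.tests:
                for norm in config.normalizations:
                    cell = {
                        "N": N, "p": p, "test": test, "norm": norm,
                        "n_sets": config.n_sets, "B": config.B,
                        "alpha": config.alpha, "seed": config.seed,
                        "ties": config.ties, "pool": config.pool_path or config.pool_size,
                    }
                    design = SimulationDesign(
                        N=N, p=p, fc=1.0, gamma=1.0, n_sets=config.n_sets,
                        B=config.B, alpha=config.alpha, seed=config.seed,
                    )
                    rate = _cached(
                        config.cache_dir,
                        _cell_digest("type1", cell),
                        lambda d=design, t=test, nm=norm: estimate_type1(
                            pool, d, t, nm, ties=config.ties
                        ),
                    )
                    rows.append({**cell, "type1_error": rate})
    table = pd.DataFrame(rows)
    if out_path:
        table.to_csv(out_path, sep="\t", index=False, lineterminator="\n")
    return table


def run_power_curves(config: StudyConfig, out_path: str | None = None) -> pd.DataFrame:
    """Power over the (test x normalization x gamma x FC) grid, long format."""
    pool = _pool_for(config)
    N = config.sample_sizes[0]
    p = config.set_sizes[0]
    rows = []
    for test in config.tests:
        for norm in config.normalizations:
            for gamma in config.gamma_values:
                for fc in config.fc_values:
                    cell = {
                        "N": N, "p": p, "test": test, "norm": norm,
                        "gamma": gamma, "fc": fc, "n_sets": config.n_sets,
                        "B": config.B, "alpha": config.alpha,
                        "seed": config.seed, "ties": config.ties,
                        "pool": config.pool_path or config.pool_size,
                    }
                    design = SimulationDesign(
                        N=N, p=p, fc=fc, gamma=gamma, n_sets=config.n_sets,
                        B=config.B, alpha=config.alpha, seed=config.seed,
                    )
                    power = _cached(
                        config.cache_dir,
                        _cell_digest("power", cell),
                        lambda d=design, t=test, nm=norm: float(
                            estimate_power(pool, d, t, nm, ties=config.ties)
                            ["power"].iloc[0]
                        ),
                    )
                    rows.append({**cell, "power": power})
    table = pd.DataFrame(rows)
    if out_path:
        table.to_csv(out_path, sep="\t", index=False, lineterminator="\n")
    return table


# ---------------------------------------------------------------------------
# bias diagnostics


@dataclass
class BiasSummary:
    """Size / %DE / mean-gene-length profile of the detected pathways."""

    per_pathway: pd.DataFrame
    ranksum_p: float
    n_detected: int
    alpha: float
    de_rule: str


def pathway_bias_summary(
    results: pd.DataFrame,
    em: ExpressionMatrix,
    sets: GeneSetCollection,
    labels: PhenotypeLabels,
    gene_lengths: dict | pd.Series,
    alpha: float = 0.05,
    fdr: float = 0.05,
) -> BiasSummary:
    """Bias diagnostics over the pathways detected at level alpha.

    %DE per pathway is the fraction of its genes declared differentially
    expressed by the built-in gene-level test with Benjamini-Hochberg
    control at ``fdr``.  The rank-sum P compares detected pathways' mean
    gene lengths against the mean lengths of all pathways (two-sided); with
    zero detected pathways the summary is empty and the P is flagged 1.
    """
    lengths = pd.Series(gene_lengths)
    pvals = default_gene_test(em, labels)
    de = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
    de_by_gene = dict(zip(em.gene_ids, de))

    mean_lengths_all = {}
    frac_de = {}
    for name, genes in sets:
        missing = [g for g in genes if g not in lengths.index]
        if missing:
            raise KeyError(f"gene lengths missing for set {name!r}: {missing[:5]}")
        mean_lengths_all[name] = float(lengths[list(genes)].mean())
        frac_de[name] = float(np.mean([de_by_gene.get(g, False) for g in genes]))

    detected = results.loc[results["pvalue"] <= alpha, "set"].tolist()
    per = pd.DataFrame({
        "set": detected,
        "size": [len(sets.sets[name]) for name in detected],
        "frac_de": [frac_de[name] for name in detected],
        "mean_length_bp": [mean_lengths_all[name] for name in detected],
    })
    if not detected:
        p = 1.0
    else:
        det = per["mean_length_bp"].to_numpy()
        allm = np.array(list(mean_lengths_all.values()))
        if np.array_equal(np.sort(det), np.sort(allm)):
            p = 1.0  # identical samples: no length bias by construction
        else:
            p = float(ranksums(det, allm).pvalue)
    return BiasSummary(per, p, len(detected), alpha, f"welch+BH@{fdr}")


def overlap_counts(result_tables: list[pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Venn cell counts of pathways detected (P <= alpha) by each subset of
    methods.  All tables must cover the same set collection."""
    if len(result_tables) < 2:
        raise ValueError("need at least two result tables")
    universes = [set(t["set"]) for t in result_tables]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("result tables cover different set collections")
    detected = [set(t.loc[t["pvalue"] <= alpha, "set"]) for t in result_tables]
    k = len(detected)
    rows = []
    for cell in range(1, 2**k):
        members = [bool(cell >> i & 1) for i in range(k)]
        inter = set.intersection(*(detected[i] for i in range(k) if members[i]))
        outside = set().union(*(detected[i] for i in range(k) if not members[i]), set())
        rows.append({
            **{f"method_{i}": members[i] for i in range(k)},
            "count": len(inter - outside),
        })
    return pd.DataFrame(rows)
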