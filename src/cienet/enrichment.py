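"""Module validation by permutation and module-vs-DE overlap enrichment.

Module validation compares each module's mean topological overlap with the
same statistic on random gene sets of identical size (drawn without
replacement from the network genes); z-scores against the permutation null
give one-sided normal p-values and BH FDRs, significant at FDR <= 0.2 by
default.  Overlap enrichment uses the one-sided hypergeometric
(Fisher's exact) test with a cross-product odds ratio; a (module, DE set)
cell is called significant by the compound rule p <= 0.005 AND odds
ratio > 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cienet.diffexpr import bh_fdr
from cienet.network import GREY, ModulePartition, Network
from cienet.types import GeneSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    """2x2 overlap of two gene sets within a universe."""

    a: int  # in both
    b: int  # A only
    c: int  # B only
    d: int  # neither
    p_value: float  # one-sided (enrichment) hypergeometric
    p_two_sided: float
    odds_ratio: float
    significant: bool


def fisher_overlap(
    set_a: GeneSet | set,
    set_b: GeneSet | set,
    universe: GeneSet | set,
    p_threshold: float = 0.005,
    or_threshold: float = 3.0,
) -> OverlapResult:
    """Exact test of overlap between two gene sets in a universe.

    The enrichment p-value is the upper hypergeometric tail P(X >= a); the
    odds ratio is the cross-product (a*d)/(b*c) with a Haldane 0.5
    correction when any cell is zero.  The compound significance flag
    requires p <= ``p_threshold`` and odds ratio > ``or_threshold``.
    """
    ua = set_a.gene_ids if isinstance(set_a, GeneSet) else set(set_a)
    ub = set_b.gene_ids if isinstance(set_b, GeneSet) else set(set_b)
    uu = universe.gene_ids if isinstance(universe, GeneSet) else set(universe)
    if not uu:
        raise ValueError("universe is empty")
    if not ua <= uu or not ub <= uu:
        raise ValueError("sets must be subsets of the universe")
    return fisher_overlap_counts(
        len(ua & ub), len(ua), len(ub), len(uu), p_threshold, or_threshold
    )


def fisher_overlap_counts(
    a: int,
    size_a: int,
    size_b: int,
    n_universe: int,
    p_threshold: float = 0.005,
    or_threshold: float = 3.0,
) -> OverlapResult:
    """Same test from counts: ``a`` genes shared by sets of ``size_a`` and
    ``size_b`` in a universe of ``n_universe``."""
    b = size_a - a
    c = size_b - a
    d = n_universe - size_a - size_b + a
    if min(a, b, c, d) < 0:
        raise ValueError(f"inconsistent counts: a={a}, b={b}, c={c}, d={d}")
    p_one = float(stats.hypergeom.sf(a - 1, n_universe, size_a, size_b))
    _, p_two = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    significant = (p_one <= p_threshold) and (odds > or_threshold)
    return OverlapResult(a, b, c, d, p_one, float(p_two), float(odds), significant)


def mean_tom(tom_values: np.ndarray, idx: np.ndarray) -> float:
    """Mean off-diagonal TOM among the genes indexed by ``idx``."""
    if len(idx) < 2:
        return float("nan")
    block = tom_values[np.ix_(idx, idx)]
    n = len(idx)
    return float((block.sum() - np.trace(block)) / (n * (n - 1)))


def validate_modules(
    network: Network,
    partition: ModulePartition,
    n_permutations: int = 100,
    rng_seed: int = 0,
    validation_fdr: float = 0.2,
) -> pd.DataFrame:
    """Permutation validation of module tightness.

    For each non-grey module the observed mean within-module TOM is
    compared with ``n_permutations`` random gene sets of the same size
    sampled without replacement from the network genes; the table reports
    observed/null mean/null sd, z, one-sided normal p, BH FDR and a
    significance flag at ``validation_fdr``.  Singleton modules are skipped
    with a flag.
    """
    if n_permutations < 2:
        raise ValueError(f"n_permutations must be >= 2, got {n_permutations}")
    tom_values = network.tom.to_numpy()
    genes = network.tom.index
    labels = partition.labels.loc[genes]
    rng = np.random.default_rng(rng_seed)
    n = len(genes)

    rows = []
    sizes = labels[labels != GREY].value_counts()
    for module in sizes.index:
        size = int(sizes[module])
        if size < 2:
            log.warning("module %s has size %d; skipped from validation", module, size)
            rows.append(
                {"module": module, "size": size, "observed": np.nan, "null_mean": np.nan,
                 "null_sd": np.nan, "z": np.nan, "p": np.nan, "skipped": True}
            )
            continue
        idx = np.flatnonzero((labels == module).to_numpy())
        observed = mean_tom(tom_values, idx)
        null = np.array(
            [mean_tom(tom_values, rng.choice(n, size=size, replace=False))
             for _ in range(n_permutations)]
        )
        null_mean, null_sd = float(null.mean()), float(null.std(ddof=1))
        z = (observed - null_mean) / null_sd if null_sd > 0 else np.inf
        p = float(stats.norm.sf(z))
        rows.append(
            {"module": module, "size": size, "observed": observed, "null_mean": null_mean,
             "null_sd": null_sd, "z": float(z), "p": p, "skipped": False}
        )
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    tested = ~table["skipped"]
    if tested.any():
        table.loc[tested, "fdr"] = bh_fdr(table.loc[tested, "p"].to_numpy())
    table["significant"] = tested & (table["fdr"] <= validation_fdr)
    table.attrs["n_permutations"] = n_permutations
    table.attrs["rng_seed"] = rng_seed
    return table.set_index("module")


def module_de_overlap(
    partition: ModulePartition,
    de_sets: dict[str, GeneSet],
    universe: GeneSet | set,
    p_threshold: float = 0.005,
    or_threshold: float = 3.0,
    include_grey: bool = True,
) -> pd.DataFrame:
    """Fisher overlap of every module against every DE set.

    Returns one row per (module, DE set) with the 2x2 counts, p-values,
    odds ratio and the compound significance flag.  DE genes outside the
    universe are dropped with a logged count; the grey pseudo-module is
    included for completeness but flagged.
    """
    uu = universe.gene_ids if isinstance(universe, GeneSet) else set(universe)
    modules = list(partition.modules) + ([GREY] if include_grey and partition.n_grey else [])
    rows = []
    for set_name, de in de_sets.items():
        de_genes = de.gene_ids & uu
        dropped = len(de.gene_ids) - len(de_genes)
        if dropped:
            log.info("DE set %s: %d genes outside the universe dropped", set_name, dropped)
        for module in modules:
            mod_genes = set(partition.module_genes(module)) & uu
            res = fisher_overlap(mod_genes, de_genes, uu, p_threshold, or_threshold)
            rows.append(
                {
                    "module": module,
                    "de_set": set_name,
                    "module_size": len(mod_genes),
                    "de_size": len(de_genes),
                    "overlap": res.a,
                    "p": res.p_value,
                    "p_two_sided": res.p_two_sided,
                    "odds_ratio": res.odds_ratio,
                    "significant": res.significant and module != GREY,
                    "is_grey": module == GREY,
                }
            )
    return pd.DataFrame(rows)
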