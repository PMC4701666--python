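"""Moderated differential expression for the CIE vs Ctrl time course.

A single 8-group (treatment x time) cell-means model is fitted per gene;
the pooled residual variance is shrunk toward a common prior by empirical
Bayes (method-of-moments fit of a scaled inverse chi-square prior on the
log residual variances), and per-time-point CIE - Ctrl contrasts are
tested with moderated t-statistics on d0 + d_g degrees of freedom.  An
overall moderated one-way F across the 8 groups flags any response to the
design.  Benjamini-Hochberg FDR is applied per contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from cienet.types import TIMEPOINTS, ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Method-of-moments empirical-Bayes variance moderation.

    Fits a scaled inverse chi-square prior (d0, s0^2) to the observed
    residual variances via the moments of log(s2) and returns the prior
    plus the posterior (moderated) variances
    ``(d0*s0^2 + df*s2) / (d0 + df)``.  Genes with zero variance must be
    excluded by the caller.
    """
    s2 = np.asarray(s2, dtype=float)
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    resid_var = e_var - polygamma(1, df / 2.0)
    if resid_var > 0:
        d0 = 2.0 * _trigamma_inverse(resid_var)
        s02 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(e_mean))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
    return d0, s02, s2_post


@dataclass
class DEResult:
    """Per-gene moderated DE statistics for all contrasts of one region.

    ``table`` has, per time point ``tp``, columns ``coef_{tp}``, ``t_{tp}``,
    ``p_{tp}``, ``fdr_{tp}`` plus overall ``F``, ``F_p``, ``F_fdr``; genes
    flagged in ``excluded`` had zero residual variance and carry NaN
    statistics outside the FDR families.
    """

    table: pd.DataFrame
    d0: float
    s02: float
    df_residual: float
    s2: pd.Series
    excluded: list = field(default_factory=list)

    def de_set(self, timepoint: str, threshold: float = 0.01) -> GeneSet:
        col = f"fdr_{timepoint}"
        hits = self.table.index[self.table[col] <= threshold]
        return GeneSet(f"DE_{timepoint}", frozenset(hits))

    def de_sets(self, threshold: float = 0.01) -> dict[str, GeneSet]:
        return {tp: self.de_set(tp, threshold) for tp in TIMEPOINTS}

    @property
    def universe(self) -> GeneSet:
        return GeneSet("universe", frozenset(self.table.index))


def _group_stats(em: ExpressionMatrix):
    groups = em.groups()
    labels = sorted(groups.unique())
    if len(labels) != 8:
        raise ValueError(f"expected 8 treatment x time groups, found {len(labels)}: {labels}")
    x = em.values.to_numpy(dtype=float)
    means, counts = {}, {}
    rss = np.zeros(x.shape[0])
    for g in labels:
        cols = (groups == g).to_numpy()
        n_g = int(cols.sum())
        if n_g < 2:
            raise ValueError(f"group {g!r} has {n_g} samples; need >= 2")
        mg = x[:, cols].mean(axis=1)
        means[g], counts[g] = mg, n_g
        rss += ((x[:, cols] - mg[:, None]) ** 2).sum(axis=1)
    df = em.n_samples - len(labels)
    s2 = rss / df
    return means, counts, s2, float(df)


def fit_de(em: ExpressionMatrix, moderated: bool = True, force_d0: float | None = None) -> DEResult:
    """Fit the 8-group model and compute all moderated contrasts and the
    overall F per gene.

    ``moderated=False`` (or ``force_d0=0``) gives the classical pooled-
    variance statistics; ``force_d0`` overrides the estimated prior degrees
    of freedom, mainly for calibration experiments.
    """
    means, counts, s2, df = _group_stats(em)
    genes = em.values.index
    ok = s2 > 0
    excluded = list(genes[~ok])
    if excluded:
        log.warning("%d constant genes excluded from moderation and FDR", len(excluded))

    if force_d0 is not None:
        d0 = float(force_d0)
        _, s02, _ = squeeze_variances(s2[ok], df) if ok.any() else (0.0, 1.0, None)
        if d0 == 0:
            s2_post_ok = s2[ok]
        elif np.isinf(d0):
            s2_post_ok = np.full(ok.sum(), s02)
        else:
            s2_post_ok = (d0 * s02 + df * s2[ok]) / (d0 + df)
    elif moderated:
        d0, s02, s2_post_ok = squeeze_variances(s2[ok], df)
    else:
        d0, s02, s2_post_ok = 0.0, float("nan"), s2[ok]

    s2_post = np.full(len(genes), np.nan)
    s2_post[ok] = s2_post_ok
    df_total = df + d0 if np.isfinite(d0) else np.inf

    table = pd.DataFrame(index=genes)
    for tp in TIMEPOINTS:
        g_cie, g_ctl = f"CIE:{tp}", f"Ctrl:{tp}"
        coef = means[g_cie] - means[g_ctl]
        c = np.sqrt(1.0 / counts[g_cie] + 1.0 / counts[g_ctl])
        with np.errstate(invalid="ignore", divide="ignore"):
            t = coef / (np.sqrt(s2_post) * c)
        p = np.full(len(genes), np.nan)
        if np.isinf(df_total):  # normal limit of the t distribution
            p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
        else:
            p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total)
        fdr = np.full(len(genes), np.nan)
        fdr[ok] = bh_fdr(p[ok])
        table[f"coef_{tp}"] = coef
        table[f"t_{tp}"] = t
        table[f"p_{tp}"] = p
        table[f"fdr_{tp}"] = fdr

    # overall moderated one-way F across the 8 groups
    n_tot = sum(counts.values())
    grand = sum(counts[g] * means[g] for g in means) / n_tot
    ss_between = sum(counts[g] * (means[g] - grand) ** 2 for g in means)
    df1 = len(means) - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat = (ss_between / df1) / s2_post
    f_p = np.full(len(genes), np.nan)
    if np.isinf(df_total):  # chi-square limit of the F distribution
        f_p[ok] = stats.chi2.sf(f_stat[ok] * df1, df1)
    else:
        f_p[ok] = stats.f.sf(f_stat[ok], df1, df_total)
    f_fdr = np.full(len(genes), np.nan)
    f_fdr[ok] = bh_fdr(f_p[ok])
    table["F"] = f_stat
    table["F_p"] = f_p
    table["F_fdr"] = f_fdr

    return DEResult(
        table=table,
        d0=d0,
        s02=s02,
        df_residual=df,
        s2=pd.Series(s2, index=genes, name="s2"),
        excluded=excluded,
    )


def moderated_t_contrast(
    em: ExpressionMatrix, timepoint: str, moderated: bool = True, force_d0: float | None = None
) -> pd.DataFrame:
    """Moderated CIE vs Ctrl contrast at one time point.

    Returns a per-gene frame with ``log_ratio``, ``t``, ``p``, ``fdr``.  The
    residual variance is pooled across all 8 design cells.
    """
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}; choose from {TIMEPOINTS}")
    res = fit_de(em, moderated=moderated, force_d0=force_d0)
    out = res.table[[f"coef_{timepoint}", f"t_{timepoint}", f"p_{timepoint}", f"fdr_{timepoint}"]]
    return out.set_axis(["log_ratio", "t", "p", "fdr"], axis=1)


def overall_anova(em: ExpressionMatrix, moderated: bool = True) -> pd.DataFrame:
    """Overall one-way F across the 8 treatment x time groups per gene."""
    res = fit_de(em, moderated=moderated)
    return res.table[["F", "F_p", "F_fdr"]]


def select_network_genes(
    f_fdr_tables: dict[str, pd.Series], threshold: float = 0.01
) -> GeneSet:
    """Union, over regions, of genes significant by the overall ANOVA.

    ``f_fdr_tables`` maps region name to a per-gene F FDR series; all
    regions must share the gene universe.
    """
    regions = list(f_fdr_tables)
    if not regions:
        raise ValueError("need at least one region table")
    universe = set(f_fdr_tables[regions[0]].index)
    selected: set = set()
    for region, fdr in f_fdr_tables.items():
        if set(fdr.index) != universe:
            raise ValueError(f"gene universe of region {region!r} differs from {regions[0]!r}")
        hits = set(fdr.index[fdr.to_numpy() <= threshold])
        log.info("region %s: %d genes at F FDR <= %g", region, len(hits), threshold)
        selected |= hits
    if not selected:
        log.warning("no genes significant in any region at F FDR <= %g", threshold)
    log.info("network gene union: %d genes", len(selected))
    return GeneSet("network_genes", frozenset(selected))


def de_set_overlap_counts(sets: dict[str, GeneSet]) -> pd.DataFrame:
    """Symmetric matrix of pairwise intersection sizes between DE sets
    (across time points and/or regions)."""
    names = list(sets)
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            counts.loc[a, b] = len(sets[a].gene_ids & sets[b].gene_ids)
    return counts
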