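"""Normalization and batch adjustment.

The normalization chain mirrors common microarray practice for data
hybridized in batches: quantile-normalize each batch separately, pool the
batches and quantile-normalize again globally, then remove residual batch
effects with a parametric empirical-Bayes location/scale adjustment
(ComBat-style) that protects the treatment x time group means.  A
PCA-based quality view supports visual outlier/batch inspection.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from cienet.types import ExpressionMatrix

log = logging.getLogger(__name__)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean order-statistic distribution.

    After normalization every column's sorted value vector equals the
    across-column mean of order statistics.  Ties within a column receive
    the mean of the reference values at their tied ranks.
    """
    arr = np.asarray(values, dtype=float)
    n, s = arr.shape
    if s < 2:
        log.warning("quantile_normalize: single sample, returning input unchanged")
        return values.copy()
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(s):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        out[order, j] = ref
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < n:  # ties: average the reference over each tied run
            sums = np.bincount(inv, weights=out[:, j])
            counts = np.bincount(inv)
            out[:, j] = (sums / counts)[inv]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _eb_solve(z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-8, max_iter=500):
    """Iterate the empirical-Bayes posterior equations for one batch to a
    fixed point (normal prior on locations, inverse-gamma on scales)."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max(),
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def batch_adjust(
    values: pd.DataFrame,
    batch: pd.Series,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per gene the data are standardized after removing covariate-group means
    (``groups``, normally treatment x time, is protected so the contrasts
    tested downstream survive adjustment), batch locations and scales are
    estimated and shrunk toward method-of-moments priors (normal for
    locations, inverse gamma for scales), and the data are adjusted by
    subtracting the shrunken location and dividing by the shrunken scale
    before de-standardization.
    """
    batch = pd.Series(batch).astype(str)
    batch = batch.set_axis(values.columns)
    levels = sorted(batch.unique())
    if len(levels) < 2:
        return values.copy()
    sizes = batch.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"batches with fewer than 2 samples: {list(small.index)}")

    x = values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    b_design = pd.get_dummies(batch).loc[:, levels].to_numpy(dtype=float)

    if groups is not None:
        groups = pd.Series(groups).astype(str).set_axis(values.columns)
        for g in groups.unique():
            in_g = set(values.columns[groups == g])
            for b in levels:
                in_b = set(values.columns[batch == b])
                if in_g == in_b:
                    raise ValueError(
                        f"batch {b!r} is confounded 1:1 with covariate group {g!r}"
                    )
        g_design = pd.get_dummies(groups, drop_first=True).to_numpy(dtype=float)
        design = np.hstack([b_design, g_design])
    else:
        design = b_design

    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design is rank-deficient: batch confounded with covariates")

    beta = np.linalg.solve(design.T @ design, design.T @ x.T)  # (k, genes)
    n_per_batch = b_design.sum(axis=0)
    grand_mean = (n_per_batch / n_samples) @ beta[: len(levels)]
    stand_mean = np.tile(grand_mean[:, None], (1, n_samples))
    if design.shape[1] > len(levels):
        stand_mean = stand_mean + (design[:, len(levels) :] @ beta[len(levels) :]).T
    var_pooled = ((x - (design @ beta).T) ** 2).mean(axis=1)
    # genes whose residual variance vanishes (model fits them exactly) have
    # nothing left to standardize; pass them through unchanged
    degenerate = var_pooled <= 1e-12
    if degenerate.all():
        log.warning("all genes fit exactly by batch+group model; nothing to adjust")
        return values.copy()
    if degenerate.any():
        log.warning("%d zero-residual genes passed through unadjusted", degenerate.sum())
        keep = ~degenerate
        adjusted_part = batch_adjust(values.loc[keep], batch, groups)
        out = values.copy()
        out.loc[keep] = adjusted_part
        return out
    sd = np.sqrt(var_pooled)[:, None]
    z = (x - stand_mean) / sd

    gamma_hat = np.column_stack([z[:, (batch == b).to_numpy()].mean(axis=1) for b in levels])
    delta_hat = np.column_stack(
        [z[:, (batch == b).to_numpy()].var(axis=1, ddof=1) for b in levels]
    )
    z_adj = np.empty_like(z)
    for i, b in enumerate(levels):
        cols = (batch == b).to_numpy()
        g_bar, t2 = gamma_hat[:, i].mean(), gamma_hat[:, i].var(ddof=1)
        a, bb = _aprior(delta_hat[:, i]), _bprior(delta_hat[:, i])
        g_star, d_star = _eb_solve(z[:, cols], gamma_hat[:, i], delta_hat[:, i], g_bar, t2, a, bb)
        z_adj[:, cols] = (z[:, cols] - g_star[:, None]) / np.sqrt(d_star)[:, None]

    adjusted = z_adj * sd + stand_mean
    return pd.DataFrame(adjusted, index=values.index, columns=values.columns)


def two_stage_normalize(
    data: ExpressionMatrix | Sequence[ExpressionMatrix],
    batch_col: str = "batch",
    protect: bool = True,
) -> ExpressionMatrix:
    """Per-batch quantile normalization, global quantile normalization,
    then empirical-Bayes batch adjustment.

    Accepts either one matrix (split internally on ``batch_col``) or one
    matrix per batch.  With a single batch this reduces to plain quantile
    normalization.
    """
    if isinstance(data, ExpressionMatrix):
        em = data
        parts = [
            em.values.loc[:, em.metadata.index[em.metadata[batch_col] == b]]
            for b in sorted(em.metadata[batch_col].astype(str).unique())
        ]
        metadata = em.metadata.copy()
        sample_order = list(em.values.columns)
    else:
        mats = list(data)
        genes0 = set(mats[0].gene_ids)
        for m in mats[1:]:
            if set(m.gene_ids) != genes0:
                diff = sorted(genes0.symmetric_difference(m.gene_ids), key=str)
                raise ValueError(f"gene ids differ across batches: {diff[:10]}")
        parts = [m.values.loc[mats[0].gene_ids] for m in mats]
        metadata = pd.concat([m.metadata for m in mats])
        sample_order = [s for m in mats for s in m.sample_ids]

    normed = [quantile_normalize(p) if p.shape[1] > 1 else p for p in parts]
    combined = pd.concat(normed, axis=1).loc[:, sample_order]
    combined = quantile_normalize(combined)

    meta = metadata.loc[sample_order]
    batches = meta[batch_col].astype(str)
    if batches.nunique() > 1:
        groups = None
        if protect:
            groups = meta["treatment"].astype(str) + ":" + meta["timepoint"].astype(str)
        combined = batch_adjust(combined, batches, groups)
    return ExpressionMatrix(combined, meta)


def pca_qc(values: pd.DataFrame, n_components: int = 2):
    """Per-sample scores on the leading principal components of the
    gene-centered matrix, plus variance-explained fractions."""
    if values.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    x = values.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    total = (centered**2).sum()
    if total <= 0:
        raise ValueError("constant matrix: no variance for PCA")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        (vt[:k].T * s[:k]),
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    varexp = (s[:k] ** 2) / total
    return scores, varexp
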