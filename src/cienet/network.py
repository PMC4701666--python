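"""Weighted co-expression network construction and module detection.

The network is the unsigned weighted kind standard in co-expression
analysis: adjacency a_ij = |cor(x_i, x_j)|^beta with Pearson correlation
and a soft-thresholding power beta chosen for approximate scale-free
topology, topological overlap

    tom_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

as the similarity for average-linkage clustering of 1 - TOM, and a
deep-split-parameterized tree cut for module detection.  Modules are
summarized by eigengenes (first principal component of the standardized
member genes) and per-gene intramodular connectivity (kIM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from cienet.types import TIMEPOINTS, ExpressionMatrix

log = logging.getLogger(__name__)

#: Module label sequence assigned by decreasing module size; "grey" is
#: reserved for unassigned genes.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

#: Tree-cut schedule per deep-split value: cut height as a fraction of the
#: dendrogram root height, and the compactness ceiling a kept branch must
#: satisfy (its median internal merge height as a fraction of the cut
#: height).  Larger deep split cuts lower and accepts looser branches,
#: yielding more, smaller modules; smaller deep split demands tighter,
#: better-separated cores.
DEEP_SPLIT_SCHEDULE = {
    0: (0.990, 0.90),
    1: (0.985, 0.93),
    2: (0.980, 0.96),
    3: (0.972, 0.98),
}

GREY = "grey"


@dataclass
class Network:
    """Soft-thresholded adjacency (zero diagonal), optional TOM, and
    whole-network connectivity for one region's selected genes."""

    gene_ids: list
    soft_power: int
    adjacency: pd.DataFrame
    tom: pd.DataFrame | None = None
    connectivity: pd.Series | None = None

    @property
    def dissimilarity(self) -> pd.DataFrame:
        if self.tom is None:
            raise ValueError("TOM not computed; call tom() first")
        return 1.0 - self.tom


@dataclass
class ModulePartition:
    """Gene -> module-label map with eigengenes and intramodular connectivity."""

    labels: pd.Series  # gene -> color label, "grey" = unassigned
    deep_split: int
    min_module_size: int
    eigengenes: pd.DataFrame | None = None  # samples x modules
    variance_explained: dict = field(default_factory=dict)
    kim: pd.DataFrame | None = None  # gene x (kim, scaled_kim, module)

    @property
    def modules(self) -> list[str]:
        sizes = self.labels[self.labels != GREY].value_counts()
        return list(sizes.index)

    def module_genes(self, module: str) -> list:
        return list(self.labels.index[self.labels == module])

    @property
    def n_grey(self) -> int:
        return int((self.labels == GREY).sum())


def adjacency(em: ExpressionMatrix | pd.DataFrame, beta: int = 6) -> Network:
    """Unsigned soft-thresholded adjacency |cor|^beta with zero diagonal."""
    values = em.values if isinstance(em, ExpressionMatrix) else em
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = values.index[sd == 0]
    if len(constant):
        raise ValueError(f"constant genes have undefined correlation: {list(constant[:10])}")
    corr = np.corrcoef(x)
    adj = np.abs(np.clip(corr, -1.0, 1.0)) ** beta
    np.fill_diagonal(adj, 0.0)
    adj_df = pd.DataFrame(adj, index=values.index, columns=values.index)
    k = pd.Series(adj.sum(axis=1), index=values.index, name="k")
    return Network(list(values.index), int(beta), adj_df, None, k)


def tom(network: Network) -> Network:
    """Fill the unsigned topological overlap matrix (diagonal 1)."""
    a = network.adjacency.to_numpy()
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_iu a_uj (diagonal a is zero so u != i, j terms dominate)
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = numer / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    network.tom = pd.DataFrame(t, index=network.adjacency.index, columns=network.adjacency.columns)
    return network


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index.

    Bins connectivity into <= ``n_bins`` equal-width bins, regresses
    log10(frequency) on log10(mean connectivity), and returns
    (signed R^2, slope); R^2 is negated when the slope is positive.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return float("nan"), float("nan")
    bins = pd.cut(k, bins=min(n_bins, len(np.unique(k))), duplicates="drop")
    df = pd.DataFrame({"k": k, "bin": bins}).groupby("bin", observed=True)["k"].agg(["mean", "size"])
    df = df[df["size"] > 0]
    if len(df) < 3:
        return float("nan"), float("nan")
    log_k = np.log10(df["mean"].to_numpy())
    log_p = np.log10(df["size"].to_numpy() / k.size)
    res = stats.linregress(log_k, log_p)
    signed_r2 = -np.sign(res.slope) * res.rvalue**2
    return float(signed_r2), float(res.slope)


def pick_soft_threshold(
    em: ExpressionMatrix | pd.DataFrame, powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16)
) -> pd.DataFrame:
    """Scale-free fit report per candidate power: signed R^2, slope, and
    mean/median connectivity."""
    values = em.values if isinstance(em, ExpressionMatrix) else em
    x = values.to_numpy(dtype=float)
    if (x.std(axis=1) == 0).any():
        raise ValueError("constant genes present")
    corr_abs = np.abs(np.clip(np.corrcoef(x), -1.0, 1.0))
    np.fill_diagonal(corr_abs, 0.0)
    rows = []
    for beta in powers:
        if int(beta) != beta or beta < 1:
            raise ValueError(f"powers must be positive integers, got {beta}")
        k = (corr_abs**beta).sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append(
            {
                "power": int(beta),
                "sft_r2": r2,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    return pd.DataFrame(rows).set_index("power")


def _cut_tree(linkage: np.ndarray, n_leaves: int, cut_height: float, core_frac: float):
    """Static cut plus branch-compactness filter.

    Returns cluster ids per leaf (0 = unassigned).  Leaves are grouped by
    the static cut; a branch is kept only if the median of its internal
    merge heights lies below ``core_frac * cut_height``.  Branches produced
    by random agglomeration sit just below the cut and are dissolved;
    genuine modules assemble far lower in the dendrogram.
    """
    assignments = hierarchy.fcluster(linkage, t=cut_height, criterion="distance")
    # per dendrogram node: cluster id if all leaves below share it, else 0
    purity = np.zeros(n_leaves + len(linkage), dtype=int)
    purity[:n_leaves] = assignments
    internal: dict[int, list[float]] = {}
    for i, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        node = n_leaves + i
        pa, pb = purity[a], purity[b]
        if pa == pb and pa != 0:
            purity[node] = pa
            internal.setdefault(pa, []).append(h)
    keep = {
        c: np.median(internal[c]) <= core_frac * cut_height if c in internal else True
        for c in np.unique(assignments)
    }
    return np.where([keep[c] for c in assignments], assignments, 0)


def _purify_membership(
    values: pd.DataFrame,
    raw: np.ndarray,
    kme_threshold: float,
    min_module_size: int,
    n_iter: int = 2,
) -> np.ndarray:
    """Strip weakly attached members: genes whose absolute correlation with
    their branch's eigengene (kME) falls below ``kme_threshold`` go
    unassigned, then undersized branches are dissolved.  Repeated so the
    eigengene is re-estimated on the cleaned membership."""
    lab = raw.copy()
    for _ in range(n_iter):
        changed = False
        for c in np.unique(lab[lab != 0]):
            idx = np.flatnonzero(lab == c)
            eig, _ = module_eigengene(values, values.index[idx])
            x = values.iloc[idx].to_numpy()
            z = x - x.mean(axis=1, keepdims=True)
            norms = np.linalg.norm(z, axis=1) * np.linalg.norm(eig)
            with np.errstate(invalid="ignore"):
                kme = np.abs(z @ eig.to_numpy() / norms)
            drop = idx[~(kme >= kme_threshold)]
            if len(drop):
                lab[drop] = 0
                changed = True
        sizes = pd.Series(lab[lab != 0]).value_counts()
        for c in sizes.index[sizes < min_module_size]:
            lab[lab == c] = 0
            changed = True
        if not changed:
            break
    return lab


def cluster_modules(
    network: Network,
    deep_split: int = 2,
    min_module_size: int = 30,
    expression: pd.DataFrame | None = None,
    kme_threshold: float = 0.5,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a deep-split-scheduled cut.

    The cut height and branch-compactness ceiling follow
    :data:`DEEP_SPLIT_SCHEDULE`; branches smaller than ``min_module_size``
    are left unassigned ("grey").  When ``expression`` is supplied, module
    membership is purified by the eigengene-correlation (kME) filter, which
    removes background genes accreted near the cut height.  Kept modules
    are named by decreasing size along the standard color sequence.
    """
    if deep_split not in DEEP_SPLIT_SCHEDULE:
        raise ValueError(f"deep_split must be one of {sorted(DEEP_SPLIT_SCHEDULE)}")
    diss = network.dissimilarity.to_numpy()
    genes = network.adjacency.index
    n = len(genes)
    if n < min_module_size:
        log.warning("fewer genes (%d) than min_module_size (%d): all grey", n, min_module_size)
        return ModulePartition(
            pd.Series(GREY, index=genes), deep_split, min_module_size
        )
    condensed = squareform(diss, checks=False)
    linkage = hierarchy.average(condensed)
    height_frac, core_frac = DEEP_SPLIT_SCHEDULE[deep_split]
    root_height = linkage[-1, 2]
    raw = _cut_tree(linkage, n, height_frac * root_height, core_frac)

    sizes = pd.Series(raw[raw != 0]).value_counts()
    raw = np.where(np.isin(raw, sizes.index[sizes >= min_module_size]), raw, 0)
    if expression is not None and (raw != 0).any():
        raw = _purify_membership(
            expression.loc[genes], raw, kme_threshold, min_module_size
        )

    sizes = pd.Series(raw[raw != 0]).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    labels = pd.Series(GREY, index=genes, dtype=object)
    for rank, c in enumerate(order):
        name = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels[raw == c] = name
    return ModulePartition(labels, deep_split, min_module_size)


def classical_mds(diss: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson classical multidimensional scaling of a dissimilarity matrix."""
    d2 = np.asarray(diss, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:n_components]
    w_top = w[idx]
    if np.any(w_top <= 0):
        raise ValueError("degenerate embedding: non-positive leading eigenvalues")
    return v[:, idx] * np.sqrt(w_top)


def module_overlap_score(coords: np.ndarray, labels: pd.Series) -> dict[str, float]:
    """Per-module fraction of genes nearer another module's 2-D centroid
    than their own (grey excluded)."""
    mods = [m for m in labels.unique() if m != GREY]
    if not mods:
        return {}
    centroids = {m: coords[(labels == m).to_numpy()].mean(axis=0) for m in mods}
    scores = {}
    for m in mods:
        pts = coords[(labels == m).to_numpy()]
        own = np.linalg.norm(pts - centroids[m], axis=1)
        misassigned = np.zeros(len(pts), dtype=bool)
        for other in mods:
            if other == m:
                continue
            misassigned |= np.linalg.norm(pts - centroids[other], axis=1) < own
        scores[m] = float(misassigned.mean())
    return scores


def select_deep_split(
    network: Network,
    partitions: dict[int, ModulePartition],
    max_overlap: float = 0.05,
) -> int:
    """Choose the deep-split value by the MDS non-overlap criterion.

    Genes are embedded in 2-D by classical MDS of 1 - TOM; a partition is
    non-overlapping when every module's centroid-misassignment fraction is
    <= ``max_overlap``.  The largest non-overlapping deep split wins; if
    none qualifies the partition with the smallest worst-case overlap is
    returned with a warning.
    """
    try:
        coords = classical_mds(network.dissimilarity.to_numpy(), 2)
    except ValueError as exc:
        log.warning("MDS failed (%s); falling back to deep_split 2", exc)
        return 2
    worst = {}
    for ds, part in sorted(partitions.items()):
        scores = module_overlap_score(coords, part.labels)
        worst[ds] = max(scores.values()) if scores else 0.0
    ok = [ds for ds, w in worst.items() if w <= max_overlap]
    if ok:
        return max(ok)
    best = min(worst, key=lambda ds: (worst[ds], -ds))
    log.warning("no deep split met the non-overlap criterion; best is %d (%.3f)", best, worst[best])
    return best


def module_eigengene(
    values: pd.DataFrame, module_genes
) -> tuple[pd.Series, float]:
    """First principal component of the standardized module genes.

    Genes are standardized to mean 0, sd 1 across samples; the eigengene is
    the unit-norm first right singular vector, sign-oriented so it
    correlates positively with the module's mean standardized profile.
    Returns (eigengene per sample, variance explained).
    """
    sub = values.loc[list(module_genes)]
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    x = sub.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        flagged = list(sub.index[sd == 0])
        log.warning("excluding %d zero-variance genes from eigengene: %s", len(flagged), flagged[:5])
        x = x[sd > 0]
        if x.shape[0] == 0:
            raise ValueError("no variable genes in module")
        sd = sd[sd > 0]
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    varexp = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(eig, index=values.columns, name="eigengene"), varexp


def compute_eigengenes(
    values: pd.DataFrame, partition: ModulePartition
) -> ModulePartition:
    """Attach eigengenes and variance explained for every non-grey module."""
    eig = {}
    varexp = {}
    for m in partition.modules:
        eig[m], varexp[m] = module_eigengene(values, partition.module_genes(m))
    partition.eigengenes = pd.DataFrame(eig) if eig else pd.DataFrame(index=values.columns)
    partition.variance_explained = varexp
    return partition


def kim(network: Network, partition: ModulePartition) -> pd.DataFrame:
    """Intramodular connectivity: kIM(g) = sum of adjacencies to same-module
    genes; scaled kIM divides by the module maximum (grey genes get 0)."""
    adj = network.adjacency
    labels = partition.labels.loc[adj.index]
    out = pd.DataFrame(
        {"module": labels, "kim": 0.0, "scaled_kim": 0.0}, index=adj.index
    )
    for m in labels.unique():
        if m == GREY:
            continue
        genes = labels.index[labels == m]
        block = adj.loc[genes, genes].to_numpy()
        k_im = block.sum(axis=1)
        out.loc[genes, "kim"] = k_im
        k_max = k_im.max()
        out.loc[genes, "scaled_kim"] = k_im / k_max if k_max > 0 else 0.0
    partition.kim = out
    return out


def eigengene_timecourse(eigengene: pd.Series, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per treatment x timepoint mean and standard error of an eigengene.

    Returns 8 rows (2 treatments x 4 time points) ordered by time, with
    NaN (and a warning) for empty cells.
    """
    md = metadata.loc[eigengene.index]
    rows = []
    for tp in TIMEPOINTS:
        for trt in ("Ctrl", "CIE"):
            sel = (md["treatment"].astype(str) == trt) & (md["timepoint"].astype(str) == tp)
            vals = eigengene[sel.to_numpy()]
            if len(vals) == 0:
                log.warning("empty cell %s/%s in eigengene time course", trt, tp)
                mean, se, n = np.nan, np.nan, 0
            else:
                mean = float(vals.mean())
                se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
                n = len(vals)
            rows.append({"treatment": trt, "timepoint": tp, "mean": mean, "se": se, "n": n})
    return pd.DataFrame(rows)


def build_network(
    em: ExpressionMatrix,
    beta: int = 6,
    deep_split: int | str = "auto",
    min_module_size: int = 30,
) -> tuple[Network, ModulePartition]:
    """Adjacency -> TOM -> module detection (-> deep-split selection when
    requested) -> eigengenes -> kIM, in one call."""
    values = em.values if isinstance(em, ExpressionMatrix) else em
    net = tom(adjacency(em, beta))
    if deep_split == "auto":
        parts = {
            ds: cluster_modules(net, ds, min_module_size, expression=values)
            for ds in range(4)
        }
        chosen = select_deep_split(net, parts)
        part = parts[chosen]
    else:
        part = cluster_modules(net, int(deep_split), min_module_size, expression=values)
    part = compute_eigengenes(values, part)
    kim(net, part)
    return net, part
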