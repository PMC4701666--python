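"""Synthetic expression data with planted co-expression modules.

The generator emulates the study design — 2 treatments (CIE, Ctrl) x
4 time points (0h, 8h, 72h, 7d) x n replicates — using a latent-factor
model: each planted module m has one factor F_m per sample, and a member
gene g is

    x_gs = mu_g + loading_g * F_m(s) + gamma_g * batch(s) + eps_gs

with eps ~ N(0, noise_sd^2).  For CIE samples F_m carries the module's
kinetic profile (decay, withdrawal peak, biphasic, persistent, or null)
scaled so that a gene with loading 1 is shifted by ``effect_size`` noise
standard deviations at the profile's peak; Ctrl samples carry only the
baseline factor variation.  Background genes are independent noise.
The planted truth (labels, factors, loadings, per-gene group differences)
is returned alongside the matrix for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cienet.types import TIMEPOINTS, ExpressionMatrix

#: Per-time-point weights of the CIE - Ctrl factor shift for each profile.
PROFILES = {
    "null": (0.0, 0.0, 0.0, 0.0),
    "decay": (1.0, 0.5, 0.0, 0.0),
    "withdrawal_peak": (0.25, 1.0, 0.25, 0.0),
    "biphasic": (1.0, 0.0, 0.0, 1.0),
    "persistent": (1.0, 1.0, 1.0, 1.0),
}


@dataclass
class SyntheticDesign:
    """Parameters of the planted-structure generator.

    Defaults give a desk-scale data set — 2,000 genes, five planted modules
    of 100-300 genes covering the five kinetic profiles, 48 samples
    (2 x 4 x 6), two balanced hybridization batches — that runs the whole
    pipeline in minutes while leaving 900 background genes.
    """

    n_genes: int = 2000
    module_sizes: tuple = (100, 150, 200, 250, 300)
    profiles: tuple = ("null", "decay", "withdrawal_peak", "biphasic", "persistent")
    effect_sizes: tuple = (4.0, 4.0, 4.0, 4.0, 4.0)
    n_replicates: int = 6
    loading_range: tuple = (0.5, 1.0)
    noise_sd: float = 0.5
    n_batches: int = 2
    batch_shift_sd: float = 0.4
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    region: str = "PFC"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) != len(self.profiles) or len(self.profiles) != len(
            self.effect_sizes
        ):
            raise ValueError("module_sizes, profiles and effect_sizes must align")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for p in self.profiles:
            if p not in PROFILES:
                raise ValueError(f"unknown profile {p!r}; choose from {sorted(PROFILES)}")
        for e in self.effect_sizes:
            if e < 0:
                raise ValueError("effect sizes must be >= 0")
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("loading_range must lie within (0, 1]")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group for variance estimation")

    @property
    def n_background_genes(self) -> int:
        return self.n_genes - sum(self.module_sizes)

    @property
    def n_samples(self) -> int:
        return 2 * len(TIMEPOINTS) * self.n_replicates


@dataclass
class PlantedTruth:
    """Ground truth of one simulation: labels, factors, loadings, planted shifts."""

    module_labels: pd.Series  # gene -> module name ("background" for noise genes)
    factors: pd.DataFrame  # samples x modules latent factor values
    loadings: pd.Series  # gene -> loading (0 for background)
    batch_coefficients: pd.DataFrame  # genes x batches additive shifts
    planted_diff: pd.DataFrame  # genes x timepoints planted CIE-Ctrl mean difference

    def module_gene_ids(self, module: str) -> list:
        return list(self.module_labels.index[self.module_labels == module])


def _sample_grid(design: SyntheticDesign) -> pd.DataFrame:
    """Balanced sample sheet: treatments x timepoints x replicates, batches
    interleaved within each group so batch is never confounded with a group."""
    rows = []
    i = 0
    for tp in TIMEPOINTS:
        for trt in ("CIE", "Ctrl"):
            for rep in range(design.n_replicates):
                i += 1
                rows.append(
                    {
                        "sample_id": f"S{i:02d}_{trt}_{tp}",
                        "treatment": trt,
                        "timepoint": tp,
                        "batch": f"B{rep % design.n_batches + 1}",
                        "region": design.region,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_expression(design: SyntheticDesign) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Draw one expression matrix plus its planted truth from the design."""
    rng = np.random.default_rng(design.rng_seed)
    meta = _sample_grid(design)
    n, p = design.n_genes, len(meta)
    module_names = [f"M{i + 1}_{prof}" for i, prof in enumerate(design.profiles)]

    gene_ids = [f"g{i + 1:04d}" for i in range(n)]
    labels = np.array(["background"] * n, dtype=object)
    start = 0
    for name, size in zip(module_names, design.module_sizes):
        labels[start : start + size] = name
        start += size

    mu = rng.normal(design.baseline_mean, design.baseline_sd, size=n)
    loadings = np.zeros(n)
    in_module = labels != "background"
    lo, hi = design.loading_range
    # random sign: modules carry both positively and negatively correlated
    # members, as unsigned co-expression analysis expects, and the signed
    # mix keeps per-sample value distributions comparable across groups
    magnitudes = rng.uniform(lo, hi, size=in_module.sum())
    signs = rng.choice([-1.0, 1.0], size=in_module.sum())
    loadings[in_module] = magnitudes * signs

    # latent factors: baseline N(0,1) per sample plus the CIE profile shift
    tp_index = meta["timepoint"].map({tp: i for i, tp in enumerate(TIMEPOINTS)}).to_numpy()
    is_cie = (meta["treatment"] == "CIE").to_numpy()
    factors = pd.DataFrame(
        rng.standard_normal((p, len(module_names))), index=meta.index, columns=module_names
    )
    for name, prof, eff in zip(module_names, design.profiles, design.effect_sizes):
        weights = np.asarray(PROFILES[prof])
        shift = eff * design.noise_sd * weights[tp_index] * is_cie
        factors[name] = factors[name].to_numpy() + shift

    batch_levels = sorted(meta["batch"].unique())
    batch_coef = pd.DataFrame(0.0, index=gene_ids, columns=batch_levels)
    for b in batch_levels[1:]:  # first batch is the reference
        batch_coef[b] = rng.normal(0.0, design.batch_shift_sd, size=n)
    batch_of = meta["batch"].to_numpy()
    batch_term = batch_coef.loc[:, batch_of].to_numpy()

    x = mu[:, None] + batch_term + rng.normal(0.0, design.noise_sd, size=(n, p))
    for j, name in enumerate(module_names):
        sel = labels == name
        x[sel] += np.outer(loadings[sel], factors[name].to_numpy())

    values = pd.DataFrame(x, index=gene_ids, columns=meta.index)
    em = ExpressionMatrix(values, meta.reset_index())

    diff = pd.DataFrame(0.0, index=gene_ids, columns=list(TIMEPOINTS))
    for name, prof, eff in zip(module_names, design.profiles, design.effect_sizes):
        sel = labels == name
        for t, tp in enumerate(TIMEPOINTS):
            diff.loc[sel, tp] = loadings[sel] * eff * design.noise_sd * PROFILES[prof][t]

    truth = PlantedTruth(
        module_labels=pd.Series(labels, index=gene_ids, name="module"),
        factors=factors,
        loadings=pd.Series(loadings, index=gene_ids, name="loading"),
        batch_coefficients=batch_coef,
        planted_diff=diff,
    )
    return em, truth


# --- synthetic 3'UTR-like sequences for the seed-complement scan -----------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _seed_kmers(motif: str, k_min: int) -> set[str]:
    """Reverse complements of every window of length >= k_min within the
    motif's first 8 bases; a sequence free of the shortest windows is free
    of all longer ones."""
    m8 = motif[:8]
    k = min(k_min, len(m8))
    return {reverse_complement(m8[i : i + k]) for i in range(len(m8) - k + 1)}


def simulate_utr_sequences(
    n_seqs: int,
    length: int,
    motif: str,
    planted_fraction: float,
    rng_seed: int = 0,
) -> list[str]:
    """Random A/C/G/T sequences, a fixed fraction carrying the motif's
    reverse complement.

    Exactly ``round(planted_fraction * n_seqs)`` sequences contain at least
    one copy of the reverse complement of ``motif``; the rest are
    rejection-sampled to contain no reverse complement of any >= 6-base
    window of the motif's first 8 bases, so match fractions at seed lengths
    6-8 are exactly the planted fraction.
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif contains non-ACGT characters: {motif}")
    if len(motif) >= length:
        raise ValueError(f"motif length {len(motif)} must be < sequence length {length}")
    if not (0.0 <= planted_fraction <= 1.0):
        raise ValueError(f"planted_fraction must lie in [0, 1], got {planted_fraction}")

    rng = np.random.default_rng(rng_seed)
    n_planted = int(round(planted_fraction * n_seqs))
    forbidden = _seed_kmers(motif, 6)
    rc = reverse_complement(motif)
    bases = np.array(list("ACGT"))

    def clean_sequence() -> str:
        while True:
            s = "".join(rng.choice(bases, size=length))
            if not any(f in s for f in forbidden):
                return s

    seqs = []
    for i in range(n_seqs):
        if i < n_planted:
            s = clean_sequence()
            pos = int(rng.integers(0, length - len(rc) + 1))
            seqs.append(s[:pos] + rc + s[pos + len(rc) :])
        else:
            seqs.append(clean_sequence())
    order = rng.permutation(n_seqs)
    return [seqs[i] for i in order]
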