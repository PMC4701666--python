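"""Hub-gene candidate ranking and the microRNA seed-complement scan.

Candidate genes are those that entered the network analysis and are
differentially expressed at the first (0h) or last (7d) time point —
the time points that bracket immediate and persistent responses — ranked
by scaled intramodular connectivity so the most central (hub-like) genes
come first.  The seed scan reports, for a set of 3'UTR-like sequences,
the fraction containing the reverse complement of a microRNA seed of a
given length, the readout used to flag candidate microRNA regulation of a
module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from cienet.diffexpr import DEResult
from cienet.simulate import reverse_complement

log = logging.getLogger(__name__)


def rank_candidates(
    kim_table: pd.DataFrame,
    de_result: DEResult,
    timepoints: tuple[str, ...] = ("0h", "7d"),
    fdr_threshold: float = 0.01,
    top_n: int = 30,
) -> pd.DataFrame:
    """Top hub candidates among DE genes at the queried time points.

    Keeps genes with DE FDR <= ``fdr_threshold`` at *any* of ``timepoints``,
    sorts by scaled kIM descending with lexicographic gene-id tie-break,
    and returns the first ``top_n`` rows with their module, connectivity
    and per-timepoint FDR.
    """
    genes = kim_table.index.intersection(de_result.table.index)
    fdr_cols = {tp: f"fdr_{tp}" for tp in timepoints}
    for col in fdr_cols.values():
        if col not in de_result.table.columns:
            raise ValueError(f"DE result lacks column {col}")
    fdr = de_result.table.loc[genes, list(fdr_cols.values())]
    passing = (fdr <= fdr_threshold).any(axis=1)
    selected = genes[passing.to_numpy()]
    if len(selected) == 0:
        log.warning("no gene passes FDR <= %g at %s", fdr_threshold, timepoints)
        cols = ["module", "scaled_kim", "kim"] + [f"fdr_{tp}" for tp in timepoints]
        return pd.DataFrame(columns=cols)
    out = kim_table.loc[selected, ["module", "kim", "scaled_kim"]].copy()
    for tp, col in fdr_cols.items():
        out[col] = de_result.table.loc[selected, col]
    # descending scaled kIM with ascending gene-id tie-break
    out = out.iloc[
        sorted(range(len(out)), key=lambda i: (-out["scaled_kim"].iloc[i], str(out.index[i])))
    ]
    return out.head(top_n)


@dataclass
class SeedScanResult:
    """Outcome of a seed-complement scan over a sequence set."""

    motif: str
    k: int
    matches: pd.Series  # per-sequence boolean
    fraction: float


def seed_match_fraction(sequences, motif: str, k: int = 8) -> SeedScanResult:
    """Fraction of sequences containing a length-``k`` seed complement.

    A sequence matches when it contains the reverse complement of any
    length-``k`` window of the motif's first 8 bases (the seed region).
    Shorter ``k`` can only add matches, so the fraction is non-increasing
    in ``k``.
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        pos = next(i for i, ch in enumerate(motif) if ch not in "ACGT")
        raise ValueError(f"non-ACGT character {motif[pos]!r} at motif position {pos}")
    seed = motif[:8]
    if k > len(seed):
        raise ValueError(f"k={k} exceeds seed length {len(seed)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    targets = {reverse_complement(seed[i : i + k]) for i in range(len(seed) - k + 1)}

    if isinstance(sequences, dict):
        names, seqs = list(sequences), list(sequences.values())
    else:
        seqs = list(sequences)
        names = list(range(len(seqs)))
    hits = []
    for name, s in zip(names, seqs):
        s = s.upper()
        bad = set(s) - set("ACGT")
        if bad:
            pos = next(i for i, ch in enumerate(s) if ch in bad)
            raise ValueError(f"non-ACGT character {s[pos]!r} at position {pos} of sequence {name}")
        hits.append(any(t in s for t in targets))
    matches = pd.Series(hits, index=names, name="match")
    fraction = float(matches.mean()) if len(matches) else float("nan")
    return SeedScanResult(motif, k, matches, fraction)
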