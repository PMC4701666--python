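"""Readers and writers for expression TSV, sample metadata, and GMT gene sets."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from cienet.types import METADATA_COLUMNS, ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)


def read_expression(path, metadata_path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample-metadata TSV.

    The expression file has a header row of sample ids and gene ids in the
    first column.  The metadata file must contain the columns
    ``sample_id, treatment, timepoint, batch, region``.  Every sample column
    must have a metadata row; the reverse is not required (extra metadata
    rows are dropped).
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    bad = values.columns[values.dtypes == object]
    for col in bad:
        coerced = pd.to_numeric(values[col], errors="coerce")
        if coerced.isna().any():
            gene = values.index[coerced.isna().to_numpy().argmax()]
            raise ValueError(
                f"non-numeric expression value at gene {gene!r}, sample {col!r} in {path}"
            )
        values[col] = coerced

    metadata = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing_cols:
        raise ValueError(f"metadata file {metadata_path} lacks columns: {missing_cols}")
    metadata = metadata.set_index("sample_id")
    absent = [s for s in values.columns if s not in metadata.index]
    if absent:
        raise ValueError(f"samples missing from metadata: {absent}")
    return ExpressionMatrix(values, metadata.loc[list(values.columns)])


def write_expression(em: ExpressionMatrix, path, metadata_path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id")
    em.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def write_gene_sets(sets: list[GeneSet], path) -> None:
    """Write gene sets in GMT format: name, description, then gene ids, tab-separated."""
    names = [s.name for s in sets]
    dup = {n for n in names if names.count(n) > 1}
    if dup:
        raise ValueError(f"duplicate gene set names: {sorted(dup)}")
    if not sets:
        log.warning("writing empty gene set list to %s", path)
    with open(path, "w") as fh:
        for s in sets:
            genes = sorted(s.gene_ids, key=str)
            fh.write("\t".join([s.name, s.description or "na", *map(str, genes)]) + "\n")


def read_gene_sets(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            name, desc, genes = parts[0], parts[1], parts[2:]
            sets.append(GeneSet(name, frozenset(genes), "" if desc == "na" else desc))
    return sets


def write_fasta(sequences: dict[str, str] | list[str], path) -> None:
    if not isinstance(sequences, dict):
        sequences = {f"seq{i + 1}": s for i, s in enumerate(sequences)}
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
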