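"""Shared domain types: expression container, gene sets, run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

#: Ordered time points of the exposure/withdrawal design.
TIMEPOINTS = ("0h", "8h", "72h", "7d")

#: Treatment arms: chronic intermittent ethanol vs air control.
TREATMENTS = ("CIE", "Ctrl")

#: Metadata columns every sample table must provide.
METADATA_COLUMNS = ("sample_id", "treatment", "timepoint", "batch", "region")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale expression with sample metadata.

    ``values`` is a :class:`pandas.DataFrame` indexed by gene id with one
    column per sample; ``metadata`` is indexed by sample id and aligned
    one-to-one with the columns of ``values``.  Values are assumed to be on
    the log2 scale already (RMA-style summaries); no stage re-logs them.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        self.metadata = pd.DataFrame(self.metadata)
        if "sample_id" in self.metadata.columns:
            self.metadata = self.metadata.set_index("sample_id")
        self.validate()
        # keep metadata rows in column order
        self.metadata = self.metadata.loc[list(self.values.columns)]
        if "timepoint" in self.metadata.columns:
            self.metadata["timepoint"] = pd.Categorical(
                self.metadata["timepoint"].astype(str),
                categories=list(TIMEPOINTS),
                ordered=True,
            )

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            ii, jj = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.values.index[ii]!r}, "
                f"sample {self.values.columns[jj]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> pd.Series:
        """Treatment x timepoint group label per sample (e.g. ``CIE:8h``)."""
        md = self.metadata
        return md["treatment"].astype(str) + ":" + md["timepoint"].astype(str)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.metadata.copy())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.metadata.copy())

    def equals(self, other: "ExpressionMatrix", tol: float = 0.0) -> bool:
        if self.gene_ids != other.gene_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self.values.to_numpy(), other.values.to_numpy()
        return bool(np.allclose(a, b, atol=tol, rtol=0.0))


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (GMT-style)."""

    name: str
    gene_ids: frozenset = field(default_factory=frozenset)
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        if not self.name:
            raise ValueError("gene set name must be nonempty")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class RunConfig:
    """Pipeline thresholds and tuning constants.

    Defaults follow the study's printed choices: DE significance at
    FDR <= 0.01, soft power 6, 100 permutations with validation FDR <= 0.2,
    and the compound overlap rule p <= 0.005 with odds ratio > 3.
    """

    de_fdr_threshold: float = 0.01
    soft_power: int = 6
    deep_split: int | str = "auto"
    min_module_size: int = 30
    n_permutations: int = 100
    validation_fdr: float = 0.2
    overlap_p: float = 0.005
    overlap_or: float = 3.0
    rng_seed: int = 0
    protect_covariates: bool = True
    top_n_candidates: int = 30

    def __post_init__(self) -> None:
        for name in ("de_fdr_threshold", "validation_fdr", "overlap_p"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if int(self.soft_power) != self.soft_power or self.soft_power < 1:
            raise ValueError(f"soft_power must be a positive integer, got {self.soft_power}")
        if self.deep_split != "auto" and self.deep_split not in (0, 1, 2, 3):
            raise ValueError(f"deep_split must be 0-3 or 'auto', got {self.deep_split}")
        if self.n_permutations < 2:
            raise ValueError(f"n_permutations must be >= 2, got {self.n_permutations}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})
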