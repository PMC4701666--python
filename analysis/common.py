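"""Shared setup for the numbered analysis drivers.

One deterministic study cohort — the default synthetic design (2,000 genes,
five planted modules covering the five kinetic profiles, 48 samples in two
hybridization batches) — is regenerated from COHORT_SEED by every driver,
so each script is self-contained and the repository carries no bulky
intermediate matrices.
"""

from pathlib import Path

from cienet.preprocess import two_stage_normalize
from cienet.simulate import SyntheticDesign, simulate_expression

COHORT_SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def cohort():
    """The simulated single-region (PFC-like) cohort plus planted truth."""
    return simulate_expression(SyntheticDesign(rng_seed=COHORT_SEED))


def normalized_cohort():
    em, truth = cohort()
    return two_stage_normalize(em), truth


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
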