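"""End-to-end driver: normalization -> DE -> network -> validation ->
overlap -> candidates, per brain region, with a machine-readable manifest."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from cienet import diffexpr, network, preprocess
from cienet.candidates import rank_candidates
from cienet.enrichment import module_de_overlap, validate_modules
from cienet.types import ExpressionMatrix, RunConfig

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(
    regions: dict[str, ExpressionMatrix],
    config: RunConfig,
    outdir,
) -> dict[str, dict[str, Path]]:
    """Run the full analysis for one or more regions.

    ``regions`` maps region name to its (raw) expression matrix.  Per
    region the stages are: two-stage normalization with batch adjustment,
    moderated DE with overall ANOVA, network-gene selection (union of
    ANOVA-significant genes across regions), network construction and
    module detection, permutation validation, module-DE overlap, eigengene
    time courses, and hub-candidate ranking.  All result tables are TSV;
    a JSON manifest records the configuration and seed.
    """
    if not regions:
        raise PipelineError("stage 'input' failed: no regions provided")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    normalized = {
        r: _stage(f"normalize[{r}]", preprocess.two_stage_normalize, em,
                  protect=config.protect_covariates)
        for r, em in regions.items()
    }
    de_results = {r: _stage(f"de[{r}]", diffexpr.fit_de, em) for r, em in normalized.items()}
    universe = _stage(
        "select_network_genes",
        diffexpr.select_network_genes,
        {r: res.table["F_fdr"] for r, res in de_results.items()},
        config.de_fdr_threshold,
    )

    written: dict[str, dict[str, Path]] = {}
    for r, em in normalized.items():
        rdir = outdir / r
        rdir.mkdir(exist_ok=True)
        paths: dict[str, Path] = {}
        de_res = de_results[r]
        paths["de"] = rdir / "de_results.tsv"
        de_res.table.to_csv(paths["de"], sep="\t", index_label="gene_id")

        net_genes = [g for g in em.gene_ids if g in universe.gene_ids]
        if len(net_genes) < 3:
            raise PipelineError(
                f"stage 'network[{r}]' failed: only {len(net_genes)} genes selected"
            )
        sub = em.subset_genes(net_genes)
        net, part = _stage(
            f"network[{r}]", network.build_network, sub, config.soft_power,
            config.deep_split, config.min_module_size,
        )
        paths["modules"] = rdir / "module_assignments.tsv"
        mod_table = pd.DataFrame({"module": part.labels})
        mod_table.to_csv(paths["modules"], sep="\t", index_label="gene_id")

        paths["eigengenes"] = rdir / "eigengenes.tsv"
        part.eigengenes.to_csv(paths["eigengenes"], sep="\t", index_label="sample_id")

        timecourses = []
        for m in part.modules:
            tc = network.eigengene_timecourse(part.eigengenes[m], em.metadata)
            tc.insert(0, "module", m)
            timecourses.append(tc)
        paths["eigengene_timecourse"] = rdir / "eigengene_timecourse.tsv"
        (pd.concat(timecourses) if timecourses else pd.DataFrame(
            columns=["module", "treatment", "timepoint", "mean", "se", "n"]
        )).to_csv(paths["eigengene_timecourse"], sep="\t", index=False)

        validation = _stage(
            f"validate[{r}]", validate_modules, net, part,
            config.n_permutations, config.rng_seed, config.validation_fdr,
        )
        paths["validation"] = rdir / "module_validation.tsv"
        validation.to_csv(paths["validation"], sep="\t")

        de_sets = de_res.de_sets(config.de_fdr_threshold)
        net_universe = set(net_genes)
        de_sets_in = {
            tp: s for tp, s in de_sets.items()
        }
        overlap = _stage(
            f"overlap[{r}]", module_de_overlap, part,
            {tp: _restrict(s, net_universe) for tp, s in de_sets_in.items()},
            net_universe, config.overlap_p, config.overlap_or,
        )
        paths["overlap"] = rdir / "module_de_overlap.tsv"
        overlap.to_csv(paths["overlap"], sep="\t", index=False)

        cand = _stage(
            f"candidates[{r}]", rank_candidates, part.kim, de_res,
            ("0h", "7d"), config.de_fdr_threshold, config.top_n_candidates,
        )
        paths["candidates"] = rdir / "candidates.tsv"
        cand.to_csv(paths["candidates"], sep="\t", index_label="gene_id")
        written[r] = paths

    manifest = {
        "config": config.to_dict(),
        "regions": {
            r: {"n_genes": em.n_genes, "n_samples": em.n_samples} for r, em in regions.items()
        },
        "network_universe_size": len(universe.gene_ids),
        "outputs": {r: {k: str(v) for k, v in p.items()} for r, p in written.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return written


def _restrict(gene_set, universe: set):
    from cienet.types import GeneSet

    return GeneSet(gene_set.name, frozenset(gene_set.gene_ids & universe))
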