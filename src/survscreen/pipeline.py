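"""End-to-end pipeline: simulate -> (reads -> quantify) -> score -> rank -> evaluate.

One flat YAML config drives every stage so a run is fully described by a
single reproducible record; identical config + seed yields byte-identical
artifacts on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .config import SimulationConfig
from .counts import CountTable, merge_counts, write_counts
from .evaluate import DepletionSummary, RecoveryReport, depletion_summary, evaluate_recovery
from .library import GuideLibrary, simulate_library, write_library
from .quant import build_spacer_index, quantify_reads
from .scoring import (
    RankedGeneList,
    ScoringParams,
    call_hits,
    fold_representation,
    rank_genes,
    read_gene_list,
    score_genes,
    write_hit_table,
)
from .simulate import ScreenTruth, assign_truth, generate_reads, simulate_counts, write_truth

log = logging.getLogger("survscreen")

#: Demo screen: 1000 genes, 20 planted resistance hits, survivor bottleneck
#: at sigma0 = 0.05 with 200 founder cells per guide, 500 reads per guide.
DEMO_CONFIG: dict = {
    "n_genes": 1000,
    "n_hits": 20,
    "rng_seed": 42,
    "simulate_reads": False,
}

_SIM_KEYS = {
    "n_genes",
    "guides_per_gene",
    "spacer_length",
    "abundance_log_sd",
    "cells_per_guide",
    "read_depth_control",
    "read_depth_treated",
    "reads_per_guide",
    "n_hits",
    "baseline_survival",
    "hit_survival_range",
    "efficiency_beta",
    "rng_seed",
    "gene_names",
}
_SCORE_KEYS = {
    "fold_threshold",
    "threshold_inclusive",
    "min_overrep_fraction",
    "fraction_inclusive",
    "denominator_mode",
    "pseudocount",
}
_PIPE_KEYS = {
    "simulate_reads",
    "error_rate",
    "max_mismatches",
    "read_prefix",
    "read_suffix",
    "gene_list",
    "plot",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineResult:
    """In-memory handles to everything a pipeline run produced."""

    library: GuideLibrary
    truth: ScreenTruth
    counts: CountTable
    scores: pd.DataFrame
    ranked: RankedGeneList
    hits: set[str]
    recovery: RecoveryReport
    depletion: DepletionSummary
    outdir: Optional[Path] = None


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineError(f"config {path} is not a flat key-value mapping")
    return cfg


def _split_config(cfg: dict) -> tuple[SimulationConfig, ScoringParams, dict]:
    unknown = set(cfg) - _SIM_KEYS - _SCORE_KEYS - _PIPE_KEYS
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    sim_kwargs = {k: v for k, v in cfg.items() if k in _SIM_KEYS}
    for key in ("guides_per_gene", "hit_survival_range", "efficiency_beta"):
        if key in sim_kwargs and isinstance(sim_kwargs[key], list):
            sim_kwargs[key] = tuple(sim_kwargs[key])
    score_kwargs = {k: v for k, v in cfg.items() if k in _SCORE_KEYS}
    pipe = {k: v for k, v in cfg.items() if k in _PIPE_KEYS}
    return SimulationConfig(**sim_kwargs), ScoringParams(**score_kwargs), pipe


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full screen pipeline from one config.

    ``config`` is a flat mapping (or path to a YAML file of one) combining
    simulation parameters, scoring thresholds and pipeline switches
    (``simulate_reads``, ``error_rate``, ``max_mismatches``, ``gene_list``,
    ``plot``). When ``outdir`` is given, every artifact (library, truth,
    counts, optional FASTQ, hit table, ranked list, recovery report, run
    parameters) is written there.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    sim_config, params, pipe = _split_config(config)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    log.info("effective simulation parameters: %s", sim_config.to_dict())
    log.info("effective scoring parameters: %s", params)
    log.info("pipeline switches: %s", pipe)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    library = stage("simulate_library", simulate_library, sim_config)
    truth = stage("assign_truth", assign_truth, library, sim_config)
    counts = stage("simulate_counts", simulate_counts, library, truth, sim_config)

    if pipe.get("simulate_reads", False):
        if out is None:
            raise PipelineError("stage 'generate_reads' failed: needs an outdir")
        error_rate = float(pipe.get("error_rate", 0.0))
        max_mm = int(pipe.get("max_mismatches", 0))
        prefix = pipe.get("read_prefix", "")
        suffix = pipe.get("read_suffix", "")
        index = stage("build_spacer_index", build_spacer_index, library)
        per_condition = []
        for cond in counts.conditions:
            fq = out / f"reads_{cond}.fastq.gz"
            stage(
                "generate_reads",
                generate_reads,
                counts,
                library,
                cond,
                fq,
                prefix=prefix,
                suffix=suffix,
                error_rate=error_rate,
                rng_seed=sim_config.rng_seed,
            )
            per_condition.append(
                stage(
                    "quantify_reads",
                    quantify_reads,
                    fq,
                    index,
                    library,
                    cond,
                    spacer_offset=len(prefix),
                    max_mismatches=max_mm,
                )
            )
        counts_for_scoring = stage("merge_counts", merge_counts, per_condition)
    else:
        counts_for_scoring = counts

    folds = stage("fold_representation", fold_representation, counts_for_scoring, params)
    scores = stage("score_genes", score_genes, folds, library, params)
    hits = stage("call_hits", call_hits, scores)

    gene_filter = None
    filter_name = None
    if pipe.get("gene_list"):
        filter_name = str(pipe["gene_list"])
        gene_filter = stage("read_gene_list", read_gene_list, filter_name)
    ranked = stage("rank_genes", rank_genes, scores, gene_filter, filter_name)

    recovery = stage(
        "evaluate_recovery", evaluate_recovery, hits, truth, scores, library
    )
    depletion = stage("depletion_summary", depletion_summary, counts_for_scoring)

    if out is not None:
        write_library(library, out / "library.tsv")
        write_truth(truth, out / "truth_genes.tsv", out / "truth_guides.tsv")
        write_counts(counts_for_scoring, out / "counts.tsv")
        write_hit_table(scores, folds, library, out / "hit_table.tsv")
        ranked.frame.to_csv(out / "ranked_genes.tsv", sep="\t")
        recovery.per_gene.to_csv(out / "recovery_per_gene.tsv", sep="\t")
        with open(out / "recovery.json", "w") as fh:
            json.dump(recovery.to_dict(), fh, indent=2)
        with open(out / "run_params.yaml", "w") as fh:
            yaml.safe_dump(
                {**sim_config.to_dict(), **params.__dict__, **pipe}, fh
            )
        if pipe.get("plot", False):
            from .plotting import plot_rank_vs_pct

            stage("plot", plot_rank_vs_pct, ranked, out / "rank_vs_pct.png")
        for artifact in sorted(out.iterdir()):
            log.info("artifact: %s", artifact)

    log.info(
        "called %d hits; sensitivity=%.3f precision=%.3f; dropout ratio=%.4f",
        len(hits),
        recovery.sensitivity,
        recovery.precision,
        depletion.ratio,
    )
    return PipelineResult(
        library=library,
        truth=truth,
        counts=counts_for_scoring,
        scores=scores,
        ranked=ranked,
        hits=hits,
        recovery=recovery,
        depletion=depletion,
        outdir=out,
    )
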