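"""Synthetic stand-in for a published per-gene screen fold table.

The real screen's per-gene summary table is not redistributable, so tests
that exercise the load-table -> recompute-statistics -> rank path run on a
stand-in generated here by the package's own simulator. Its planted
structure mirrors the qualitative shape of a genome-wide survivor screen in
a neutrophil-like cell line: ~1000 genes with 5-6 guides each, a handful of
strong resistance hits including two linker-histone H1 family genes
(HIST1H1E with perfect guide concordance and the strongest enrichment,
HIST1H1C close behind) alongside known NADPH-oxidase/differentiation genes
(CYBB, NCF1, MPO, CEBPD). Everything here is simulated; no value is taken
from any experimental dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from survscreen import (
    ScoringParams,
    ScreenTruth,
    SimulationConfig,
    fold_representation,
    score_genes,
    simulate_counts,
    simulate_library,
    write_hit_table,
)

NAMED_HITS = ["HIST1H1E", "HIST1H1C", "CYBB", "NCF1", "MPO", "CEBPD"]


def build_synthetic_source_table(path, n_genes: int = 1000, seed: int = 2024):
    """Simulate a screen with named planted hits and write its hit table.

    Returns (library, truth, scores, folds) for cross-checking.
    """
    rng = np.random.default_rng(seed)
    generic = [f"GENE{i + 1:04d}" for i in range(n_genes - len(NAMED_HITS))]
    names = NAMED_HITS + generic
    cfg = SimulationConfig(
        n_genes=n_genes, rng_seed=seed, gene_names=names, reads_per_guide=500
    )
    library = simulate_library(cfg)

    sigma = pd.Series(
        cfg.baseline_survival, index=pd.Index(library.gene_ids, name="gene_id")
    )
    # two H1-family genes as the strongest hits, HIST1H1E on top
    sigma["HIST1H1E"] = 1.0
    sigma["HIST1H1C"] = 0.9
    for g in ("CYBB", "NCF1", "MPO", "CEBPD"):
        sigma[g] = rng.uniform(0.5, 0.8)
    extra = rng.choice(generic, size=14, replace=False)
    sigma[extra] = rng.uniform(0.5, 0.8, size=14)

    a, b = cfg.efficiency_beta
    eps = pd.Series(
        rng.beta(a, b, size=library.n_guides),
        index=pd.Index(library.frame["guide_id"], name="guide_id"),
    )
    # perfect cutting for the H1 guides: every guide concordantly enriched
    h1_guides = library.frame["gene_id"].isin(["HIST1H1E", "HIST1H1C"]).to_numpy()
    eps[h1_guides] = 1.0

    truth = ScreenTruth(
        baseline_survival=cfg.baseline_survival,
        gene_survival=sigma,
        guide_efficiency=eps,
    )
    counts = simulate_counts(library, truth, cfg)
    params = ScoringParams()
    folds = fold_representation(counts, params)
    scores = score_genes(folds, library, params)
    write_hit_table(scores, folds, library, path)
    return library, truth, scores, folds
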