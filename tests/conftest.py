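from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from survscreen import CountTable, GuideLibrary, SimulationConfig, simulate_library


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=10, rng_seed=1)


@pytest.fixture
def small_library(small_config) -> GuideLibrary:
    return simulate_library(small_config)


def make_count_table(
    counts: dict[str, tuple[int, int]], guide_to_gene: dict[str, str]
) -> CountTable:
    """Build a two-condition CountTable from explicit per-guide counts."""
    guides = list(counts)
    frame = pd.DataFrame(
        {
            "gene_id": [guide_to_gene[g] for g in guides],
            "control": [counts[g][0] for g in guides],
            "treated": [counts[g][1] for g in guides],
        },
        index=pd.Index(guides, name="guide_id"),
    )
    return CountTable(frame=frame)


def random_count_instance(rng: np.random.Generator, n_genes: int):
    """A random screen-shaped count table: 5-6 guides/gene, skewed counts,
    occasional zeros so NA/inf fold cases arise."""
    counts: dict[str, tuple[int, int]] = {}
    guide_to_gene: dict[str, str] = {}
    for j in range(n_genes):
        gene = f"G{j:04d}"
        for i in range(int(rng.integers(5, 7))):
            guide = f"{gene}_g{i + 1}"
            c = int(rng.poisson(30)) if rng.random() > 0.05 else 0
            t = int(rng.poisson(30)) if rng.random() > 0.15 else 0
            counts[guide] = (c, t)
            guide_to_gene[guide] = gene
    return counts, guide_to_gene


def library_from_mapping(guide_to_gene: dict[str, str], spacer_length: int = 20) -> GuideLibrary:
    """Deterministic distinct spacers for an explicit guide->gene mapping."""
    bases = "ACGT"
    rows = []
    for k, (guide, gene) in enumerate(guide_to_gene.items()):
        digits = []
        x = k
        for _ in range(spacer_length):
            digits.append(bases[x % 4])
            x //= 4
        rows.append((guide, gene, "".join(digits)))
    return GuideLibrary.from_frame(
        pd.DataFrame(rows, columns=["guide_id", "gene_id", "spacer"])
    )
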