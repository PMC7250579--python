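"""Generative model of a pooled CRISPR knockout survival screen.

The screen is simulated in five stages, each with a closed-form expectation
so downstream scoring can be verified analytically:

1. baseline relative guide abundance ``a_g`` ~ log-normal(0, abundance_log_sd),
   normalised to sum to 1 (library skew from cloning and outgrowth);
2. founder cells ``C_g`` ~ Poisson(cells_per_guide * a_g * n_guides), one
   integrated guide per cell (MOI < 1 idealised to exactly one);
3. control reads ~ Multinomial(read_depth_control, p proportional to C_g);
4. survivors ``S_g`` ~ Binomial(C_g, p_g) with per-cell survival
   ``p_g = eps_g * sigma_j + (1 - eps_g) * sigma0`` for guide g of gene j —
   a cell survives the lethal stimulus at the knockout rate sigma_j if the
   guide actually disrupted the gene (probability eps_g), else at the
   baseline rate sigma0; this bottleneck is what produces guide dropout;
5. treated reads ~ Multinomial(read_depth_treated, p proportional to S_g).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig, SimulationError
from .counts import CountTable
from .library import DNA_ALPHABET, GuideLibrary


@dataclass(frozen=True)
class ScreenTruth:
    """Ground truth of a simulated screen.

    ``gene_survival`` maps every gene to its knockout survival probability
    sigma_j (equal to ``baseline_survival`` for neutral genes);
    ``guide_efficiency`` maps every guide to its knockout efficiency
    epsilon in [0, 1].
    """

    baseline_survival: float
    gene_survival: pd.Series
    guide_efficiency: pd.Series

    def __post_init__(self) -> None:
        s = self.gene_survival
        if ((s < 0) | (s > 1)).any():
            raise ValueError("gene survival probabilities must lie in [0, 1]")
        e = self.guide_efficiency
        if ((e < 0) | (e > 1)).any():
            raise ValueError("guide efficiencies must lie in [0, 1]")

    @property
    def hit_genes(self) -> set[str]:
        """Genes whose knockout changes survival relative to baseline."""
        return set(self.gene_survival.index[self.gene_survival != self.baseline_survival])

    @property
    def resistance_genes(self) -> set[str]:
        """Hits whose knockout increases survival (sigma_j > sigma0)."""
        return set(self.gene_survival.index[self.gene_survival > self.baseline_survival])

    @property
    def sensitizer_genes(self) -> set[str]:
        """Hits whose knockout decreases survival (sigma_j < sigma0)."""
        return set(self.gene_survival.index[self.gene_survival < self.baseline_survival])


def assign_truth(library: GuideLibrary, config: SimulationConfig) -> ScreenTruth:
    """Assign survival effects to genes and efficiencies to guides.

    Exactly ``config.n_hits`` genes (chosen uniformly without replacement)
    receive a survival probability drawn uniformly from
    ``config.hit_survival_range``; all others keep ``baseline_survival``
    exactly. Deterministic under ``config.rng_seed``.
    """
    rng = np.random.default_rng([0x7247, config.rng_seed])
    genes = library.gene_ids
    if config.n_hits > len(genes):
        raise ValueError(f"n_hits={config.n_hits} exceeds {len(genes)} genes")
    sigma = pd.Series(config.baseline_survival, index=pd.Index(genes, name="gene_id"))
    hit_idx = rng.choice(len(genes), size=config.n_hits, replace=False)
    lo, hi = config.hit_survival_range
    sigma.iloc[np.sort(hit_idx)] = rng.uniform(lo, hi, size=config.n_hits)
    a, b = config.efficiency_beta
    eps = pd.Series(
        rng.beta(a, b, size=library.n_guides),
        index=pd.Index(library.frame["guide_id"], name="guide_id"),
    )
    return ScreenTruth(
        baseline_survival=config.baseline_survival,
        gene_survival=sigma,
        guide_efficiency=eps,
    )


def simulate_counts(
    library: GuideLibrary, truth: ScreenTruth, config: SimulationConfig
) -> CountTable:
    """Draw paired control/treated read counts from the five-stage model.

    Returns a two-condition :class:`CountTable` (``control``, ``treated``)
    keyed by guide_id, with multinomial totals equal to the configured read
    depths.

    Raises
    ------
    SimulationError
        If every founder cell dies (all S_g = 0) — increase
        ``baseline_survival`` or ``cells_per_guide``.
    """
    rng = np.random.default_rng([0xC07, config.rng_seed])
    n = library.n_guides
    sigma0 = truth.baseline_survival

    a = rng.lognormal(0.0, config.abundance_log_sd, size=n)
    a /= a.sum()
    founders = rng.poisson(config.cells_per_guide * a * n)
    if founders.sum() == 0:
        raise SimulationError(
            "no founder cells drawn; increase cells_per_guide"
        )

    depth_c = config.depth("control", n)
    control = rng.multinomial(depth_c, founders / founders.sum())

    gene_sigma = truth.gene_survival.reindex(library.frame["gene_id"]).to_numpy()
    eps = truth.guide_efficiency.reindex(library.frame["guide_id"]).to_numpy()
    p_survive = eps * gene_sigma + (1.0 - eps) * sigma0
    survivors = rng.binomial(founders, p_survive)
    if survivors.sum() == 0:
        raise SimulationError(
            "total kill: no cell survived the stimulus; increase "
            "baseline_survival or cells_per_guide"
        )

    depth_t = config.depth("treated", n)
    treated = rng.multinomial(depth_t, survivors / survivors.sum())

    frame = pd.DataFrame(
        {
            "gene_id": library.frame["gene_id"].to_numpy(),
            "control": control,
            "treated": treated,
        },
        index=pd.Index(library.frame["guide_id"], name="guide_id"),
    )
    return CountTable(
        frame=frame,
        total_reads={"control": int(depth_c), "treated": int(depth_t)},
        unassigned_reads={"control": 0, "treated": 0},
    )


def simulate_screen(
    config: SimulationConfig,
) -> tuple[GuideLibrary, ScreenTruth, CountTable]:
    """Convenience wrapper: library -> truth -> counts from one config."""
    from .library import simulate_library

    library = simulate_library(config)
    truth = assign_truth(library, config)
    table = simulate_counts(library, truth, config)
    return library, truth, table


_BASE_IDX = {b: i for i, b in enumerate(DNA_ALPHABET)}
_BASES = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)


def generate_reads(
    table: CountTable,
    library: GuideLibrary,
    condition: str,
    path,
    prefix: str = "",
    suffix: str = "",
    error_rate: float = 0.0,
    rng_seed: int = 0,
) -> int:
    """Emit one FASTQ read per counted molecule of a condition.

    Each guide g contributes exactly ``count_g`` reads of
    ``prefix + spacer_g + suffix``, with substitution errors applied i.i.d.
    per base at ``error_rate`` (a substituted base becomes one of the three
    other bases uniformly). Qualities are a constant placeholder. A ``.gz``
    path suffix gzip-compresses the output. Returns the number of reads
    written.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must lie in [0, 1)")
    counts = table.counts(condition)
    unknown = counts.index.difference(library.guide_ids)
    if len(unknown):
        raise ValueError(f"counted guides absent from library: {list(unknown[:5])}")
    rng = np.random.default_rng([0x4EAD, rng_seed])
    spacers = library.frame.set_index("guide_id")["spacer"]
    read_len = len(prefix) + library.spacer_length + len(suffix)
    qual = "I" * read_len

    n_written = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for guide_id, count in counts.items():
            count = int(count)
            if count == 0:
                continue
            template = prefix + spacers.loc[guide_id] + suffix
            if error_rate > 0:
                base = np.frombuffer(template.encode(), dtype=np.uint8)
                reads = np.tile(base, (count, 1))
                mask = rng.random(reads.shape) < error_rate
                n_err = int(mask.sum())
                if n_err:
                    # shift each hit base by 1-3 positions in the alphabet
                    idx = np.array([_BASE_IDX[chr(b)] for b in reads[mask]])
                    shift = rng.integers(1, 4, size=n_err)
                    reads[mask] = _BASES[(idx + shift) % 4]
                seqs = [row.tobytes().decode() for row in reads]
            else:
                seqs = [template] * count
            chunk = []
            for i, seq in enumerate(seqs):
                chunk.append(f"@{guide_id}:{n_written + i}\n{seq}\n+\n{qual}\n")
            fh.write("".join(chunk))
            n_written += count
    return n_written


def write_truth(truth: ScreenTruth, gene_path, guide_path) -> None:
    """Write ground truth as two tab-separated tables.

    Genes: ``gene_id, sigma, is_hit``. Guides: ``guide_id, epsilon``.
    """
    genes = pd.DataFrame(
        {
            "sigma": truth.gene_survival,
            "is_hit": truth.gene_survival != truth.baseline_survival,
        }
    )
    genes.to_csv(gene_path, sep="\t", index_label="gene_id")
    truth.guide_efficiency.rename("epsilon").to_csv(
        guide_path, sep="\t", index_label="guide_id"
    )


def read_truth(gene_path, guide_path, baseline_survival: float) -> ScreenTruth:
    genes = pd.read_csv(gene_path, sep="\t", index_col="gene_id")
    guides = pd.read_csv(guide_path, sep="\t", index_col="guide_id")
    return ScreenTruth(
        baseline_survival=baseline_survival,
        gene_survival=genes["sigma"],
        guide_efficiency=guides["epsilon"],
    )
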