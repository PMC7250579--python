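"""Configuration for the pooled-screen simulator.

A :class:`SimulationConfig` fixes every stochastic choice the simulator
makes: library shape, baseline abundance skew, founder-cell coverage,
selection strength, knockout-efficiency distribution and sequencing depth.
The same config plus the same seed reproduces the screen byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence


class SimulationError(RuntimeError):
    """A simulated screen could not be generated under the given parameters."""


@dataclass
class SimulationConfig:
    """Parameters of a simulated pooled CRISPR knockout survival screen.

    Parameters
    ----------
    n_genes
        Number of targeted genes in the library.
    guides_per_gene
        Inclusive (min, max) range of guides per gene; the per-gene count is
        drawn uniformly from this range. Default (5, 6), the shape of a
        genome-wide knockout library with 5-6 sgRNAs per gene.
    spacer_length
        Length of each guide's spacer sequence in nucleotides.
    abundance_log_sd
        Standard deviation, on the natural-log scale, of the log-normal
        baseline guide-abundance skew. 0 gives a perfectly uniform library.
    cells_per_guide
        Expected number of founder cells per guide at average abundance.
        Together with ``baseline_survival`` this sets the survivor
        bottleneck: ~``cells_per_guide * baseline_survival`` surviving cells
        per neutral guide.
    read_depth_control, read_depth_treated
        Total sequencing reads per condition. ``None`` means
        ``reads_per_guide`` times the realised number of guides.
    reads_per_guide
        Per-guide depth used when an explicit total depth is not given.
    n_hits
        Number of genes assigned a survival effect different from baseline.
    baseline_survival
        Probability sigma0 that a cell with no knockout phenotype survives
        the lethal stimulus.
    hit_survival_range
        Inclusive range from which a resistance hit's survival probability
        sigma_j is drawn uniformly.
    efficiency_beta
        (alpha, beta) of the Beta distribution for per-guide knockout
        efficiency epsilon. Default Beta(8, 2), mean 0.8: most guides cut
        well, a minority poorly.
    rng_seed
        Seed for all random draws.
    gene_names
        Optional explicit gene identifiers; default auto-generated
        ``GENE0001`` style ids.
    """

    n_genes: int
    guides_per_gene: tuple[int, int] = (5, 6)
    spacer_length: int = 20
    abundance_log_sd: float = 0.5
    cells_per_guide: float = 200.0
    read_depth_control: Optional[int] = None
    read_depth_treated: Optional[int] = None
    reads_per_guide: int = 500
    n_hits: int = 0
    baseline_survival: float = 0.05
    hit_survival_range: tuple[float, float] = (0.5, 1.0)
    efficiency_beta: tuple[float, float] = (8.0, 2.0)
    rng_seed: int = 0
    gene_names: Optional[Sequence[str]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.guides_per_gene
        if not (1 <= lo <= hi <= 10):
            raise ValueError("guides_per_gene range must lie within [1, 10]")
        if self.spacer_length < 1:
            raise ValueError("spacer_length must be positive")
        if self.abundance_log_sd < 0:
            raise ValueError("abundance_log_sd must be >= 0")
        if self.cells_per_guide <= 0:
            raise ValueError("cells_per_guide must be positive")
        for name in ("read_depth_control", "read_depth_treated"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be positive")
        if self.reads_per_guide < 1:
            raise ValueError("reads_per_guide must be positive")
        if not 0 <= self.n_hits <= self.n_genes:
            raise ValueError("n_hits must lie in [0, n_genes]")
        if not 0 < self.baseline_survival <= 1:
            raise ValueError("baseline_survival must lie in (0, 1]")
        slo, shi = self.hit_survival_range
        if not (0 <= slo <= shi <= 1):
            raise ValueError("hit_survival_range must lie within [0, 1]")
        a, b = self.efficiency_beta
        if a <= 0 or b <= 0:
            raise ValueError("efficiency_beta parameters must be positive")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise ValueError("gene_names length must equal n_genes")

    def depth(self, condition: str, n_guides: int) -> int:
        """Resolve the total read depth for a condition."""
        explicit = {
            "control": self.read_depth_control,
            "treated": self.read_depth_treated,
        }.get(condition)
        return explicit if explicit is not None else self.reads_per_guide * n_guides

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gene_names"] = list(self.gene_names) if self.gene_names is not None else None
        return d
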