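"""The sgRNA library: guide-to-gene mapping plus spacer sequences."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig

DNA_ALPHABET = "ACGT"
_LIBRARY_COLUMNS = ["guide_id", "gene_id", "spacer"]


class LibraryError(ValueError):
    """The guide library violates a structural invariant."""


@dataclass(frozen=True)
class GuideLibrary:
    """An sgRNA library.

    Wraps a DataFrame with columns ``guide_id``, ``gene_id``, ``spacer``.
    All guide ids and all spacers are unique; every spacer has the same
    length and uses only A/C/G/T; every guide belongs to exactly one gene.
    Construct through :meth:`from_frame` (or :func:`read_library`) so the
    invariants are checked.
    """

    frame: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GuideLibrary":
        missing = [c for c in _LIBRARY_COLUMNS if c not in frame.columns]
        if missing:
            raise LibraryError(f"library table lacks columns: {missing}")
        frame = frame[_LIBRARY_COLUMNS].reset_index(drop=True)
        if frame["guide_id"].duplicated().any():
            dups = frame.loc[frame["guide_id"].duplicated(), "guide_id"].tolist()
            raise LibraryError(f"duplicate guide_id values: {dups[:5]}")
        dup_mask = frame["spacer"].duplicated(keep=False)
        if dup_mask.any():
            offenders = frame.loc[dup_mask].sort_values("spacer")
            pair = offenders["guide_id"].tolist()[:2]
            raise LibraryError(
                f"duplicate spacer shared by guides {pair[0]} and {pair[1]}"
            )
        lengths = frame["spacer"].str.len().unique()
        if len(lengths) > 1:
            raise LibraryError(f"spacers have mixed lengths: {sorted(lengths)}")
        if not frame["spacer"].str.fullmatch(f"[{DNA_ALPHABET}]+").all():
            bad = frame.loc[
                ~frame["spacer"].str.fullmatch(f"[{DNA_ALPHABET}]+"), "guide_id"
            ].tolist()
            raise LibraryError(f"non-ACGT spacer for guides: {bad[:5]}")
        return cls(frame=frame)

    @property
    def n_guides(self) -> int:
        return len(self.frame)

    @property
    def n_genes(self) -> int:
        return self.frame["gene_id"].nunique()

    @property
    def spacer_length(self) -> int:
        return len(self.frame["spacer"].iloc[0])

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.frame["guide_id"])

    @property
    def gene_ids(self) -> list[str]:
        # first-appearance order
        return list(dict.fromkeys(self.frame["gene_id"]))

    def guide_to_gene(self) -> pd.Series:
        return self.frame.set_index("guide_id")["gene_id"]

    def guides_per_gene(self) -> pd.Series:
        return self.frame.groupby("gene_id", sort=False).size()


def simulate_library(config: SimulationConfig) -> GuideLibrary:
    """Generate a random sgRNA library.

    Gene ids are ``GENE0001``-style unless ``config.gene_names`` supplies
    explicit names; the per-gene guide count is drawn uniformly from
    ``config.guides_per_gene``; spacers are unique uniform-random DNA of
    length ``config.spacer_length``.

    Raises
    ------
    SimulationError
        If the spacer space ``4**spacer_length`` is too small to host one
        unique spacer per guide.
    """
    from .config import SimulationError

    rng = np.random.default_rng([0x11B, config.rng_seed])
    lo, hi = config.guides_per_gene
    n_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    total = int(n_per_gene.sum())

    space = 4 ** config.spacer_length
    if total > space:
        raise SimulationError(
            f"cannot draw {total} unique spacers of length "
            f"{config.spacer_length} (only {space} exist); increase spacer_length"
        )

    spacers: list[str] = []
    seen: set[str] = set()
    bases = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
    while len(spacers) < total:
        batch = rng.integers(0, 4, size=(total - len(spacers), config.spacer_length))
        for row in bases[batch]:
            s = row.tobytes().decode()
            if s not in seen:
                seen.add(s)
                spacers.append(s)

    if config.gene_names is not None:
        genes = list(config.gene_names)
    else:
        width = max(4, len(str(config.n_genes)))
        genes = [f"GENE{i + 1:0{width}d}" for i in range(config.n_genes)]

    records = []
    k = 0
    for gene, n in zip(genes, n_per_gene):
        for i in range(int(n)):
            records.append((f"{gene}_g{i + 1}", gene, spacers[k]))
            k += 1
    frame = pd.DataFrame(records, columns=_LIBRARY_COLUMNS)
    return GuideLibrary.from_frame(frame)


def write_library(library: GuideLibrary, path) -> None:
    """Write the library as a 3-column tab-separated table with header."""
    library.frame.to_csv(path, sep="\t", index=False)


def read_library(path) -> GuideLibrary:
    """Read a tab-separated library table, validating all invariants."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return GuideLibrary.from_frame(frame)
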