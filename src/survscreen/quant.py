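"""Assigning sequencing reads to library guides.

Mapping is exact spacer match by default — the dominant convention for
pooled-screen quantification and fully deterministic. An optional
Hamming-distance-1 mode rescues reads with a single substitution, assigning
a read only when exactly one guide lies within distance 1 (ambiguous reads
stay unassigned, keeping counts integral and conservative).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pysam

from .counts import CountTable
from .library import DNA_ALPHABET, GuideLibrary, LibraryError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpacerIndex:
    """Exact-match lookup from L-mer to owning guide_id."""

    spacer_to_guide: dict[str, str]
    spacer_length: int

    def lookup(self, kmer: str) -> str | None:
        """Return the unique guide owning this spacer, or None."""
        return self.spacer_to_guide.get(kmer)


def build_spacer_index(library: GuideLibrary) -> SpacerIndex:
    """Build an exact-match spacer index; rejects duplicate spacers."""
    mapping: dict[str, str] = {}
    for guide_id, spacer in zip(library.frame["guide_id"], library.frame["spacer"]):
        if spacer in mapping:
            raise LibraryError(
                f"duplicate spacer shared by guides {mapping[spacer]} and {guide_id}"
            )
        mapping[spacer] = guide_id
    return SpacerIndex(spacer_to_guide=mapping, spacer_length=library.spacer_length)


def _hamming1_matches(index: SpacerIndex, kmer: str) -> set[str]:
    """All guides within Hamming distance <= 1 of the k-mer."""
    hits: set[str] = set()
    exact = index.lookup(kmer)
    if exact is not None:
        hits.add(exact)
    chars = list(kmer)
    for i, orig in enumerate(chars):
        for b in DNA_ALPHABET:
            if b == orig:
                continue
            chars[i] = b
            g = index.lookup("".join(chars))
            if g is not None:
                hits.add(g)
        chars[i] = orig
    return hits


def quantify_reads(
    reads_path,
    index: SpacerIndex,
    library: GuideLibrary,
    condition: str,
    spacer_offset: int = 0,
    max_mismatches: int = 0,
    revcomp: bool = False,
) -> CountTable:
    """Count reads per guide for one condition.

    The spacer window ``[spacer_offset, spacer_offset + L)`` of each read
    (after optional reverse-complementing) is matched against the library.
    ``max_mismatches`` 0 demands an exact match; 1 additionally accepts a
    read whose window is within Hamming distance 1 of exactly one guide.
    Reads that are too short, unmatched, or ambiguous count as unassigned.

    Raises
    ------
    ValueError
        On a malformed FASTQ record, reporting the record index.
    """
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    L = index.spacer_length
    counts: dict[str, int] = {}
    total = 0
    unassigned = 0
    try:
        with pysam.FastxFile(str(reads_path)) as fh:
            for record in fh:
                total += 1
                seq = record.sequence
                if seq is None or record.quality is None:
                    raise ValueError(
                        f"malformed FASTQ record {total} in {reads_path}: "
                        "missing sequence or quality"
                    )
                seq = seq.upper()
                if revcomp:
                    seq = reverse_complement(seq)
                if len(seq) < spacer_offset + L:
                    unassigned += 1
                    continue
                window = seq[spacer_offset : spacer_offset + L]
                guide = index.lookup(window)
                if guide is None and max_mismatches == 1:
                    hits = _hamming1_matches(index, window)
                    guide = hits.pop() if len(hits) == 1 else None
                elif guide is not None and max_mismatches == 1:
                    # exact hit can still be ambiguous against a distance-1 neighbour
                    hits = _hamming1_matches(index, window)
                    if len(hits) != 1:
                        guide = None
                if guide is None:
                    unassigned += 1
                else:
                    counts[guide] = counts.get(guide, 0) + 1
    except OSError as exc:
        raise ValueError(
            f"malformed FASTQ near record {total + 1} in {reads_path}: {exc}"
        ) from exc

    col = pd.Series(counts, dtype="int64").reindex(library.guide_ids, fill_value=0)
    frame = pd.DataFrame(
        {"gene_id": library.frame["gene_id"].to_numpy(), condition: col.to_numpy()},
        index=pd.Index(library.frame["guide_id"], name="guide_id"),
    )
    return CountTable(
        frame=frame,
        total_reads={condition: total},
        unassigned_reads={condition: unassigned},
    )
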