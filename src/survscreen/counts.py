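"""Per-guide read counts across named screen conditions."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class CountTable:
    """Integer read counts per guide, one column per condition.

    ``frame`` is indexed by ``guide_id`` with a ``gene_id`` column followed
    by one integer column per condition. Every guide of the library appears;
    guides never observed carry count 0. ``total_reads`` and
    ``unassigned_reads`` record, per condition, how many reads were
    processed and how many could not be assigned to any guide, so that
    assigned + unassigned = total.
    """

    frame: pd.DataFrame
    total_reads: dict[str, int] = field(default_factory=dict)
    unassigned_reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond in self.conditions:
            col = self.frame[cond]
            if (col < 0).any():
                raise ValueError(f"negative counts in condition {cond!r}")
            assigned = int(col.sum())
            self.total_reads.setdefault(cond, assigned)
            self.unassigned_reads.setdefault(cond, self.total_reads[cond] - assigned)
            if assigned + self.unassigned_reads[cond] != self.total_reads[cond]:
                raise ValueError(
                    f"condition {cond!r}: assigned ({assigned}) + unassigned "
                    f"({self.unassigned_reads[cond]}) != total ({self.total_reads[cond]})"
                )

    @property
    def conditions(self) -> list[str]:
        return [c for c in self.frame.columns if c != "gene_id"]

    @property
    def guide_ids(self) -> pd.Index:
        return self.frame.index

    def counts(self, condition: str) -> pd.Series:
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        return self.frame[condition]

    def assigned(self, condition: str) -> int:
        return int(self.counts(condition).sum())


def merge_counts(tables: list[CountTable]) -> CountTable:
    """Merge single-condition tables over the same guide universe.

    Raises on condition-name collisions or mismatched guide sets.
    """
    if not tables:
        raise ValueError("no tables to merge")
    base = tables[0]
    frame = base.frame.copy()
    totals = dict(base.total_reads)
    unassigned = dict(base.unassigned_reads)
    for t in tables[1:]:
        if not t.frame.index.equals(base.frame.index):
            raise ValueError("count tables cover different guide sets")
        for cond in t.conditions:
            if cond in totals:
                raise ValueError(f"condition name collision: {cond!r}")
            frame[cond] = t.frame[cond]
            totals[cond] = t.total_reads[cond]
            unassigned[cond] = t.unassigned_reads[cond]
    return CountTable(frame=frame, total_reads=totals, unassigned_reads=unassigned)


def identified_fraction(table: CountTable, condition: str) -> float:
    """Fraction of library guides observed (count > 0) in a condition."""
    col = table.counts(condition)
    if len(col) == 0:
        return 0.0
    return float((col > 0).sum() / len(col))


def write_counts(table: CountTable, path) -> None:
    """Write a count table as tab-separated text.

    Per-condition totals and unassigned-read tallies go into ``#``-prefixed
    header lines so the file round-trips through :func:`read_counts`.
    """
    with open(path, "w") as fh:
        for cond in table.conditions:
            fh.write(
                f"# condition={cond}\ttotal={table.total_reads[cond]}"
                f"\tunassigned={table.unassigned_reads[cond]}\n"
            )
        table.frame.to_csv(fh, sep="\t", index=True, index_label="guide_id")


def read_counts(path) -> CountTable:
    totals: dict[str, int] = {}
    unassigned: dict[str, int] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            fields = dict(
                kv.split("=", 1) for kv in line.lstrip("#").strip().split("\t")
            )
            cond = fields["condition"]
            totals[cond] = int(fields["total"])
            unassigned[cond] = int(fields["unassigned"])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t", index_col="guide_id")
    return CountTable(frame=frame, total_reads=totals, unassigned_reads=unassigned)
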