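"""Fold representation, gene-level scoring, hit calling and ranking.

The analysis of a survivor (positive-selection) screen reduces to a
deterministic threshold rule on per-guide fold representation:

* a guide's *fold representation* is the ratio of its relative abundance
  (count / condition total) in the survivor sample to that in the control;
* a guide absent from both samples is *not identified* (fold NA); a guide
  seen only in survivors has fold +inf, only in control fold 0;
* a gene is a *hit* when at least half of its identified guides are at
  least two-fold overrepresented in survivors (thresholds, inclusivity and
  the denominator are configurable);
* genes are ranked by % overrepresented guides, then median fold, with
  documented deterministic tie-breaks.

No p-values or permutation statistics are computed: the procedure is a
threshold rule and is implemented as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .counts import CountTable
from .library import GuideLibrary

SCORE_COLUMNS = [
    "n_guides_total",
    "n_identified",
    "n_overrepresented",
    "pct_overrepresented",
    "median_fold",
    "mean_fold",
    "is_hit",
]


@dataclass(frozen=True)
class ScoringParams:
    """Thresholds of the hit-calling rule.

    ``fold_threshold`` — minimum fold representation for a guide to count
    as overrepresented (default 2.0, inclusive). ``min_overrep_fraction`` —
    minimum fraction of a gene's guides that must be overrepresented
    (default 0.5, inclusive). ``denominator_mode`` — whether that fraction
    is taken over identified (non-NA) guides or over all of the gene's
    guides. ``pseudocount`` > 0 removes NA/inf folds entirely.
    """

    fold_threshold: float = 2.0
    threshold_inclusive: bool = True
    min_overrep_fraction: float = 0.5
    fraction_inclusive: bool = True
    denominator_mode: str = "identified"
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 < self.min_overrep_fraction <= 1:
            raise ValueError("min_overrep_fraction must lie in (0, 1]")
        if self.denominator_mode not in ("identified", "total"):
            raise ValueError("denominator_mode must be 'identified' or 'total'")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    def is_overrepresented(self, fold: float) -> bool:
        if math.isnan(fold):
            return False
        if self.threshold_inclusive:
            return fold >= self.fold_threshold
        return fold > self.fold_threshold

    def meets_fraction(self, pct: float) -> bool:
        if math.isnan(pct):
            return False
        cutoff = 100.0 * self.min_overrep_fraction
        return pct >= cutoff if self.fraction_inclusive else pct > cutoff


@dataclass
class FoldTable:
    """Per-guide fold representation with provenance frequencies.

    ``frame`` is indexed by guide_id with columns ``gene_id``,
    ``freq_control``, ``freq_treated``, ``fold``. NA (NaN) marks guides not
    identified in either sample; +inf marks guides identified only in the
    survivor sample.
    """

    frame: pd.DataFrame
    control: str = "control"
    treated: str = "treated"

    @property
    def folds(self) -> pd.Series:
        return self.frame["fold"]


@dataclass
class RankedGeneList:
    """Gene scores in final rank order (1-based ``rank`` column)."""

    frame: pd.DataFrame
    gene_filter_name: Optional[str] = None
    n_filter_missing: int = 0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)


def normalize_to_frequencies(
    table: CountTable, condition: str, pseudocount: float = 0.0
) -> pd.Series:
    """Relative guide abundance: (count + pseudocount) / their sum."""
    col = table.counts(condition).astype(float) + pseudocount
    total = col.sum()
    if total <= 0:
        raise ValueError(
            f"condition {condition!r} has zero total count; "
            "use a positive pseudocount or check the input"
        )
    return col / total


def fold_representation(
    table: CountTable,
    params: ScoringParams | None = None,
    control: str = "control",
    treated: str = "treated",
) -> FoldTable:
    """Per-guide fold representation of the survivor sample versus control.

    With pseudocount 0: NA iff the guide is absent from both samples; +inf
    iff absent from control only; 0 iff absent from survivors only. With a
    positive pseudocount every fold is finite and positive.
    """
    params = params or ScoringParams()
    p = params.pseudocount
    fc = normalize_to_frequencies(table, control, p)
    ft = normalize_to_frequencies(table, treated, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = ft.to_numpy() / fc.to_numpy()
    frame = pd.DataFrame(
        {
            "gene_id": table.frame["gene_id"].to_numpy(),
            "freq_control": fc.to_numpy(),
            "freq_treated": ft.to_numpy(),
            "fold": fold,
        },
        index=table.frame.index,
    )
    return FoldTable(frame=frame, control=control, treated=treated)


def score_genes(
    folds: FoldTable, library: GuideLibrary, params: ScoringParams | None = None
) -> pd.DataFrame:
    """Aggregate per-guide folds into per-gene scores.

    Returns a DataFrame indexed by gene_id with columns ``n_guides_total``,
    ``n_identified``, ``n_overrepresented``, ``pct_overrepresented``,
    ``median_fold``, ``mean_fold`` and ``is_hit``. Median and mean are over
    identified (non-NA) folds only, on the extended real line (+inf folds
    participate by rank position); both are NA when no guide is identified,
    and then the gene is never a hit.
    """
    params = params or ScoringParams()
    fr = folds.frame
    unknown = fr.index.difference(library.guide_ids)
    if len(unknown):
        raise ValueError(f"folds contain guides absent from library: {list(unknown[:5])}")
    gene_of = library.guide_to_gene()
    missing = library.guide_ids.difference(fr.index)
    if len(missing):
        raise ValueError(f"library guides missing from folds: {list(missing[:5])}")

    fold = fr["fold"]
    identified = fold.notna()
    if params.threshold_inclusive:
        over = identified & (fold >= params.fold_threshold)
    else:
        over = identified & (fold > params.fold_threshold)

    genes = library.gene_ids
    work = pd.DataFrame(
        {
            "gene_id": gene_of.reindex(fr.index).to_numpy(),
            "fold": fold.to_numpy(),
            "identified": identified.to_numpy(),
            "over": over.to_numpy(),
        },
        index=fr.index,
    )
    grouped = work.groupby("gene_id", sort=False)
    n_total = library.guides_per_gene().reindex(genes)
    n_ident = grouped["identified"].sum().reindex(genes).fillna(0).astype(int)
    n_over = grouped["over"].sum().reindex(genes).fillna(0).astype(int)

    denom = n_ident if params.denominator_mode == "identified" else n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * n_over.to_numpy() / denom.to_numpy()
    pct = pd.Series(np.where(denom.to_numpy() > 0, pct, np.nan), index=genes)

    med = grouped["fold"].median().reindex(genes)  # NaN folds excluded; inf by rank
    mean = grouped["fold"].mean().reindex(genes)  # skipna: identified only

    is_hit = pd.Series(
        [params.meets_fraction(v) for v in pct], index=genes
    ) & (n_ident >= 1)

    scores = pd.DataFrame(
        {
            "n_guides_total": n_total.astype(int),
            "n_identified": n_ident,
            "n_overrepresented": n_over,
            "pct_overrepresented": pct,
            "median_fold": med,
            "mean_fold": mean,
            "is_hit": is_hit,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return scores


def call_hits(scores: pd.DataFrame) -> set[str]:
    """Gene ids flagged as hits."""
    return set(scores.index[scores["is_hit"]])


def _rank_key(scores: pd.DataFrame) -> pd.DataFrame:
    # descending sort columns; NA ranks behind every number, so map it below
    # the fold/pct range (all values are >= 0)
    key = pd.DataFrame(index=scores.index)
    key["pct"] = scores["pct_overrepresented"].fillna(-1.0)
    key["median"] = scores["median_fold"].fillna(-1.0)
    key["mean"] = scores["mean_fold"].fillna(-1.0)
    return key


def rank_genes(
    scores: pd.DataFrame,
    gene_filter: Optional[Iterable[str]] = None,
    filter_name: Optional[str] = None,
) -> RankedGeneList:
    """Rank genes for reporting.

    Order: descending % overrepresented, then descending median fold (+inf
    greatest, NA last), then descending mean fold, then ascending gene_id —
    a total, reproducible order. Genes with NA percentage rank after all
    scored genes. When ``gene_filter`` is given, ranking is computed on all
    genes first and then restricted to the filter, preserving relative
    order; absent filter ids are tallied in ``n_filter_missing``.
    """
    key = _rank_key(scores)
    # mergesort is stable; pre-sort by gene_id for the ascending final key
    order = key.sort_index().sort_values(
        ["pct", "median", "mean"], ascending=False, kind="mergesort"
    )
    ranked = scores.loc[order.index].copy()
    n_missing = 0
    if gene_filter is not None:
        wanted = set(gene_filter)
        n_missing = len(wanted - set(scores.index))
        ranked = ranked.loc[[g for g in ranked.index if g in wanted]]
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return RankedGeneList(
        frame=ranked, gene_filter_name=filter_name, n_filter_missing=n_missing
    )


def filter_gene_list(ranked: RankedGeneList, ids: Iterable[str], name: str | None = None) -> RankedGeneList:
    """Restrict an existing ranking to a gene list, keeping relative order."""
    wanted = set(ids)
    frame = ranked.frame.loc[[g for g in ranked.frame.index if g in wanted]].copy()
    frame["rank"] = np.arange(1, len(frame) + 1)
    return RankedGeneList(
        frame=frame,
        gene_filter_name=name,
        n_filter_missing=len(wanted - set(ranked.frame.index)),
    )


def read_gene_list(path) -> list[str]:
    """Read a gene list, one id per line, ignoring blanks."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _format_value(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    if x == math.inf:
        return "inf"
    return repr(float(x))


def _parse_value(s: str) -> float:
    if s == "NA":
        return math.nan
    return float(s)


def write_hit_table(
    scores: pd.DataFrame, folds: FoldTable, library: GuideLibrary, path
) -> None:
    """Write the per-gene hit table.

    One row per gene: gene_id, the gene's per-guide folds in fold_1..fold_k
    columns (NA literal for guides not identified in either sample, empty
    for genes with fewer than k guides), then median, mean,
    pct_overrepresented and is_hit. Round-trips through
    :func:`read_hit_table`.
    """
    gene_folds: dict[str, list[float]] = {}
    for guide_id, gene_id, fold in zip(
        folds.frame.index, folds.frame["gene_id"], folds.frame["fold"]
    ):
        gene_folds.setdefault(gene_id, []).append(fold)
    k = max((len(v) for v in gene_folds.values()), default=0)
    cols = [f"fold_{i + 1}" for i in range(k)]
    with open(path, "w") as fh:
        fh.write(
            "gene_id\t" + "\t".join(cols)
            + "\tmedian_fold\tmean_fold\tpct_overrepresented\tis_hit\n"
        )
        for gene_id, row in scores.iterrows():
            fl = gene_folds.get(gene_id, [])
            cells = [_format_value(f) for f in fl] + [""] * (k - len(fl))
            fh.write(
                f"{gene_id}\t" + "\t".join(cells) + "\t"
                + _format_value(row["median_fold"]) + "\t"
                + _format_value(row["mean_fold"]) + "\t"
                + _format_value(row["pct_overrepresented"]) + "\t"
                + ("TRUE" if row["is_hit"] else "FALSE") + "\n"
            )


@dataclass
class HitTable:
    """A parsed per-gene hit table: stats plus raw per-guide folds."""

    scores: pd.DataFrame
    gene_folds: dict[str, list[float]] = field(repr=False, default_factory=dict)


def read_hit_table(path) -> HitTable:
    """Read a hit table written by :func:`write_hit_table`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        fold_cols = [c for c in header if c.startswith("fold_")]
        k = len(fold_cols)
        records = []
        gene_folds: dict[str, list[float]] = {}
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            gene_id = cells[0]
            gene_folds[gene_id] = [
                _parse_value(c) for c in cells[1 : 1 + k] if c != ""
            ]
            med, mean, pct, hit = cells[1 + k : 5 + k]
            records.append(
                (
                    gene_id,
                    _parse_value(med),
                    _parse_value(mean),
                    _parse_value(pct),
                    hit == "TRUE",
                )
            )
    scores = pd.DataFrame(
        records,
        columns=["gene_id", "median_fold", "mean_fold", "pct_overrepresented", "is_hit"],
    ).set_index("gene_id")
    return HitTable(scores=scores, gene_folds=gene_folds)


def rescore_hit_table(table: HitTable, params: ScoringParams | None = None) -> pd.DataFrame:
    """Recompute per-gene statistics from a hit table's raw per-guide folds.

    Used to check a published per-gene fold table against the hit-calling
    rule: counts identified and overrepresented guides afresh and rebuilds
    pct/median/mean/is_hit from the folds alone.
    """
    params = params or ScoringParams()
    records = []
    for gene_id, fl in table.gene_folds.items():
        ident = [f for f in fl if not math.isnan(f)]
        n_over = sum(params.is_overrepresented(f) for f in ident)
        denom = len(ident) if params.denominator_mode == "identified" else len(fl)
        pct = 100.0 * n_over / denom if denom > 0 else math.nan
        med = float(np.median(ident)) if ident else math.nan
        mean = float(np.mean(ident)) if ident else math.nan
        records.append(
            (
                gene_id,
                len(fl),
                len(ident),
                n_over,
                pct,
                med,
                mean,
                params.meets_fraction(pct) and len(ident) >= 1,
            )
        )
    return pd.DataFrame(
        records, columns=["gene_id"] + SCORE_COLUMNS
    ).set_index("gene_id")
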