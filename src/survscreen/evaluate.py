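"""Recovery of simulated ground truth and guide-dropout summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .counts import CountTable, identified_fraction
from .simulate import ScreenTruth


@dataclass
class RecoveryReport:
    """Confusion summary of called hits against planted resistance genes.

    Sensitizer genes (sigma_j < sigma0) cannot enrich in a survivor screen,
    so they are excluded from the positive class and tallied separately.
    ``precision`` is NA when nothing was called.
    """

    n_true_hits: int
    n_called: int
    true_positives: int
    false_positives: int
    false_negatives: int
    sensitivity: float
    precision: float
    n_sensitizers: int
    sensitizers_called: int
    per_gene: pd.DataFrame

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_true_hits",
                "n_called",
                "true_positives",
                "false_positives",
                "false_negatives",
                "sensitivity",
                "precision",
                "n_sensitizers",
                "sensitizers_called",
            )
        }
        return d


def evaluate_recovery(
    called: Iterable[str],
    truth: ScreenTruth,
    scores: Optional[pd.DataFrame] = None,
    library=None,
) -> RecoveryReport:
    """Score a called hit set against the simulator's ground truth.

    ``sensitivity = TP / (TP + FN)`` over resistance genes;
    ``precision = TP / (TP + FP)`` where FP counts called neutral genes
    (called sensitizers are reported separately, not as FP).
    """
    called = set(called)
    all_genes = set(truth.gene_survival.index)
    unknown = called - all_genes
    if unknown:
        raise ValueError(f"called genes absent from truth: {sorted(unknown)[:5]}")

    positives = truth.resistance_genes
    sensitizers = truth.sensitizer_genes
    tp = len(called & positives)
    fn = len(positives - called)
    fp = len(called - positives - sensitizers)
    sensitivity = tp / (tp + fn) if positives else math.nan
    precision = tp / (tp + fp) if called else math.nan

    if library is not None:
        gene_of = library.guide_to_gene().reindex(truth.guide_efficiency.index)
        eps_by_gene = truth.guide_efficiency.groupby(gene_of).mean()
    else:
        eps_by_gene = pd.Series(dtype=float)
    per_gene = pd.DataFrame(
        {
            "sigma": truth.gene_survival,
            "mean_epsilon": eps_by_gene.reindex(truth.gene_survival.index),
            "called": [g in called for g in truth.gene_survival.index],
        }
    )
    if scores is not None:
        per_gene["pct_overrepresented"] = scores["pct_overrepresented"].reindex(
            per_gene.index
        )
    return RecoveryReport(
        n_true_hits=len(positives),
        n_called=len(called),
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        sensitivity=sensitivity,
        precision=precision,
        n_sensitizers=len(sensitizers),
        sensitizers_called=len(called & sensitizers),
        per_gene=per_gene,
    )


@dataclass
class DepletionSummary:
    """Identified-guide fraction per condition and the treated/control ratio."""

    fractions: dict[str, float]
    ratio: float


def depletion_summary(
    table: CountTable, control: str = "control", treated: str = "treated"
) -> DepletionSummary:
    """Summarise guide dropout through the survivor bottleneck.

    The ratio is identified fraction in the survivor sample over that in
    the control: < 1 indicates loss of library diversity under selection.
    """
    fractions = {c: identified_fraction(table, c) for c in table.conditions}
    fc, ft = fractions[control], fractions[treated]
    ratio = ft / fc if fc > 0 else math.nan
    return DepletionSummary(fractions=fractions, ratio=ratio)
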