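"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain Python loops and dicts, directly from
the definitions (relative abundance, fold ratio, threshold counts, sort by
the documented key), deliberately sharing no code with the package.
"""

from __future__ import annotations

import math


def brute_force_folds(
    counts: dict[str, tuple[int, int]], pseudocount: float = 0.0
) -> dict[str, float]:
    """Fold representation per guide from (control, treated) count pairs.

    NaN when both counts are zero (pseudocount 0); inf when only the
    control count is zero.
    """
    total_c = sum(c for c, _ in counts.values()) + pseudocount * len(counts)
    total_t = sum(t for _, t in counts.values()) + pseudocount * len(counts)
    folds = {}
    for g, (c, t) in counts.items():
        fc = (c + pseudocount) / total_c
        ft = (t + pseudocount) / total_t
        if fc == 0 and ft == 0:
            folds[g] = math.nan
        elif fc == 0:
            folds[g] = math.inf
        else:
            folds[g] = ft / fc
    return folds


def _median(values: list[float]) -> float:
    # midpoint convention on the extended real line
    s = sorted(values)
    n = len(s)
    if n == 0:
        return math.nan
    if n % 2 == 1:
        return s[n // 2]
    a, b = s[n // 2 - 1], s[n // 2]
    if math.isinf(a) and math.isinf(b):
        return a
    return (a + b) / 2


def brute_force_scores(
    counts: dict[str, tuple[int, int]],
    guide_to_gene: dict[str, str],
    fold_threshold: float = 2.0,
    threshold_inclusive: bool = True,
    min_overrep_fraction: float = 0.5,
    fraction_inclusive: bool = True,
    denominator_mode: str = "identified",
    pseudocount: float = 0.0,
) -> dict[str, dict]:
    """Per-gene statistics recomputed from raw counts by definition."""
    folds = brute_force_folds(counts, pseudocount)
    genes: dict[str, list[float]] = {}
    for g, fold in folds.items():
        genes.setdefault(guide_to_gene[g], []).append(fold)
    out = {}
    for gene, fl in genes.items():
        ident = [f for f in fl if not math.isnan(f)]
        if threshold_inclusive:
            n_over = sum(1 for f in ident if f >= fold_threshold)
        else:
            n_over = sum(1 for f in ident if f > fold_threshold)
        denom = len(ident) if denominator_mode == "identified" else len(fl)
        pct = 100.0 * n_over / denom if denom > 0 else math.nan
        if math.isnan(pct):
            hit = False
        elif fraction_inclusive:
            hit = pct >= 100.0 * min_overrep_fraction
        else:
            hit = pct > 100.0 * min_overrep_fraction
        hit = hit and len(ident) >= 1
        mean = sum(ident) / len(ident) if ident else math.nan
        out[gene] = {
            "n_guides_total": len(fl),
            "n_identified": len(ident),
            "n_overrepresented": n_over,
            "pct_overrepresented": pct,
            "median_fold": _median(ident),
            "mean_fold": mean,
            "is_hit": hit,
        }
    return out


def brute_force_rank(scores: dict[str, dict]) -> list[str]:
    """Total order: pct desc, median desc, mean desc, gene_id asc; NA last."""

    def desc(x: float) -> float:
        # NA ranks behind every number; all statistics are >= 0
        return -1.0 if math.isnan(x) else x

    return sorted(
        scores,
        key=lambda g: (
            -desc(scores[g]["pct_overrepresented"]),
            -desc(scores[g]["median_fold"]),
            -desc(scores[g]["mean_fold"]),
            g,
        ),
    )


def brute_force_assign(
    spacer: str, library: dict[str, str], max_mismatches: int
) -> str | None:
    """Assign a spacer window by scanning every guide's Hamming distance."""
    hits = []
    for guide_id, ref in library.items():
        if len(ref) != len(spacer):
            continue
        d = sum(1 for a, b in zip(spacer, ref) if a != b)
        if d <= max_mismatches:
            hits.append(guide_id)
    return hits[0] if len(hits) == 1 else None
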