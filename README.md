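# survscreen

Simulation and analysis of pooled CRISPR/Cas9 **survival screens**
(positive-selection screens), for functional-genomics researchers who want
a tested, reproducible implementation of the standard fold-representation
hit-calling procedure — and a generative simulator to benchmark it without
any external dataset.

## The problem and the method

In a survivor screen, cells each carrying one knockout (genome-wide
library, 5–6 sgRNAs per gene, MOI < 1) are exposed to a lethal stimulus;
survivors are sorted and sequenced alongside an untreated control. Guides
disrupting genes *required for death* enrich among survivors.

For guide *g* with counts `c_g` (control) and `t_g` (treated) and condition
totals `C`, `T`, the **fold representation** is

```
fold_g = (t_g / T) / (c_g / C)
```

with NA when the guide is identified in neither sample, +∞ when it is seen
only in survivors, and 0 when seen only in the control. A gene is a **hit**
when at least 50% of its identified guides are at least 2-fold
overrepresented (both thresholds inclusive by default; exclusive variants,
a `total`-guides denominator and a pseudocount are available). Genes are
ranked by % overrepresented guides, then median fold, with deterministic
tie-breaks, and can be filtered against a gene list (e.g. a proteome of the
relevant cell type).

The companion simulator draws screens from an explicit five-stage model
(log-normal library skew → Poisson founder cells → multinomial control
reads → binomial survivor bottleneck with per-guide knockout efficiency →
multinomial survivor reads), so sensitivity, precision, false-hit rates and
guide dropout can all be measured against known ground truth. See
[docs/methods.md](docs/methods.md) for the model and its assumptions.

## Worked example

```python
import survscreen as ss

cfg = ss.SimulationConfig(n_genes=1000, n_hits=20, rng_seed=42)
lib, truth, counts = ss.simulate_screen(cfg)

folds  = ss.fold_representation(counts)
scores = ss.score_genes(folds, lib)
hits   = ss.call_hits(scores)
ranked = ss.rank_genes(scores)

rep = ss.evaluate_recovery(hits, truth, scores, lib)
dep = ss.depletion_summary(counts)
print(ranked.frame.head(5)[["rank", "pct_overrepresented", "median_fold", "is_hit"]])
print(f"hits called: {len(hits)}  sensitivity: {rep.sensitivity:.2f}  precision: {rep.precision:.2f}")
print(f"identified fraction control={dep.fractions['control']:.4f} "
      f"treated={dep.fractions['treated']:.4f} ratio={dep.ratio:.4f}")
```

prints

```
          rank  pct_overrepresented  median_fold  is_hit
gene_id
GENE0140     1                100.0    14.181818    True
GENE0611     2                100.0    13.974811    True
GENE0183     3                100.0    13.412207    True
GENE0860     4                100.0    13.262684    True
GENE0698     5                100.0    12.897500    True
hits called: 20  sensitivity: 1.00  precision: 1.00
identified fraction control=1.0000 treated=0.9964 ratio=0.9964
```

All 20 planted resistance genes (knockout survival 0.5–1.0 against a 0.05
baseline) are called with no false positives; the top-ranked genes have
every guide ≥2-fold enriched with median folds around the expected ~10–15×;
and the survivor bottleneck drops ~0.4% of guides from the treated sample
(ratio < 1), the qualitative signature of selection.

The same pipeline runs from the shell:

```sh
survscreen simulate-screen --n-genes 1000 --n-hits 20 --seed 42 --outdir screen/
survscreen score --counts screen/counts.tsv --library screen/library.tsv \
    --out-hits hits.tsv --out-ranked ranked.tsv
survscreen run --config screen.yaml --outdir out/   # end-to-end from one config
```

and can optionally emit and re-quantify FASTQ reads
(`simulate-screen --reads`, `survscreen quantify`) to exercise the
exact-match / Hamming-1 read-assignment stage.

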