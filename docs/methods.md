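# Methods

## The screen being modelled

`survscreen` analyses pooled CRISPR/Cas9 knockout screens read out by
*survival under a lethal stimulus* (a positive-selection, or survivor,
screen). A cell population is transduced at low multiplicity of infection
with a genome-wide guide library, so each cell carries one knockout. A
stimulus then kills most cells; guides disrupting genes required for death
become overrepresented among the sorted survivors, which are sequenced
along with an untreated control. Gene effects are read out entirely as
changes in per-guide read abundance between the two samples.

## Generative model of the simulator

The simulator draws a paired (control, treated) count table in five stages,
each with a closed-form expectation so every downstream statistic can be
checked analytically or by Monte-Carlo:

1. **Library skew.** Baseline relative abundance per guide
   `a_g ~ LogNormal(0, s)`, normalised to sum to 1, with `s =
   abundance_log_sd` (default 0.5). This emulates unequal guide
   representation from library cloning and culture outgrowth.
2. **Founder cells.** `C_g ~ Poisson(cells_per_guide * a_g * n_guides)`
   (default 200 expected founders per guide at average abundance). Each
   cell carries exactly one integrated guide — multiplicity of infection
   below one idealised to one integration, since multi-integration
   modelling adds parameters without changing the scoring stage under test.
3. **Control sequencing.** `reads_control ~ Multinomial(depth_c, p ∝ C_g)`.
4. **Selection bottleneck.** A cell with guide g of gene j survives with
   probability `p_g = ε_g σ_j + (1 − ε_g) σ_0`: with probability `ε_g` (the
   guide's knockout efficiency, `ε_g ~ Beta(8, 2)`, mean 0.8) the knockout
   phenotype applies and the cell survives at the gene's rate `σ_j`;
   otherwise it survives at the baseline rate `σ_0` (default 0.05).
   Survivors `S_g ~ Binomial(C_g, p_g)`. This bottleneck is the sole source
   of guide dropout.
5. **Survivor sequencing.** `reads_treated ~ Multinomial(depth_t, p ∝ S_g)`.

Neutral genes have `σ_j = σ_0` exactly; planted resistance hits draw
`σ_j ~ Uniform(0.5, 1.0)`. The expected fold representation of a perfectly
cutting guide of a hit gene is then `σ_j / p̄` where `p̄` is the
population-mean survival probability — with the defaults roughly a 10–15×
enrichment against ~0.8× for neutral guides, comfortably separated by the
2-fold rule.

Optionally, the counted molecules are emitted as FASTQ reads
(constant prefix + spacer + constant suffix, substitution errors i.i.d. per
base, constant placeholder qualities) so the read-quantification stage can
be exercised end to end.

### What the simulator does *not* emulate

Lentiviral copy-number variation, clonal outgrowth during the week of
differentiation, PCR jackpotting, base-quality structure, indels, and the
composition of any real genome-wide library. Passing tests on this
generator therefore demonstrate the correctness and statistical behaviour
of the *analysis* under a plausible screen mechanism, not the noise profile
of any particular experiment.

## Quantification

Reads are assigned by **exact spacer match** at a configurable offset
(default 0), the dominant convention for screen quantification and fully
deterministic. An optional Hamming-distance-1 mode rescues single-
substitution reads, assigning only when exactly one guide lies within
distance 1; ambiguous reads stay unassigned, keeping counts integral and
conservative. Reads are assumed spacer-sense; a reverse-complement switch
covers the opposite amplicon orientation. Per condition, assigned +
unassigned always equals total reads processed.

## Scoring and hit calling

Per-guide *fold representation* is the ratio of relative abundances
(count / condition total) in survivor versus control samples. With
pseudocount 0:

* absent from both samples → **NA** (the guide was not identified);
* absent from control only → **+∞** (counts as overrepresented);
* absent from survivors only → **0**.

A gene's guides aggregate to: number identified (non-NA), number
overrepresented (fold ≥ 2, inclusive by default), `% overrepresented` over
the identified guides (a `total` denominator mode is available), and
median/mean fold over identified guides computed on the extended real line
(+∞ participates by rank position; the even-n median is the midpoint of the
two central values). A gene is a **hit** when its % overrepresented meets
50% (inclusive by default) and at least one guide was identified.

Threshold inclusivity deserves a note: prose descriptions of such screens
oscillate between "more than two-fold"/"at least 2-fold" and "at least
50%"/"greater than 50%". Both thresholds here default to *inclusive*
(≥ 2-fold, ≥ 50%) with exclusive variants behind flags; with 5–6 guides per
gene the two fraction rules differ only for genes at exactly 50%.

Ranking is by `% overrepresented` (descending), then median fold
(descending, +∞ greatest, NA last), then — beyond the two documented keys,
to make the order total and reproducible — mean fold descending and
gene id ascending. Genes with an undefined percentage rank after all scored
genes. A gene-list filter (e.g. restricting to a proteome list) is applied
*after* global ranking, preserving relative order; the pre-filter ranking
is also available since either order of the two operations is defensible.

Because only relative abundances enter, every statistic is invariant under
scaling all counts of one condition by a positive constant; there is one
caveat to per-guide monotonicity: raising a single treated count raises
that guide's own fold, but the induced change of the treated total can push
a *sibling* guide marginally below the threshold, so gene-level
monotonicity holds only up to that normalisation coupling (the property
tests check exactly this).

No p-values, permutation statistics or control-guide normalisation are
computed: the hit rule is a deterministic threshold procedure and is
implemented as such.

## Evaluation

Against simulated truth, sensitivity = TP/(TP+FN) and precision =
TP/(TP+FP) are computed over *resistance* genes (σ_j > σ_0). Sensitizer
genes (σ_j < σ_0) cannot enrich in a survivor readout, so they are excluded
from the positive class and tallied separately rather than counted as false
positives. Precision is NA when nothing was called. Guide dropout is
summarised as the identified-guide fraction per condition and their
treated/control ratio.

## Numerical and design choices

* **Determinism.** Every stage derives its RNG stream from the configured
  seed plus a fixed stage tag, so library, truth, counts and reads are
  reproducible independently and jointly; identical config + seed yields
  byte-identical artifacts on disk.
* **Degenerate inputs.** Zero condition totals fail loudly unless a
  pseudocount is supplied; a simulation in which no cell survives aborts
  with advice to raise `baseline_survival` or `cells_per_guide`; duplicate
  spacers are rejected at library construction and at index build, naming
  both offending guides.
* **Null-screen bound.** In a selection-free screen at 500 reads/guide the
  hit rule requires half a gene's guides to be concordantly ≥2-fold, which
  sampling noise essentially never produces: the false-hit count measured
  over ten development seeds was 0, and the suite asserts a pinned mean
  bound of ≤ 1.0 thereafter.
* **Problem sizes in the test suite.** Oracle-equivalence checks run on 200
  random tables of up to 500 genes; recovery and null benchmarks use
  1000-gene screens at 300–500 reads/guide over 5–10 seeds; the read
  round-trip uses a 2000-gene screen at 50 reads/guide. These sizes give
  stable statistics while keeping the full suite fast.
* **Defaults as study conditions.** `L = 20`, 5–6 guides/gene,
  `abundance_log_sd = 0.5`, `cells_per_guide = 200`, `σ_0 = 0.05`, hit
  `σ_j ∈ [0.5, 1.0]`, `ε ~ Beta(8, 2)`, 500 reads/guide. Sequencing depth,
  sorted-cell numbers and library representation are not published for the
  motivating class of experiment, so these are the package's own choices of
  a realistic regime, fixed once: coverage and depth typical of genome-wide
  screens, a ~5% baseline survival giving a strong but not total bottleneck
  (~10 expected surviving cells per neutral guide).

## Known limitations

* Exact-match quantification discards reads with indels or >1 substitution.
* The hit rule inherits the fragility of any hard threshold: a gene at
  exactly the boundary flips with the inclusivity convention.
* Recovery benchmarks measure performance under the simulator's mechanism;
  real screens add overdispersion (PCR, clonal drift) that would lower
  precision at the same thresholds.
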