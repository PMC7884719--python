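# Methods

This note documents the model behind `portraitforge`, its parameter
defaults, the numerical and design choices made where the construction
was genuinely open, what the synthetic-data generator does and does not
emulate, and known limitations.

## Per-study representation

A DGE table is reduced to one signed score per gene,
`sign1 = -log10(p) · sgn(logFC)`. Choices:

- **p-value floor** (`p_floor = 1e-320`): exported tables sometimes carry
  p = 0 from upstream underflow; clamping before the logarithm keeps
  scores finite and the significance ordering stable. Clamped rows are
  counted in the load report. All −log10 p values elsewhere in the
  pipeline are capped at 320 for the same reason; the cap is
  config-exposed and recorded in provenance.
- **logFC = 0** gives direction 0: the gene scores 0 and ranks after all
  signed genes in *both* directional orderings, so it can never occupy a
  top tier. This avoids an arbitrary side assignment.
- **Symbol harmonization** is exact, case-sensitive string matching after
  whitespace trimming (human symbols are case-significant). The update
  map never rewrites a currently valid symbol, which also makes it
  idempotent; spreadsheet-date strings are repaired only when exactly one
  source gene could have produced them, otherwise flagged and left
  alone. The shipped map (`data/symbol_map_synthetic.json`) is a small
  constructed demonstration covering the classic date-mangled families
  (MARCH/MARCHF, SEPT/SEPTIN, DEC1); it is a stand-in, not a complete
  nomenclature history, and is user-replaceable via
  `SymbolMap.from_json`.
- **Duplicate probes** collapse to the smallest-p record (ties: larger
  |score|, then first occurrence).

## Portrait construction

Given *n* harmonized studies:

1. **Directional ranks.** Within each study, rank 1 = most significantly
   upregulated in the up ordering and most significantly downregulated in
   the down ordering. The two orderings are ranked independently (they
   coincide reversed when no zero-direction genes exist). All ties break
   by source-file order, then symbol — builds are fully deterministic and
   invariant to the order input tables are supplied.
2. **Missingness rule.** A gene missing from more than a third of the
   studies is dropped (missing in exactly one third is kept). Ranks are
   computed per study over its genes *restricted to the retained
   universe*, so each study's non-missing ranks form a permutation of
   1..(genes observed there).
3. **Midpoint imputation.** Remaining missing cells get the midpoint rank
   ⌈(G+1)/2⌉ of the retained universe (the same value in both
   orderings). The intent is that an unobserved gene is neutral: in the
   intended regime G ≥ 2·max(tiers) the midpoint lies outside every
   tier, so imputed cells contribute nothing. When a configuration
   violates that regime the package warns. An alternative reading of the
   imputation (per-gene mean rank over observed studies) was considered
   and rejected: it would let a gene's own signal leak into cells where
   it was never measured, while the midpoint reading matches the stated
   purpose of making imputed values ignorable.
4. **Cumulative tiers.** For cutoffs t₁ < … < t_K (default
   1000…8000), U_k(g) counts studies with up-rank ≤ t_k and D_k(g)
   likewise for down-ranks. Tiers are cumulative — the top-2000 count
   includes the top-1000 — which is the reading consistent with the
   decimal structure of the scores (the tier-1 term is the integer part;
   deeper increments refine decimals and cannot exceed ~0.111·n).
5. **Decay-weighted score.** score(g) = Σ_k w_k (U_k − D_k) with
   w_k built by repeated multiplication: w₁ = 1 and w_{k+1} = 0.1·w_k.
   The summation runs tier by tier, shallowest first. Both choices are
   definitional: an independent per-gene loop implementing "each deeper
   tier weighs tenfold less" reproduces the scores bit-for-bit, which the
   test suite checks. |score| is bounded by n·Σw_k ≈ 1.1111·n, and a
   gene equally often in the top tier of both directions cancels to 0.
6. **Ordering.** Genes sort by |score| descending, ties lexicographic by
   symbol.

Datasets with fewer genes than max(tiers) are counted over the ranks
they have, with a warning: deep tiers then saturate and such a study
contributes less contrast.

## Quadrant overlap, match and reversal

Two signed lists are reduced to top-N up / top-N down sets (default
N = 1000, which keeps scores uniform across treatment libraries; only
strictly positive scores can enter the up set and strictly negative the
down set). On the **intersection universe** of the two lists' symbols,
each quadrant pair (A: up/up, B: up/down, C: down/up, D: down/down) is
scored by the one-sided upper-tail hypergeometric p of its overlap
count, reported as −log10 p. The intersection universe avoids counting
genes unobservable on one platform as disagreement; an overlap of 0
yields p = 1 and contributes nothing. Raw (uncorrected) p-values are
used and the choice is recorded in provenance.

- match = (A + D) − (B + C); reversal = (B + C) − (A + D).
- Identity: reversal(t, P) = match(sign-flip(t), P) exactly.
- Pairs sharing fewer than 100 universe genes are scored but flagged
  low-confidence: hypergeometric scores on tiny universes are unstable.

The RRHO heat-map grid slides thresholds down both lists in a fixed
stride (default 100 ranks). Cells are quadrant-anchored: a threshold on
the up side of its list selects the top-i most-upregulated genes, on the
down side the most-downregulated suffix. Concordant quadrants are signed
positive, discordant negative. A pure top-prefix overlap cannot exhibit
discordant enrichment at all (for anti-correlated lists the prefix
overlap never exceeds its expectation), so the anchored convention is
what makes the mirror symmetry hold: sign-flipping one list mirrors the
grid with negated values, exactly. The grid is for visualization and QC
only; no headline score uses it.

## Randomized-control validation

The control shuffles the gene–score association *within* each study
(preserving every study's score multiset exactly), rebuilds the portrait
from the shuffled studies, and scores each shuffled study against that
control portrait; repeated for `n_reps` replicates (default 10) with
per-replicate states split from one master seed. The one-way ANOVA
(implemented from the closed-form F, two groups so F = t²,
cross-checked against `scipy.stats.f_oneway`) compares real per-study
scores against the random arm. Because the source is ambiguous about the
ANOVA's units, both modes are provided: per-study random scores averaged
over replicates (default) or pooled across replicates. Concordant
up-quadrant (A) and down-quadrant (D) component means are reported
separately, since a disorder may be more consistently dysregulated in
one direction.

**Calibration caveat.** Under pure-noise inputs the control does not
flag significance more often than nominal (empirically ~1.5% at
α = 0.05), but the null p-values are *conservative*, not uniform: every
component study is scored against a portrait built from all of them, and
the studies compete for that shared portrait, giving negatively
correlated scores within each arm (measured mean pairwise correlation
≈ −0.07; group-mean variance ≈ 60% of the iid expectation). The F test
therefore under-rejects at the null. This is a property of the
procedure's design, not of a particular scale — the same pattern holds
from 4 to 16 studies. Practically it means a significant result is
trustworthy, while the test is somewhat under-powered near the
threshold.

## Comparative analyses

Sex-divergent (or any cross-portrait) genes are exact set intersections
of one portrait's top-N up set with the other's top-N down set, and vice
versa. External-list testing (e.g. GWAS hits vs the top 1000 portrait
genes) uses the same upper-tail hypergeometric machinery as the
quadrants, by construction bit-identical; the universe defaults to the
portrait's full gene universe and is config-overridable, with the
universe size reported so sensitivity can be assessed. Interaction-based
network filtering of such lists is out of scope — gene lists are
exported for external network tools.

The embedding feature matrix takes the union of all portraits' top-N up
and down genes as features (three realistic portraits of 1000+1000 genes
land in the few-thousand range after overlap), rows are treatments with
raw signed scores plus portraits with negated signs (a perfect reverser
coincides with its portrait's row), unmeasured features are 0, and no
normalization is applied — the transformation, and the 2-D embedding
itself, are left to downstream tools.

## Synthetic data

The generator emulates the structure the method assumes: a fraction of
genes consistently dysregulated with a shared direction across studies
(default 5%, with 70% of those downregulated, mirroring the
down-dominance motif of depressed-brain signatures), a fraction with a
real effect but per-study random direction (default 5%), and null genes
with Uniform(0,1) p-values and random signs. Signal p-values follow
Beta(a, 1) — a one-parameter family standard in p-value simulation,
uniform at a = 1 and concentrated near 0 as a → 0 (default a = 0.05, a
strong signal). Cells go missing completely at random (default 10%).
Planted treatments give a chosen fraction of the consistent genes strong
p-values with the direction opposite to (reversal) or equal to
(mimicry) their true direction; the affected-gene selection is nested so
reversal grows monotonically with the fraction at a fixed seed. Default
scale is 2000 genes × 12 studies, a mid-sized meta-analysis.

Not emulated: platform-structured missingness (real missingness follows
probe content, not MCAR), inter-gene correlation, brain-region and sex
covariance, and realistic gene-symbol vintages. Passing recovery tests
therefore demonstrates that the pipeline's arithmetic and ranking
machinery recover a planted consistent signal under noise, missingness
and direction instability — not that any particular real dataset
collection carries such a signal.

## Problem sizes used in tests

The test and acceptance suites run the construction at reduced scale
chosen to exercise every code path: tiers scaled to the universe (e.g.
(10, …, 80) for 200-gene fixtures, (100, …, 800) for the 2000-gene
recovery benchmark, so all eight decay terms are active), top-N cutoffs
of 15–250, exhaustive hypergeometric oracles on universes ≤ 30 genes,
and 200-run calibration sweeps at 150 genes × 4 studies. Reference-scale
defaults (tiers 1000…8000, N = 1000) remain the package defaults
throughout.

## Known limitations

- The tier/decay scoring is a heuristic aggregation, not a likelihood
  model; no uncertainty accompanies portrait scores.
- The hypergeometric quadrant tests treat gene sets as exchangeable
  draws; co-expression makes true overlaps overdispersed, so −log10 p
  values are best read as scores, not calibrated probabilities.
- The shipped symbol map is demonstration-scale; serious use requires a
  complete, versioned nomenclature map.
- Quadrant scores depend on the intersection universe; comparing
  treatments profiled on very different platforms changes universes
  between pairs (mitigated, not removed, by the fixed top-N cutoff and
  the low-overlap flag).
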