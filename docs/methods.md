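# Methods

This note documents the models, parameter choices and numerical conventions
behind `mirtriad`, and what the synthetic-data tests do and do not establish
about real microarray studies.

## Differential expression

Each probe is tested with a one-way fixed-effect ANOVA on log2 intensities
with breed as the only factor.  With groups g and total complete samples n,
F = MS_between/MS_within on (g−1, n−g) df; the two-group case is identical to
the squared pooled-variance t statistic, which a test asserts probe-wise.
Rows with missing values use complete samples only and record `n_used`.
Degenerate rows are defined explicitly: zero spread everywhere → F = 0,
p = 1; between-group spread with zero within-group variance → F = ∞, p = 0.

Sex is *not* in the default model — breed is the single declared fixed
effect — but an additive categorical covariate can be switched on
(`anova_fixed_effect(..., covariate="sex")`), implemented as a nested-model
F-test with lsmeans evaluated at balanced covariate weights and verified
against `statsmodels` type-II ANOVA in the test suite.  In the balanced
one-factor default, lsmeans reduce to plain group means.

Selection uses strict inequalities (p < 0.05 and q < 0.2 for miRNA, q < 0.05
for mRNA, both configurable).  Fold change is 2^|Δlog2| with direction
reported separately, so all fold changes are ≥ 1.  The Benjamini–Hochberg
step-up is implemented directly (sort ascending, q(i) = min over the tail of
m·p(j)/j, capped at 1, returned in input order) because it is a core
operation with a brute-force oracle; it is additionally cross-checked
against `statsmodels.multipletests`.

## Target prediction

**Seed matching.** The seed is miRNA positions 2–8 (1-based from the 5′
end).  A site is an exact Watson–Crick reverse complement on the target; no
G:U is accepted in seed pairing.  Site types follow the canonical hierarchy
8mer > 7mer-m8 > 7mer-A1 > 6mer: a position satisfying several definitions
is reported once as the strongest requested type.  The "A1" base is an A on
the target opposite miRNA position 1, regardless of the miRNA's first base.
All three regions (5′UTR, CDS, 3′UTR) are scanned; sites never straddle a
region boundary.  Conservation and context scoring are out of scope.

**Duplex minimum free energy.** The hybridization model is intermolecular
only (no hairpins, no pseudoknots): an antiparallel chain of base pairs
(WC or G:U), consecutive pairs separated by at most 4 unpaired bases per
strand.  Energy = duplex initiation (+4.09 kcal/mol) + doublet stacking
terms + tabulated bulge/interior-loop penalties + a +0.45 kcal/mol penalty
per duplex terminus whose closing pair is AU or GU (a single-pair duplex
pays it twice — a deliberate convention mirrored by the test oracle).  The
bundled tables (`data/stack_dg.tsv`, 36 doublets; `data/loop_dg.tsv`) are a
versioned nearest-neighbor parameterization in the spirit of the Turner
rules: the 16 WC–WC stacks use the standard published ΔG°37 values, the
G:U-containing entries are approximate, and rotational symmetry
E(p,q) = E(rev q, rev p) was enforced when the table was generated.  The
table is data, not code, and can be swapped; every energy contract in the
tests (dynamic program ≡ exhaustive enumeration; monotonicity under
extension) holds for any complete table.

The dynamic program fills E(i, j) = best energy of a partial duplex whose
last pair is (miRNA i, target j), extending predecessors within the 5×5
loop-capped offset window; it is vectorized over the target axis, so a
region is scored exactly in a single pass.  Windowed scanning
(60 nt / step 20) is retained as an option for very long targets, but
because the loop cap already bounds any single duplex's span, full-region
and windowed scans agree (asserted by a test) and full-region is the
default.  Ties in the optimum are broken toward the smallest target start,
then the smallest miRNA index, making outputs deterministic.

Prediction keeps at most one duplex hit per (miRNA, transcript) (the best
energy), flags `energy` evidence at mfe ≤ −25 kcal/mol, `seed` evidence for
any canonical site, and combines them as a union by default (intersection
available): the two detectors are treated as complementary lines of
evidence, and downstream stages filter aggressively on correlation anyway.

## Correlation statistics

Pearson r on pairwise-complete observations with per-pair n recorded; the
two-sided p uses t = r·√(n−2)/√(1−r²) with n−2 df, and |r| = 1 maps to
p = 0.  Constant vectors give an undefined correlation: the pair is reported
with r = NaN, excluded from its BH family, and never propagated.  The
all-pairs family (rows(A) × rows(B)) takes a vectorized z-score/matmul path
when no values are missing and falls back to the scalar pairwise-complete
path otherwise; a test asserts both paths agree.  Analytic p-values are
validated against 20,000-draw permutation tests at n = 20.

qPCR concordance normalizes Ct to the arithmetic mean of the 5S and U6
reference Ct values — equivalent to the geometric mean of the linear-scale
reference levels — and correlates 2^−ΔCt with the chip log2 signal.

## Integration and triads

A regulatory pair requires r < 0, p and q below their thresholds, and target
evidence; the DE-restricted stage applies FDR < 0.05 within the DE×DE
correlation family.  A triad is a per-trait record requiring the three
criteria listed in the README; one pair can back several triads.  Traits are
treated independently (no multivariate adjustment).  The "top ten per
trait" ranking is not uniquely determined by the criteria, so the default
key is explicit and total: ascending miRNA–gene p, then |r| descending, then
lexicographic ids — fully deterministic under re-runs.  Networks are
exported as GraphML (round-trip tested) or SIF, with node `type`
(miRNA/gene/trait) and breed-direction attributes rather than colors.

## Enrichment

One-sided over-representation only: P(X ≥ k) from the hypergeometric
distribution with (N, K, n), equal to the one-sided Fisher exact test; a
two-sided variant sits behind a flag.  The universe defaults to the genes on
the filtered mRNA matrix (the measured background).  Gene sets are read from
standard GMT; the analysis driver constructs *synthetic* gene sets (one
seeded with recovered targets, plus random decoys), so no claims about real
pathway names are made or tested.

## Synthetic data generator

The generator emulates the study design end to end: two breeds × 10 pigs
(configurable, ≥ 3), probe-level log2 intensities with Gaussian noise
(SD 0.5 log2 units by default), planted breed shifts of ±effect/2 per group
(so group means differ by exactly `effect_size_log2`, default 1.0, with
alternating direction), presence flags drawn per probe × sample at
`presence_rate` (0.9), and mature-miRNA structure (probes alternate 2-and-1
per mature sequence, as arrays measure one mature with several probes).

Planted regulation is simultaneous at two levels: (i) expression — a target
gene is rebuilt as baseline − c·(miRNA centered) + noise with c chosen so
the miRNA explains exactly `reg_strength` of the gene's variance (expected
r = −√reg_strength); (ii) sequence — the full reverse complement of the
miRNA is written into the gene's 3′UTR at a random offset, which guarantees
seed-site complementarity and a duplex energy far below −25 kcal/mol for
any miRNA of typical base composition.  Phenotypes are linear combinations
of their driver genes plus Gaussian noise, scaled so the expected
trait–driver correlation equals `pheno_link_strength`, then standardized to
mean 0, SD 1 (trait units and scales are not modeled).  Chain members are
drawn from the non-DE probes by default so that regulatory correlations are
not confounded with the breed factor; a `chains_in_de` switch exists for
studying the confounded regime.  The 19 trait names are the muscle traits
listed in the README.

One RNG seed drives everything through child streams spawned in a fixed
order, so a seed reproduces the bundle byte-for-byte regardless of call
order.  All sequences are RNA ({A,C,G,U}); DNA input is transcribed on read.

What the generator does **not** emulate: array normalization artifacts,
probe cross-hybridization, batch or litter effects, correlated probes within
a mature (sibling probes get independent noise), non-Gaussian trait
distributions, and real regulatory network topology (chains are independent
by construction).  Passing the recovery tests therefore shows the pipeline's
logic and thresholds behave as specified under clean planted signal — not
that the biological discovery rates of a real study would match.

## Problem sizes and calibration checks

The default synthetic study is desk-scale (120 miRNA / 300 mRNA probes); the
planted-recovery experiment uses 60 miRNA / 150 mRNA probes, 30 chains at
reg_strength 0.9 and link 0.9, n = 10+10, aggregated over 5 seeds, chosen so
the whole suite runs in minutes on one CPU while keeping every stage's
statistics meaningful.  Null calibration uses 2000 probes with zero planted
effect: the empirical p < 0.05 rate must sit inside the 99 % binomial
interval around 5 %, and BH at q < 0.05 must flag essentially nothing.
Oracle suites compare the duplex DP with exhaustive enumeration (combined
length ≤ 16), BH with the direct min-over-tails definition, and the
hypergeometric tail with exact integer enumeration for all N ≤ 30.

## Known limitations

* The energy table's G:U stacks are approximate; absolute mfe values should
  not be compared against other tools, only relative rankings under this
  table.  RNAhybrid's extreme-value p-value model is not implemented.
* Probe-set summarization, RMA normalization and DABG presence-calling are
  upstream of this package: presence calls are inputs.
* Correlation plus target evidence is not causal inference; triads are
  screening hypotheses, not mechanisms.
* With `chains_in_de` enabled, breed acts as a global confounder and the
  false-discovery proportion of the triad screen rises accordingly — which
  is exactly the regime a real two-breed contrast lives in.
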