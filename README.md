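# mirtriad

Integrative miRNA–mRNA–phenotype correlation analysis for two-breed pig
muscle transcriptomics.

Muscle phenotypes such as fiber-type composition (STO/FTO/FTG), mitochondrial
respiration (state 3/state 4, respiratory control indices), metabolic enzyme
activities (GP, PFK, LDH, CS, ETC complexes I/II/IV) and adenine-nucleotide
concentrations differ systematically between breeds like Duroc and Pietrain.
`mirtriad` implements the full desk-side analysis that links microarray miRNA
expression, mRNA expression and these 19 phenotypes:

1. **Probe quality filtering** — keep probes detected (DABG-style presence
   calls) in ≥ 70 % of samples *within each breed* (inclusive threshold) and
   miRNA probes with mature sequence ≤ 29 nt.
2. **Differential expression** — per-probe one-way fixed-effect ANOVA with
   breed as the only factor: F = MS<sub>between</sub>/MS<sub>within</sub> with
   df (g−1, n−g); for two groups F = t² of the pooled t statistic.  Fold
   change is reported as 2^|Δlog2| with the direction kept separate.
   Multiple testing is controlled with Benjamini–Hochberg step-up q-values,
   q(i) = min<sub>j≥i</sub> m·p(j)/j.
3. **Target prediction** — (a) TargetScan-style exact seed matching (miRNA
   positions 2–8 from the 5′ end; site types 6mer, 7mer-A1, 7mer-m8, 8mer; no
   G:U in the seed) over 5′UTR, CDS and 3′UTR; (b) RNAhybrid-style
   intermolecular duplex minimum free energy under a nearest-neighbor model
   (doublet stacking with G:U wobble, bulge/interior loops ≤ 4 nt per side,
   duplex initiation, AU/GU end penalties) with an energy cutoff of
   −25 kcal/mol and one hit per target.  The dynamic program is exact for the
   model and is tested against exhaustive enumeration.
4. **Correlation screens** — all pairwise Pearson correlations (miRNA×mRNA,
   molecule×phenotype, gene×gene), p from t = r·√(n−2)/√(1−r²) with n−2 df
   (two-sided), BH-FDR per declared family, pairwise-complete missing-data
   handling with per-pair n.
5. **Triad assembly** — a (miRNA, gene, trait) triad requires (i) both
   molecules correlated with the trait (p < 0.05), (ii) negative miRNA–gene
   correlation (p < 0.05), and (iii) the gene being a predicted target.
   Includes top-N-per-trait reports, cross-list (e.g. mitochondria vs
   ubiquitin-proteasome gene) correlation grids, and GraphML/SIF export.
6. **Enrichment** — one-sided Fisher exact (hypergeometric upper-tail)
   over-representation of target-gene lists against GMT gene sets.
7. **Synthetic studies** — a generator that plants breed effects,
   miRNA→target repression (expression-level variance transfer plus
   sequence-level complementary 3′UTR sites) and latent-factor-driven
   phenotypes, with the full ground truth recorded, so the complete pipeline
   is testable without any data download.

## Worked example

The `analysis/` drivers run the whole study on a synthetic bundle:

```sh
python analysis/01_simulate.py --seed 1        # write results/data/
python analysis/02_filter_probes.py
python analysis/03_differential_expression.py
python analysis/04_predict_targets.py
python analysis/05_correlation_screen.py
python analysis/06_triads_network.py
python analysis/07_enrichment.py
```

With seed 1 this prints (abridged):

```
mirna: kept 118 / 120 probes (presence >= 70% per breed, length <= 29 nt)
mirna: 27 / 118 probes DE (p < 0.05, FDR < 0.2)
  -> 25 unique mature sequences, per direction {'up_in_PiNN': 11, 'up_in_Duroc': 13}
mrna: 30 / 293 probes DE (p < 0.05, FDR < 0.05)
2884 (miRNA, transcript) target pairs (union; 38 supported by both seed and energy evidence)
DE family: 810 correlations (27 miRNA x 30 mRNA); 245 significant negative at p < 0.05, FDR < 0.05
integrated: 23 pairs, 16 genes, 13 miRNA probes with target support
39 triads over 16 traits (26 miRNA probes, 32 genes)
top set: planted_target_module (k=14/K=25, p=3.65e-09, q=3.29e-08)
```

Reading this: the presence/length filters drop a handful of probes; the
breed contrast recovers most of the 20 planted differential miRNA probes;
the 15 planted full-complement 3′UTR sites all carry both seed and energy
evidence (38 pairs pass the −25 kcal/mol cutoff, including the planted
ones); integrating negative correlation with target support collapses the
candidate space to 23 regulatory pairs; and the triad stage ties miRNA–gene
pairs to specific muscle traits.  The final line shows the enrichment stage
correctly singling out the synthetic gene set seeded with recovered targets
(14 of its 25 members overlap the 32-gene query).

A `mirtriad` console command exposes the same stages
(`mirtriad simulate|filter|de|predict|correlate|pheno-correlate|triads|enrich|export`).

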