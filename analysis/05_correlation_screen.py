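#!/usr/bin/env python
"""Correlation screens: (a) DE miRNA x DE mRNA Pearson family with BH-FDR,
integrated with target predictions into negatively-correlated regulatory
pairs; (b) probe x phenotype correlations for both platforms."""

import argparse
import json
from pathlib import Path

import pandas as pd

from mirtriad.correlate import correlate_all, correlate_with_phenotypes
from mirtriad.de import DESelection
from mirtriad.integrate import integrate_de_pairs
from mirtriad.io import read_expression, read_phenotypes


def load_selection(de_path: Path, p_th: float, q_th: float) -> DESelection:
    de = pd.read_csv(de_path, sep="\t", index_col=0)
    sel = de[de["selected"]]
    return DESelection(list(sel.index), p_th, q_th, dict(zip(sel.index, sel["direction"])))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    mirna = read_expression(args.results / "mirna_filtered.tsv")
    mrna = read_expression(args.results / "mrna_filtered.tsv")
    pheno = read_phenotypes(args.data / "phenotypes.tsv")
    targets = pd.read_csv(args.results / "targets.tsv", sep="\t")

    # (a) DE-restricted correlation family + integration
    sel_mirna = load_selection(args.results / "mirna_de.tsv", 0.05, 0.2)
    sel_mrna = load_selection(args.results / "mrna_de.tsv", 0.05, 0.05)
    if sel_mirna.probe_ids and sel_mrna.probe_ids:
        family = correlate_all(mirna.subset(sel_mirna.probe_ids), mrna.subset(sel_mrna.probe_ids))
        family.to_csv(args.results / "de_correlations.tsv", sep="\t", index=False,
                      float_format="%.6g")
        neg = ((family["r"] < 0) & (family["p"] < 0.05) & (family["q"] < 0.05)).sum()
        print(f"DE family: {len(family)} correlations "
              f"({len(sel_mirna.probe_ids)} miRNA x {len(sel_mrna.probe_ids)} mRNA); "
              f"{neg} significant negative at p < 0.05, FDR < 0.05")
        pairs, summary = integrate_de_pairs(sel_mirna, sel_mrna, family, targets)
        pairs.to_csv(args.results / "regulatory_pairs.tsv", sep="\t", index=False,
                     float_format="%.6g")
        (args.results / "regulatory_pairs_summary.json").write_text(json.dumps(summary, indent=1))
        print(f"integrated: {summary['n_pairs']} pairs, {summary['n_unique_genes']} genes, "
              f"{summary['n_unique_mirnas']} miRNA probes with target support")

    # (b) phenotype correlations
    for name, mat in (("mirna", mirna), ("mrna", mrna)):
        res, summary = correlate_with_phenotypes(mat, pheno)
        res.to_csv(args.results / f"{name}_pheno_correlations.tsv", sep="\t", index=False,
                   float_format="%.6g")
        n_sig = int(summary["any_significant"].sum())
        print(f"{name}: {len(res)} probe x trait correlations; "
              f"{n_sig} probes correlate with >= 1 of {pheno.shape[0]} traits (p < 0.05)")

    mg = correlate_all(mirna, mrna)
    mg.to_csv(args.results / "mirna_mrna_correlations.tsv", sep="\t", index=False,
              float_format="%.6g")
    print(f"full miRNA x mRNA family: {len(mg)} correlations")


if __name__ == "__main__":
    main()
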