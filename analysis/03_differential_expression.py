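#!/usr/bin/env python
"""Breed differential expression: per-probe fixed-effect ANOVA, BH-FDR,
fold changes, and selection at p < 0.05 with FDR < 0.2 (miRNA) / < 0.05 (mRNA),
plus the mature-miRNA-level summary of the selected probes."""

import argparse
import json
from pathlib import Path

from mirtriad.de import anova_fixed_effect, collapse_to_mature, select_de
from mirtriad.io import read_annotations, read_expression, read_samples


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    samples = read_samples(args.data / "samples.tsv")
    thresholds = {"mirna": (0.05, 0.2), "mrna": (0.05, 0.05)}
    for platform, (p_th, q_th) in thresholds.items():
        mat = read_expression(args.results / f"{platform}_filtered.tsv")
        result = anova_fixed_effect(mat, samples)
        sel = select_de(result, p_th, q_th)
        result["selected"] = result.index.isin(set(sel.probe_ids))
        result.to_csv(args.results / f"{platform}_de.tsv", sep="\t", float_format="%.6g")
        print(f"{platform}: {len(sel.probe_ids)} / {len(result)} probes DE "
              f"(p < {p_th}, FDR < {q_th})")
        if platform == "mirna":
            annot = read_annotations(args.data / "mirna_annotation.tsv")
            summary = collapse_to_mature(sel, annot)
            (args.results / "mirna_de_mature_summary.json").write_text(
                json.dumps(summary, indent=1)
            )
            print(f"  -> {summary['n_unique_mature']} unique mature sequences, "
                  f"per direction {summary['per_direction']}")


if __name__ == "__main__":
    main()
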