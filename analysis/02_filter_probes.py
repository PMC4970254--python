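#!/usr/bin/env python
"""Probe quality filtering: presence in >= 70% of samples within each breed
(inclusive) and mature sequence length <= 29 nt for miRNA probes."""

import argparse
from pathlib import Path

from mirtriad.io import (
    length_filter,
    presence_filter,
    read_annotations,
    read_expression,
    read_samples,
    write_expression,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--min-fraction", type=float, default=0.70)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    samples = read_samples(args.data / "samples.tsv")
    for platform in ("mirna", "mrna"):
        mat = read_expression(
            args.data / f"{platform}_expression.tsv", args.data / f"{platform}_presence.tsv"
        )
        kept, report = presence_filter(mat, samples, args.min_fraction)
        if platform == "mirna":
            annot = read_annotations(args.data / "mirna_annotation.tsv")
            ok = set(length_filter(annot, max_len=29)["probe_id"])
            kept = kept.subset([p for p in kept.probe_ids if p in ok])
        write_expression(kept, args.out / f"{platform}_filtered.tsv")
        report.to_csv(args.out / f"{platform}_presence_report.tsv", sep="\t")
        print(f"{platform}: kept {kept.shape[0]} / {mat.shape[0]} probes "
              f"(presence >= {args.min_fraction:.0%} per breed"
              + (", length <= 29 nt)" if platform == "mirna" else ")"))


if __name__ == "__main__":
    main()
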