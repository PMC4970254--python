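"""Gene-set over-representation analysis via the one-sided Fisher exact test.

The p-value for a set with K members (in the universe), a query of n genes
and an overlap of k is the hypergeometric upper tail P(X >= k) drawn from a
universe of N genes — identical to the one-sided (greater) Fisher exact test
on the 2x2 membership table.  q-values are BH across all tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr
from .errors import ConsistencyError


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file (tab format: name, description, member genes...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >= 1 gene")
            sets.append(GeneSet(fields[0], fields[1], frozenset(g for g in fields[2:] if g)))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description] + sorted(s.genes)) + "\n")


def fisher_enrichment(
    query_genes,
    universe,
    gene_sets: list[GeneSet],
    alternative: str = "greater",
) -> pd.DataFrame:
    """Over-representation p per gene set, BH-corrected, sorted by p.

    Sets are intersected with the universe before testing; the query must be
    a subset of the universe.
    """
    query = set(query_genes)
    uni = set(universe)
    outside = sorted(query - uni)
    if outside:
        raise ConsistencyError(f"query genes outside the universe: {outside[:10]}")
    N, n = len(uni), len(query)
    rows = []
    for gs in gene_sets:
        members = gs.genes & uni
        K = len(members)
        k = len(members & query)
        if alternative == "greater":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        elif alternative == "two-sided":
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        a, b, c, d = k, K - k, n - k, N - K - (n - k)
        odds = np.inf if b * c == 0 and a * d > 0 else (a * d) / (b * c) if b * c else np.nan
        rows.append(
            {"set_name": gs.name, "k": k, "K": K, "n": n, "N": N,
             "odds_ratio": odds, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "odds_ratio", "p"])
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
    else:
        out["q"] = []
    return out
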