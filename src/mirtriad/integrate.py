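"""Assembly of regulatory pairs, miRNA-gene-trait triads and network exports.

The integration logic mirrors a correlation-plus-target-prediction screen:
a miRNA-mRNA pair survives when the two molecules are negatively correlated
at the declared significance thresholds *and* the gene is a predicted
target; a triad additionally requires both molecules to correlate with a
common phenotype.  Triads are per-trait records, so one (miRNA, gene) pair
can back several triads.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .de import DESelection
from .errors import ConsistencyError
from .io import ExpressionMatrix
from .correlate import pearson_pvalue, pearson_r


def integrate_de_pairs(
    de_mirna: DESelection,
    de_mrna: DESelection,
    corr: pd.DataFrame,
    targets: pd.DataFrame,
    p_max: float = 0.05,
    q_max: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Negatively correlated, target-supported pairs among the DE sets.

    ``corr`` must be the correlation family computed over exactly the DE
    miRNA x DE mRNA probes (id_a = miRNA, id_b = gene).  Returns the kept
    pairs and summary counts (pairs, unique genes, unique miRNAs).
    """
    mirna_set, mrna_set = set(de_mirna.probe_ids), set(de_mrna.probe_ids)
    stray_a = set(corr["id_a"]) - mirna_set
    stray_b = set(corr["id_b"]) - mrna_set
    if stray_a or stray_b:
        raise ConsistencyError(
            f"correlation family contains ids outside the DE sets: "
            f"{sorted(stray_a)[:3] + sorted(stray_b)[:3]}"
        )
    pair_set = set(zip(targets["mirna_id"], targets["gene_id"]))
    has_target = np.fromiter(
        (pair in pair_set for pair in zip(corr["id_a"], corr["id_b"])),
        dtype=bool, count=len(corr),
    )
    kept = corr[(corr["r"] < 0) & (corr["p"] < p_max) & (corr["q"] < q_max) & has_target].copy()
    kept = kept.rename(columns={"id_a": "mirna_id", "id_b": "gene_id"})
    kept["mirna_direction"] = kept["mirna_id"].map(de_mirna.directions).fillna("")
    kept["gene_direction"] = kept["gene_id"].map(de_mrna.directions).fillna("")
    summary = {
        "n_pairs": len(kept),
        "n_unique_genes": kept["gene_id"].nunique(),
        "n_unique_mirnas": kept["mirna_id"].nunique(),
        "p_max": p_max,
        "q_max": q_max,
    }
    return kept.reset_index(drop=True), summary


def build_triads(
    mirna_pheno: pd.DataFrame,
    gene_pheno: pd.DataFrame,
    mirna_gene: pd.DataFrame,
    targets: pd.DataFrame,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """miRNA-gene-trait triads meeting all three correlation criteria.

    A triad exists for a trait iff (1) both the miRNA and the gene correlate
    with that trait (p < p_max), (2) the miRNA-gene correlation is negative
    with p < p_max, and (3) the (miRNA, gene) pair is a predicted target.
    """
    pair_set = set(zip(targets["mirna_id"], targets["gene_id"]))
    has_target = np.fromiter(
        (pair in pair_set for pair in zip(mirna_gene["id_a"], mirna_gene["id_b"])),
        dtype=bool, count=len(mirna_gene),
    )
    mg = mirna_gene[(mirna_gene["r"] < 0) & (mirna_gene["p"] < p_max) & has_target]
    mp = mirna_pheno[mirna_pheno["p"] < p_max]
    gp = gene_pheno[gene_pheno["p"] < p_max]
    mp_cols = mp.rename(
        columns={"probe_id": "mirna_id", "r": "mirna_trait_r", "p": "mirna_trait_p"}
    )[["mirna_id", "trait", "mirna_trait_r", "mirna_trait_p"]]
    gp_cols = gp.rename(
        columns={"probe_id": "gene_id", "r": "gene_trait_r", "p": "gene_trait_p"}
    )[["gene_id", "trait", "gene_trait_r", "gene_trait_p"]]
    mg_cols = mg.rename(
        columns={"id_a": "mirna_id", "id_b": "gene_id", "r": "mirna_gene_r", "p": "mirna_gene_p"}
    )[["mirna_id", "gene_id", "mirna_gene_r", "mirna_gene_p"]]
    triads = mg_cols.merge(mp_cols, on="mirna_id").merge(gp_cols, on=["gene_id", "trait"])
    cols = [
        "mirna_id", "gene_id", "trait",
        "mirna_gene_r", "mirna_gene_p",
        "mirna_trait_r", "mirna_trait_p",
        "gene_trait_r", "gene_trait_p",
    ]
    triads = triads[cols].sort_values(["trait", "mirna_gene_p", "mirna_id", "gene_id"])
    return triads.reset_index(drop=True)


def top_pairs_per_trait(triads: pd.DataFrame, n: int = 10, rank_key=None) -> pd.DataFrame:
    """The n best triads per trait.

    Default ranking: ascending miRNA-gene p, ties broken by |r| descending,
    then lexicographic (mirna_id, gene_id) for full determinism.
    """
    if triads.empty:
        return triads.copy()
    df = triads.copy()
    if rank_key is None:
        df["_absr"] = -df["mirna_gene_r"].abs()
        sort_cols = ["mirna_gene_p", "_absr", "mirna_id", "gene_id"]
    else:
        sort_cols = list(rank_key)
    out = (
        df.sort_values(["trait"] + sort_cols, kind="stable")
        .groupby("trait", sort=True)
        .head(n)
        .drop(columns=["_absr"], errors="ignore")
    )
    return out.reset_index(drop=True)


@dataclass
class CrossListMatrix:
    """Complete correlation grid between two gene lists (e.g. mito vs UPS)."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    significant: pd.DataFrame  # p < alpha flags
    alpha: float


def crosslist_correlation(
    expr: ExpressionMatrix, genes_a, genes_b, alpha: float = 0.05
) -> CrossListMatrix:
    """Pearson r and p for every (gene in A) x (gene in B) cell."""
    genes_a, genes_b = list(genes_a), list(genes_b)
    known = set(expr.probe_ids)
    missing = [g for g in genes_a + genes_b if g not in known]
    if missing:
        raise KeyError(f"genes not in expression matrix: {missing}")
    r = pd.DataFrame(index=genes_a, columns=genes_b, dtype=float)
    p = pd.DataFrame(index=genes_a, columns=genes_b, dtype=float)
    n_shared = len(expr.sample_ids)
    for ga in genes_a:
        x = expr.values.loc[ga].to_numpy(dtype=float)
        for gb in genes_b:
            y = expr.values.loc[gb].to_numpy(dtype=float)
            rv, n = pearson_r(x, y)
            r.loc[ga, gb] = rv
            p.loc[ga, gb] = pearson_pvalue(rv, n) if pd.notna(rv) else float("nan")
            n_shared = n
    return CrossListMatrix(r, p, n_shared, p < alpha, alpha)


def build_graph(pairs: pd.DataFrame | None = None, triads: pd.DataFrame | None = None) -> nx.Graph:
    """Bipartite (or tripartite, with traits) regulatory graph.

    Node attribute ``type`` is one of miRNA / gene / trait; pair edges carry
    the correlation, direction attributes follow the breed contrast when
    present.
    """
    g = nx.Graph()
    if pairs is not None:
        for row in pairs.itertuples(index=False):
            g.add_node(row.mirna_id, type="miRNA")
            g.add_node(row.gene_id, type="gene")
            attrs = {"relation": "represses", "r": float(row.r), "p": float(row.p)}
            if hasattr(row, "mirna_direction") and row.mirna_direction:
                g.nodes[row.mirna_id]["direction"] = row.mirna_direction
            if hasattr(row, "gene_direction") and row.gene_direction:
                g.nodes[row.gene_id]["direction"] = row.gene_direction
            g.add_edge(row.mirna_id, row.gene_id, **attrs)
    if triads is not None:
        for row in triads.itertuples(index=False):
            g.add_node(row.mirna_id, type="miRNA")
            g.add_node(row.gene_id, type="gene")
            g.add_node(row.trait, type="trait")
            g.add_edge(
                row.mirna_id, row.gene_id,
                relation="represses", r=float(row.mirna_gene_r), p=float(row.mirna_gene_p),
            )
            g.add_edge(
                row.mirna_id, row.trait,
                relation="correlates", r=float(row.mirna_trait_r), p=float(row.mirna_trait_p),
            )
            g.add_edge(
                row.gene_id, row.trait,
                relation="correlates", r=float(row.gene_trait_r), p=float(row.gene_trait_p),
            )
    return g


def export_graph(
    path,
    pairs: pd.DataFrame | None = None,
    triads: pd.DataFrame | None = None,
    fmt: str = "graphml",
) -> nx.Graph:
    """Write the regulatory network as GraphML or SIF; returns the graph."""
    g = build_graph(pairs=pairs, triads=triads)
    if fmt == "graphml":
        nx.write_graphml(g, str(path))
    elif fmt == "sif":
        if g.number_of_edges() == 0:
            raise ValueError("SIF export requires a non-empty edge set")
        with open(path, "w") as fh:
            for a, b, data in sorted(g.edges(data=True)):
                fh.write(f"{a}\t{data.get('relation', 'edge')}\t{b}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return g
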