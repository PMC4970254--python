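"""Pair integration, triad assembly, top-N reports, cross-list grids, exports."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirtriad.de import DESelection
from mirtriad.errors import ConsistencyError
from mirtriad.integrate import (
    build_triads,
    crosslist_correlation,
    export_graph,
    integrate_de_pairs,
    top_pairs_per_trait,
)

from conftest import make_matrix


def corr_frame(rows):
    """rows: (id_a, id_b, r, p, q)"""
    df = pd.DataFrame(rows, columns=["id_a", "id_b", "r", "p", "q"])
    df["n"] = 20
    return df


def target_frame(pairs):
    return pd.DataFrame(
        [{"mirna_id": m, "gene_id": g, "evidence": "seed"} for m, g in pairs]
    )


def pheno_frame(rows):
    """rows: (probe_id, trait, r, p)"""
    return pd.DataFrame(rows, columns=["probe_id", "trait", "r", "p"])


# ---------------------------------------------------------------------------
# integrate_de_pairs
# ---------------------------------------------------------------------------

def toy_selections():
    mir = DESelection(["m1", "m2"], 0.05, 0.2, {"m1": "up_in_Duroc", "m2": "up_in_PiNN"})
    gene = DESelection(["g1", "g2", "g3"], 0.05, 0.05, {"g1": "up_in_PiNN"})
    return mir, gene


def test_toy_integration_keeps_the_supported_negative_pair():
    mir, gene = toy_selections()
    corr = corr_frame(
        [
            ("m1", "g1", -0.9, 1e-6, 1e-5),
            ("m1", "g2", 0.9, 1e-6, 1e-5),   # positive: excluded
            ("m1", "g3", -0.85, 1e-5, 1e-4),  # no target evidence: excluded
            ("m2", "g1", -0.1, 0.7, 0.8),
            ("m2", "g2", 0.2, 0.4, 0.6),
            ("m2", "g3", 0.0, 1.0, 1.0),
        ]
    )
    targets = target_frame([("m1", "g1"), ("m1", "g2")])
    pairs, summary = integrate_de_pairs(mir, gene, corr, targets)
    assert list(pairs["mirna_id"]) == ["m1"] and list(pairs["gene_id"]) == ["g1"]
    assert summary["n_pairs"] == 1 and summary["n_unique_genes"] == 1
    assert summary["n_unique_mirnas"] == 1
    assert pairs.iloc[0]["mirna_direction"] == "up_in_Duroc"


def test_integration_rejects_ids_outside_de_sets():
    mir, gene = toy_selections()
    corr = corr_frame([("mX", "g1", -0.9, 1e-6, 1e-5)])
    with pytest.raises(ConsistencyError):
        integrate_de_pairs(mir, gene, corr, target_frame([]))


def test_tightening_thresholds_never_adds_pairs(rng):
    mir = DESelection([f"m{i}" for i in range(5)], 0.05, 0.2)
    gene = DESelection([f"g{i}" for i in range(8)], 0.05, 0.05)
    rows = []
    for m in mir.probe_ids:
        for g in gene.probe_ids:
            r = rng.uniform(-1, 1)
            p = rng.uniform(0, 0.2)
            rows.append((m, g, r, p, p * 1.5))
    corr = corr_frame(rows)
    targets = target_frame([(m, g) for m in mir.probe_ids for g in gene.probe_ids])
    loose, _ = integrate_de_pairs(mir, gene, corr, targets, p_max=0.1, q_max=0.2)
    tight, _ = integrate_de_pairs(mir, gene, corr, targets, p_max=0.05, q_max=0.1)
    loose_set = set(zip(loose["mirna_id"], loose["gene_id"]))
    tight_set = set(zip(tight["mirna_id"], tight["gene_id"]))
    assert tight_set <= loose_set


# ---------------------------------------------------------------------------
# build_triads
# ---------------------------------------------------------------------------

def test_triad_requires_all_three_criteria():
    mp = pheno_frame([("m1", "STO", -0.8, 0.001)])
    gp = pheno_frame([("g1", "STO", 0.85, 0.0005), ("g2", "STO", 0.2, 0.2)])
    mg = corr_frame([("m1", "g1", -0.9, 1e-5, 1e-4), ("m1", "g2", -0.9, 1e-5, 1e-4)])
    targets = target_frame([("m1", "g1"), ("m1", "g2")])
    triads = build_triads(mp, gp, mg, targets)
    # g2 fails the gene-trait criterion (p = 0.2)
    assert list(triads["gene_id"]) == ["g1"]
    assert triads.iloc[0]["trait"] == "STO"


def test_triads_are_per_trait_records():
    mp = pheno_frame([("m1", "STO", -0.8, 0.001), ("m1", "ATP", -0.7, 0.004)])
    gp = pheno_frame([("g1", "STO", 0.8, 0.001), ("g1", "ATP", 0.75, 0.002)])
    mg = corr_frame([("m1", "g1", -0.9, 1e-5, 1e-4)])
    triads = build_triads(mp, gp, mg, target_frame([("m1", "g1")]))
    assert len(triads) == 2 and set(triads["trait"]) == {"STO", "ATP"}


def test_positive_mirna_gene_correlation_blocks_triads():
    mp = pheno_frame([("m1", "STO", 0.8, 0.001)])
    gp = pheno_frame([("g1", "STO", 0.8, 0.001)])
    mg = corr_frame([("m1", "g1", 0.9, 1e-5, 1e-4)])
    assert build_triads(mp, gp, mg, target_frame([("m1", "g1")])).empty


def test_triads_recovered_from_planted_chains(small_study, small_pipeline):
    res = small_pipeline
    planted = {(m, g) for m, g, _, _ in small_study.truth.planted_pairs}
    reported = set(zip(res.triads["mirna_id"], res.triads["gene_id"]))
    assert len(planted & reported) / len(planted) >= 0.5  # strong chains, small study


def test_triad_count_monotone_in_threshold(small_pipeline):
    res = small_pipeline
    tighter = build_triads(res.mirna_pheno, res.gene_pheno, res.mirna_gene, res.targets, p_max=0.01)
    looser = build_triads(res.mirna_pheno, res.gene_pheno, res.mirna_gene, res.targets, p_max=0.05)
    assert len(tighter) <= len(looser)


# ---------------------------------------------------------------------------
# top_pairs_per_trait
# ---------------------------------------------------------------------------

def triads_fixture(n, trait="STO", rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n):
        rows.append(
            {
                "mirna_id": f"m{i}", "gene_id": f"g{i}", "trait": trait,
                "mirna_gene_r": -rng.uniform(0.5, 1.0), "mirna_gene_p": rng.uniform(0, 0.05),
                "mirna_trait_r": 0.7, "mirna_trait_p": 0.01,
                "gene_trait_r": 0.7, "gene_trait_p": 0.01,
            }
        )
    return pd.DataFrame(rows)


def test_top_ten_of_twentyfive_ordered_by_p():
    top = top_pairs_per_trait(triads_fixture(25), n=10)
    assert len(top) == 10
    assert top["mirna_gene_p"].is_monotonic_increasing


def test_fewer_than_n_returns_all():
    assert len(top_pairs_per_trait(triads_fixture(4), n=10)) == 4


def test_ties_broken_by_abs_r_then_ids_stably():
    df = triads_fixture(4)
    df["mirna_gene_p"] = 0.01
    df["mirna_gene_r"] = [-0.6, -0.9, -0.9, -0.7]
    t1 = top_pairs_per_trait(df, n=3)
    t2 = top_pairs_per_trait(df.sample(frac=1, random_state=5), n=3)
    assert list(t1["mirna_id"]) == ["m1", "m2", "m3"]
    assert list(t1["mirna_id"]) == list(t2["mirna_id"])


# ---------------------------------------------------------------------------
# cross-list correlation
# ---------------------------------------------------------------------------

def test_crosslist_grid_is_complete(rng):
    expr = make_matrix(rng.normal(size=(14, 20)), probe_ids=[f"G{i}" for i in range(14)])
    mito = [f"G{i}" for i in range(8)]
    ups = [f"G{i}" for i in range(8, 14)]
    grid = crosslist_correlation(expr, mito, ups)
    assert grid.r.shape == (8, 6) and grid.p.shape == (8, 6)
    assert grid.n == 20
    assert grid.significant.to_numpy().dtype == bool


def test_crosslist_self_correlation_is_one(rng):
    expr = make_matrix(rng.normal(size=(3, 10)), probe_ids=["a", "b", "c"])
    grid = crosslist_correlation(expr, ["a", "b"], ["a", "c"])
    assert grid.r.loc["a", "a"] == pytest.approx(1.0)


def test_crosslist_missing_gene_raises(rng):
    expr = make_matrix(rng.normal(size=(2, 10)), probe_ids=["a", "b"])
    with pytest.raises(KeyError):
        crosslist_correlation(expr, ["a"], ["ghost"])


def test_crosslist_p_matches_scalar_formula(rng):
    from mirtriad.correlate import pearson_pvalue, pearson_r

    expr = make_matrix(rng.normal(size=(4, 20)), probe_ids=list("abcd"))
    grid = crosslist_correlation(expr, ["a", "b"], ["c", "d"])
    r, n = pearson_r(expr.values.loc["a"], expr.values.loc["d"])
    assert grid.p.loc["a", "d"] == pytest.approx(pearson_pvalue(r, n), rel=1e-12)


# ---------------------------------------------------------------------------
# graph export
# ---------------------------------------------------------------------------

def pairs_fixture():
    return pd.DataFrame(
        {
            "mirna_id": ["m1", "m1", "m2"],
            "gene_id": ["g1", "g2", "g1"],
            "r": [-0.9, -0.8, -0.7],
            "p": [0.001, 0.002, 0.003],
            "mirna_direction": ["up_in_Duroc", "up_in_Duroc", "up_in_PiNN"],
            "gene_direction": ["up_in_PiNN", "up_in_PiNN", "up_in_Duroc"],
        }
    )


def test_graphml_round_trip_preserves_structure_and_attributes(tmp_path):
    path = tmp_path / "net.graphml"
    g = export_graph(path, pairs=pairs_fixture())
    back = nx.read_graphml(path)
    assert nx.is_isomorphic(g, back)
    assert back.number_of_edges() == 3
    node_types = nx.get_node_attributes(back, "type")
    assert node_types["m1"] == "miRNA" and node_types["g1"] == "gene"
    assert back.edges["m1", "g1"]["r"] == pytest.approx(-0.9)


def test_empty_triad_set_gives_valid_empty_graphml(tmp_path):
    path = tmp_path / "empty.graphml"
    export_graph(path, triads=pd.DataFrame(columns=[
        "mirna_id", "gene_id", "trait", "mirna_gene_r", "mirna_gene_p",
        "mirna_trait_r", "mirna_trait_p", "gene_trait_r", "gene_trait_p"]))
    assert nx.read_graphml(path).number_of_nodes() == 0


def test_sif_export_one_edge_per_line(tmp_path):
    path = tmp_path / "net.sif"
    export_graph(path, pairs=pairs_fixture(), fmt="sif")
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 3
    assert all(len(line.split("\t")) == 3 for line in lines)


def test_sif_export_refuses_empty_edge_set(tmp_path):
    with pytest.raises(ValueError):
        export_graph(tmp_path / "x.sif", pairs=pairs_fixture().iloc[0:0], fmt="sif")


def test_pair_graph_is_bipartite(tmp_path):
    g = export_graph(tmp_path / "n.graphml", pairs=pairs_fixture())
    types = nx.get_node_attributes(g, "type")
    for a, b in g.edges():
        assert {types[a], types[b]} == {"miRNA", "gene"}
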