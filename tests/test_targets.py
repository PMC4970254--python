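"""Seed matching and duplex-MFE prediction, checked against brute-force oracles."""

import itertools

import numpy as np
import pytest

from mirtriad.errors import ConfigError
from mirtriad.simulate import plant_target_site
from mirtriad.targets import (
    EnergyParams,
    duplex_mfe,
    find_seed_matches,
    predict_targets,
    revcomp,
    scan_duplex,
    seed_of,
    target_pair_set,
)

from conftest import make_transcript

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"
PARAMS = EnergyParams.default()
_END_PAIRS = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
_ALLOWED = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def brute_force_mfe(m: str, t: str, params: EnergyParams = PARAMS):
    """Exhaustive minimum over all valid non-crossing intermolecular pairings.

    A pairing is a chain of (i, j) with i strictly increasing, j strictly
    decreasing (antiparallel), each pair WC or G:U, and at most
    max_loop_per_side unpaired bases between consecutive pairs on each
    strand.  Energy: initiation + per-step stack/loop terms + AU/GU
    penalties at both duplex termini.
    """
    span = params.max_loop_per_side + 1
    candidates = [
        (i, j) for i in range(len(m)) for j in range(len(t)) if (m[i], t[j]) in _ALLOWED
    ]

    def end_pen(pair):
        i, j = pair
        return params.au_end_penalty if (m[i], t[j]) in _END_PAIRS else 0.0

    best = [None]

    def energy(chain):
        e = params.duplex_init_dG + end_pen(chain[0]) + end_pen(chain[-1])
        for (i1, j1), (i2, j2) in zip(chain, chain[1:]):
            di, dj = i2 - i1, j1 - j2
            if di == 1 and dj == 1:
                e += params.stack_dG[(m[i1] + t[j1], m[i2] + t[j2])]
            else:
                e += params.loop_dG[(di - 1, dj - 1)]
        return e

    def extend(chain):
        e = energy(chain)
        if best[0] is None or e < best[0]:
            best[0] = e
        i1, j1 = chain[-1]
        for (i, j) in candidates:
            if 1 <= i - i1 <= span and 1 <= j1 - j <= span:
                extend(chain + [(i, j)])

    for pair in candidates:
        extend([pair])
    return best[0]


def random_rna(rng, n):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# seed extraction and matching
# ---------------------------------------------------------------------------

def test_seed_of_let7_is_positions_2_to_8():
    assert seed_of(LET7) == "GAGGUAG"


def test_seed_of_8mer_input():
    assert seed_of("UAACCGGA") == "AACCGGA"


def test_seed_of_short_input_raises():
    with pytest.raises(ValueError):
        seed_of("UAACCGG")


def test_seed_match_7mer_m8_at_planted_motif():
    tr = make_transcript(utr3="G" * 40)
    tr = plant_target_site(tr, LET7, "3UTR", 5)  # plants CUACCUC = rc(GAGGUAG)
    matches = find_seed_matches(LET7, tr)
    assert len(matches) == 1
    (hit,) = matches
    assert hit.region == "3UTR" and hit.site_type == "7mer-m8"
    assert (hit.start, hit.end) == (5, 12)
    assert tr.region_seq("3UTR")[hit.start : hit.end] == "CUACCUC"


def test_seed_match_site_types_classified_by_flanks():
    seed_rc6 = revcomp(LET7[1:7])  # rc of positions 2-7
    m8c = revcomp(LET7[7])  # complement of position 8
    cases = {
        "6mer": "GG" + seed_rc6 + "GG",
        "7mer-m8": "G" + m8c + seed_rc6 + "GG",
        "7mer-A1": "GG" + seed_rc6 + "AGG",
        "8mer": "G" + m8c + seed_rc6 + "AGG",
    }
    for expected, utr3 in cases.items():
        tr = make_transcript(utr3=utr3)
        matches = [s for s in find_seed_matches(LET7, tr) if s.region == "3UTR"]
        assert [s.site_type for s in matches] == [expected], expected
        (hit,) = matches
        assert hit.end - hit.start == {"6mer": 6, "7mer-m8": 7, "7mer-A1": 7, "8mer": 8}[expected]


def test_seed_match_target_subsequence_reverse_complements_the_seed(rng):
    """Every reported match's core reverse-complements miRNA positions 2-7."""
    for _ in range(20):
        mirna = random_rna(rng, 22)
        tr = make_transcript(utr5=random_rna(rng, 30), cds=random_rna(rng, 80),
                             utr3=random_rna(rng, 60))
        for s in find_seed_matches(mirna, tr):
            site = tr.region_seq(s.region)[s.start : s.end]
            assert revcomp(mirna[1:7]) in site


def test_no_seed_matches_in_poly_A():
    tr = make_transcript(utr5="A" * 30, cds="A" * 50, utr3="A" * 40)
    assert find_seed_matches(LET7, tr) == []


def test_requested_site_types_restrict_output():
    tr = make_transcript(utr3="GG" + revcomp(LET7[1:7]) + "GG")  # bare 6mer
    assert find_seed_matches(LET7, tr, site_types={"7mer-m8", "8mer"}) == []
    assert len(find_seed_matches(LET7, tr, site_types={"6mer"})) == 1


# ---------------------------------------------------------------------------
# energy model and dynamic program
# ---------------------------------------------------------------------------

def test_default_params_complete_and_wc_stabilizing():
    p = EnergyParams.default()
    assert len(p.stack_dG) == 36
    for l in range(5):
        for r in range(5):
            if (l, r) != (0, 0):
                assert p.loop_dG[(l, r)] > 0


def test_incomplete_stack_table_rejected():
    p = EnergyParams.default()
    broken = dict(p.stack_dG)
    broken.pop(("AU", "AU"))
    with pytest.raises(ConfigError):
        EnergyParams(broken, p.loop_dG)


def test_no_complementary_pair_means_no_duplex():
    assert duplex_mfe("AAAA", "AAAA").mfe is None
    assert duplex_mfe("CCCC", "AAAA").mfe is None


def test_perfect_5mer_duplex_energy_is_hand_sum_of_table():
    """GCACG vs its reverse complement CGUGC: four stacks read off the table
    (GC/CG -3.42, CA/GU -2.11, AC/UG -2.24, CG/GC -2.36) + init 4.09 = -6.04;
    both terminal pairs are G:C so no AU-end penalty applies."""
    res = duplex_mfe("GCACG", revcomp("GCACG"))
    assert res.mfe == pytest.approx(-6.04, abs=1e-9)
    assert res.pairing_string == "(((((&)))))"


def test_dp_equals_brute_force_on_random_small_pairs(rng):
    for _ in range(200):
        m = random_rna(rng, int(rng.integers(2, 9)))
        t = random_rna(rng, int(rng.integers(2, 9)))
        dp = duplex_mfe(m, t).mfe
        bf = brute_force_mfe(m, t)
        if bf is None:
            assert dp is None
        else:
            assert dp == pytest.approx(bf, abs=1e-9), (m, t)


def test_appending_bases_never_raises_the_optimum(rng):
    """Extending both strands keeps every previous pairing available."""
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    for _ in range(30):
        m = random_rna(rng, 8)
        t = random_rna(rng, 10)
        base = duplex_mfe(m, t).mfe
        extra = random_rna(rng, 1)
        ext = duplex_mfe(m + extra, comp[extra] + t).mfe
        if base is not None:
            assert ext is not None and ext <= base + 1e-9


def test_duplex_result_is_deterministic(rng):
    m, t = random_rna(rng, 12), random_rna(rng, 30)
    r1, r2 = duplex_mfe(m, t), duplex_mfe(m, t)
    assert r1.mfe == r2.mfe and r1.pairs == r2.pairs and r1.pairing_string == r2.pairing_string


def test_windowed_scan_agrees_with_full_length(rng):
    tr = make_transcript(utr5=random_rna(rng, 40), cds=random_rna(rng, 150),
                         utr3=random_rna(rng, 100))
    m = random_rna(rng, 22)
    full = scan_duplex(m, tr, window=None)
    windowed = scan_duplex(m, tr, window=60, step=20)
    assert full is not None and windowed is not None
    assert windowed.mfe == pytest.approx(full.mfe, abs=1e-9)


# ---------------------------------------------------------------------------
# predict_targets
# ---------------------------------------------------------------------------

def test_planted_full_complement_yields_both_evidence_types(rng):
    mirna = random_rna(rng, 21)
    tr = make_transcript(gene_id="G", utr3=random_rna(rng, 80))
    tr = plant_target_site(tr, mirna, "3UTR", 10, kind="full")
    table = predict_targets({"m": mirna}, [tr])
    assert len(table) == 1
    row = table.iloc[0]
    assert row["evidence"] == "seed+energy"
    assert row["mfe"] <= -25.0


def test_union_keeps_seed_only_pairs_intersection_drops_them():
    tr = make_transcript(gene_id="G", utr3="GG" + revcomp(LET7[1:8]) + "GGGG")
    union = predict_targets({"m": LET7}, [tr], mode="union")
    inter = predict_targets({"m": LET7}, [tr], mode="intersection")
    assert list(union["evidence"]) == ["seed"]  # seed site alone is far above -25
    assert inter.empty
    assert target_pair_set(inter) <= target_pair_set(union)


def test_intersection_is_subset_of_union_on_random_batch(rng):
    mirnas = {f"m{i}": random_rna(rng, 21) for i in range(4)}
    trs = [
        make_transcript(gene_id=f"G{j}", utr5=random_rna(rng, 30),
                        cds=random_rna(rng, 90), utr3=random_rna(rng, 70))
        for j in range(6)
    ]
    union = target_pair_set(predict_targets(mirnas, trs, mode="union"))
    inter = target_pair_set(predict_targets(mirnas, trs, mode="intersection"))
    assert inter <= union


def test_single_best_hit_kept_per_transcript(rng):
    mirna = random_rna(rng, 21)
    utr3 = random_rna(rng, 30) + revcomp(mirna) + random_rna(rng, 20) + revcomp(mirna[5:]) + "GG"
    tr = make_transcript(gene_id="G", utr3=utr3)
    table = predict_targets({"m": mirna}, [tr])
    assert len(table) == 1
    full_site_start = 30  # the full complement is the better of the two sites
    assert table.iloc[0]["energy_start"] == pytest.approx(full_site_start, abs=1)
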