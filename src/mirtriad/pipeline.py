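"""End-to-end orchestration: filter -> DE -> targets -> correlations -> triads.

This is the module the analysis drivers, the test suite and the acceptance
script all share, so every headline number is produced by one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import de as de_mod
from .correlate import correlate_all, correlate_with_phenotypes
from .integrate import build_triads, integrate_de_pairs
from .io import ExpressionMatrix, presence_filter
from .simulate import SimConfig, SyntheticStudy, generate_dataset
from .targets import predict_targets


@dataclass
class Thresholds:
    """Significance thresholds for each pipeline stage (strict inequalities)."""

    de_mirna_p: float = 0.05
    de_mirna_q: float = 0.2
    de_mrna_p: float = 0.05
    de_mrna_q: float = 0.05
    corr_p: float = 0.05
    corr_q: float = 0.05
    pheno_p: float = 0.05
    energy_cutoff: float = -25.0
    presence_min_fraction: float = 0.70
    target_mode: str = "union"


@dataclass
class PipelineResult:
    study: SyntheticStudy
    mirna_filtered: ExpressionMatrix
    mrna_filtered: ExpressionMatrix
    de_mirna: pd.DataFrame
    de_mrna: pd.DataFrame
    de_mirna_sel: de_mod.DESelection
    de_mrna_sel: de_mod.DESelection
    targets: pd.DataFrame
    mirna_pheno: pd.DataFrame
    gene_pheno: pd.DataFrame
    mirna_gene: pd.DataFrame
    triads: pd.DataFrame
    de_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    de_pair_summary: dict = field(default_factory=dict)


def run_pipeline(
    study: SyntheticStudy,
    thresholds: Thresholds | None = None,
    with_de_integration: bool = False,
) -> PipelineResult:
    """Run the full analysis on a study bundle.

    The phenotype-triad branch follows the three-criterion rule (both
    molecules correlate with a common trait, the pair correlates negatively,
    the gene is a predicted target).  ``with_de_integration`` additionally
    runs the DE-restricted pair integration (negative correlation at FDR
    among DE miRNA x DE mRNA with target support).
    """
    th = thresholds or Thresholds()
    mirna_f, _ = presence_filter(study.mirna, study.samples, th.presence_min_fraction)
    mrna_f, _ = presence_filter(study.mrna, study.samples, th.presence_min_fraction)

    de_mirna = de_mod.anova_fixed_effect(mirna_f, study.samples)
    de_mrna = de_mod.anova_fixed_effect(mrna_f, study.samples)
    sel_mirna = de_mod.select_de(de_mirna, th.de_mirna_p, th.de_mirna_q)
    sel_mrna = de_mod.select_de(de_mrna, th.de_mrna_p, th.de_mrna_q)

    annot = study.mirna_annotation
    kept = set(mirna_f.probe_ids)
    mirna_seqs = dict(
        zip(annot["probe_id"], annot["sequence"])
    )
    mirna_seqs = {p: s for p, s in mirna_seqs.items() if p in kept}
    transcripts = {g: t for g, t in study.transcripts.items() if g in set(mrna_f.probe_ids)}
    targets = predict_targets(
        mirna_seqs, transcripts, mode=th.target_mode, energy_cutoff=th.energy_cutoff
    )

    mirna_pheno, _ = correlate_with_phenotypes(mirna_f, study.phenotypes, th.pheno_p)
    gene_pheno, _ = correlate_with_phenotypes(mrna_f, study.phenotypes, th.pheno_p)
    mirna_gene = correlate_all(mirna_f, mrna_f, family_fdr=True)
    triads = build_triads(mirna_pheno, gene_pheno, mirna_gene, targets, p_max=th.pheno_p)

    result = PipelineResult(
        study, mirna_f, mrna_f, de_mirna, de_mrna, sel_mirna, sel_mrna,
        targets, mirna_pheno, gene_pheno, mirna_gene, triads,
    )
    if with_de_integration and sel_mirna.probe_ids and sel_mrna.probe_ids:
        de_corr = correlate_all(
            mirna_f.subset(sel_mirna.probe_ids), mrna_f.subset(sel_mrna.probe_ids)
        )
        result.de_pairs, result.de_pair_summary = integrate_de_pairs(
            sel_mirna, sel_mrna, de_corr, targets, th.corr_p, th.corr_q
        )
    return result


def recovery_config(seed: int) -> SimConfig:
    """Study conditions for the planted-chain recovery experiment:
    30 strong miRNA -> gene -> trait chains in a 20-pig design."""
    return SimConfig(
        seed=seed,
        n_per_group=10,
        n_mirna_probes=60,
        n_mrna_probes=150,
        n_de_mirna=10,
        n_de_mrna=20,
        n_planted_pairs=30,
        reg_strength=0.9,
        pheno_link_strength=0.9,
    )


def recovery_experiment(base_seed: int, n_seeds: int = 5) -> dict:
    """Planted-structure recovery aggregated over seeds.

    Recovery: fraction of planted (miRNA, gene) regulations present among the
    triad output; FDP: fraction of reported triad (miRNA, gene) pairs that
    were not planted.  Both are evaluated at the mature-sequence level, since
    probes sharing one mature sequence carry identical target evidence.
    """
    recovered = 0
    planted_total = 0
    false_pairs = 0
    pairs_total = 0
    false_triads = 0
    triads_total = 0
    per_seed = []
    for k in range(n_seeds):
        study = generate_dataset(recovery_config(int(base_seed) + k))
        res = run_pipeline(study)
        probe2mat = dict(
            zip(study.mirna_annotation["probe_id"], study.mirna_annotation["mature_name"])
        )
        planted = {(probe2mat[m], g) for m, g, _, _ in study.truth.planted_pairs}
        triad_pairs = [
            (probe2mat[m], g)
            for m, g in zip(res.triads["mirna_id"], res.triads["gene_id"])
        ]
        reported = set(triad_pairs)
        rec = len(planted & reported)
        n_false_triads = sum(pair not in planted for pair in triad_pairs)
        recovered += rec
        planted_total += len(planted)
        false_pairs += len(reported - planted)
        pairs_total += len(reported)
        false_triads += n_false_triads
        triads_total += len(triad_pairs)
        per_seed.append(
            {
                "seed": int(base_seed) + k,
                "planted": len(planted),
                "recovered": rec,
                "reported_pairs": len(reported),
                "false_pairs": len(reported - planted),
                "triads": len(triad_pairs),
                "false_triads": n_false_triads,
            }
        )
    recovery = 100.0 * recovered / planted_total if planted_total else float("nan")
    fdp_triads = 100.0 * false_triads / triads_total if triads_total else 0.0
    fdp_pairs = 100.0 * false_pairs / pairs_total if pairs_total else 0.0
    return {
        "recovery_pct": recovery,
        "fdp_pct": fdp_triads,
        "fdp_pairs_pct": fdp_pairs,
        "n_seeds": n_seeds,
        "per_seed": per_seed,
    }


def null_calibration(seed: int, n_probes: int = 2000, n_per_group: int = 10) -> dict:
    """Type-I error of the DE stage on a zero-effect simulation."""
    config = SimConfig(
        seed=seed,
        n_per_group=n_per_group,
        n_mirna_probes=n_probes,
        n_mrna_probes=10,
        n_de_mirna=0,
        n_de_mrna=0,
        n_planted_pairs=0,
        effect_size_log2=0.0,
        presence_rate=1.0,
    )
    study = generate_dataset(config)
    de = de_mod.anova_fixed_effect(study.mirna, study.samples)
    rate = float((de["p"] < 0.05).mean())
    q_hits = int((de["q"] < 0.05).sum())
    return {"p05_rate": rate, "q05_discoveries": q_hits, "n_probes": n_probes}
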