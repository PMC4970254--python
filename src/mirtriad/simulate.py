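"""Synthetic two-breed muscle study with planted ground truth.

Emulates the design of a Duroc vs Pietrain (PiNN) microarray experiment:
two breed groups of ``n_per_group`` pigs, probe-level log2 intensities with
planted breed effects, miRNA -> target negative regulation realized both at
the expression level (variance transfer) and at the sequence level (planted
complementary sites), and 19 muscle phenotypes driven by latent expression
factors.  Expression is simulated directly on the log2 scale with Gaussian
noise — the object downstream code consumes is the post-normalization
matrix, so array-level normalization is deliberately not modeled.

Everything is driven by one seed; sub-generators draw from child streams
spawned in a fixed order so outputs are byte-identical per seed regardless
of call order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    ExpressionMatrix,
    SampleTable,
    Transcript,
    write_annotations,
    write_expression,
    write_phenotypes,
    write_samples,
    write_transcripts,
)
from .targets import revcomp

#: The 19 muscle phenotypes: fiber-type composition (STO/FTO/FTG),
#: mitochondrial respiration (states 3/4, respiratory control indices),
#: metabolic enzyme activities (GP, PFK, LDH, CS, ETC complexes) and
#: adenine-nucleotide concentrations.
TRAIT_NAMES = (
    "STO", "FTO", "FTG",
    "State3_pyruvate", "State3_succinate", "State4_CAT",
    "RCI_pyruvate", "RCI_succinate",
    "GP", "PFK", "LDH", "CS",
    "ComplexI", "ComplexII", "ComplexIV",
    "IMP", "AMP", "ADP", "ATP",
)

_REGION_LENGTHS = {"5UTR": 50, "CDS": 200, "3UTR": 120}


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic generator.

    Defaults reproduce the real study's design scale where it is known
    (10 pigs per breed) and desk-scale probe counts elsewhere.
    """

    seed: int = 0
    n_per_group: int = 10
    n_mirna_probes: int = 120
    n_mrna_probes: int = 300
    n_de_mirna: int = 20
    n_de_mrna: int = 40
    n_planted_pairs: int = 15
    effect_size_log2: float = 1.0
    reg_strength: float = 0.6
    noise_sd_log2: float = 0.5
    presence_rate: float = 0.9
    n_phenotypes: int = 19
    pheno_link_strength: float = 0.7
    mirna_length: int = 22
    n_low_presence: int = 0  # probes forced to sparse detection (filter testing)
    sex_effect_log2: float = 0.0  # off by default; breed is the only planted factor
    chains_in_de: bool = False  # draw planted chain members from the DE sets

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise ConfigError("n_per_group must be >= 3")
        if self.n_de_mirna > self.n_mirna_probes or self.n_de_mrna > self.n_mrna_probes:
            raise ConfigError("planted DE probes cannot exceed probe counts")
        if not (0 <= self.presence_rate <= 1):
            raise ConfigError("presence_rate must be in [0, 1]")
        if not (0 <= self.reg_strength <= 1):
            raise ConfigError("reg_strength must be in [0, 1]")
        if not (0 <= self.pheno_link_strength <= 1):
            raise ConfigError("pheno_link_strength must be in [0, 1]")
        if self.n_phenotypes > len(TRAIT_NAMES):
            raise ConfigError(f"at most {len(TRAIT_NAMES)} phenotypes available")
        pool = self.n_de_mirna if self.chains_in_de else self.n_mirna_probes - self.n_de_mirna
        gene_pool = self.n_de_mrna if self.chains_in_de else self.n_mrna_probes - self.n_de_mrna
        if self.n_planted_pairs > min(pool, gene_pool):
            raise ConfigError("n_planted_pairs exceeds the available probe pool")
        if self.mirna_length < 8:
            raise ConfigError("miRNA length must be >= 8")


@dataclass
class GroundTruth:
    """What was planted: DE sets, regulatory pairs with site coordinates, trait drivers."""

    de_mirna_ids: list[str]
    de_mrna_ids: list[str]
    planted_pairs: list[tuple[str, str, str, int]]  # (mirna probe, gene, region, seed-site start)
    pheno_loadings: dict[str, list[str]]  # trait -> driving gene probe ids

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["planted_pairs"] = [tuple(p) for p in d["planted_pairs"]]
        return cls(**d)


@dataclass
class SyntheticStudy:
    config: SimConfig
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    mirna_annotation: pd.DataFrame
    transcripts: dict[str, Transcript]
    samples: SampleTable
    phenotypes: pd.DataFrame  # traits x samples
    truth: GroundTruth


def plant_target_site(
    transcript: Transcript,
    mirna_seq: str,
    region: str,
    position: int,
    kind: str = "7mer-m8",
) -> Transcript:
    """Write a complementary site into a transcript region.

    ``kind``: '7mer-m8' plants the reverse complement of seed positions 2-8;
    '8mer' additionally puts an A opposite miRNA position 1; 'full' plants
    the reverse complement of the entire miRNA.  ``position`` is the offset
    of the planted motif within the region.
    """
    seq = mirna_seq
    if kind == "7mer-m8":
        motif = revcomp(seq[1:8])
    elif kind == "8mer":
        motif = revcomp(seq[1:8]) + "A"
    elif kind == "full":
        motif = revcomp(seq)
    else:
        raise ValueError(f"unknown site kind {kind!r}")
    if region not in transcript.regions:
        raise IndexError(f"{transcript.gene_id} has no {region} region")
    start, end = transcript.regions[region]
    if position < 0 or start + position + len(motif) > end:
        raise IndexError(
            f"site of length {len(motif)} at offset {position} does not fit in "
            f"{region} of length {end - start}"
        )
    abs_start = start + position
    new_seq = transcript.sequence[:abs_start] + motif + transcript.sequence[abs_start + len(motif):]
    return Transcript(transcript.gene_id, new_seq, dict(transcript.regions))


def seed_site_offset(mirna_seq: str, kind: str) -> int:
    """Offset of the seed-complement (positions 2-8) within a planted motif."""
    if kind in ("7mer-m8", "8mer"):
        return 0
    if kind == "full":
        return len(mirna_seq) - 8
    raise ValueError(f"unknown site kind {kind!r}")


def simulate_phenotypes(
    expr: ExpressionMatrix,
    loadings: dict[str, dict[str, float]],
    noise_sd: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Traits as linear combinations of driver probes plus Gaussian noise.

    ``loadings``: trait -> {probe_id: coefficient}.  Returns traits x samples.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    known = set(expr.probe_ids)
    out = {}
    for trait, coefs in loadings.items():
        missing = [p for p in coefs if p not in known]
        if missing:
            raise KeyError(f"{trait}: unknown driver probe(s) {missing}")
        vec = np.zeros(len(expr.sample_ids))
        for probe, coef in coefs.items():
            vec = vec + coef * expr.values.loc[probe].to_numpy(dtype=float)
        if noise_sd > 0:
            vec = vec + rng.normal(0.0, noise_sd, size=vec.shape)
        out[trait] = vec
    return pd.DataFrame(out, index=expr.sample_ids).T


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])


def generate_dataset(config: SimConfig) -> SyntheticStudy:
    """Generate the full synthetic study bundle for one seed."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_assign, rng_mirna, rng_mrna, rng_seqs, rng_pres, rng_pheno = (
        np.random.default_rng(s) for s in streams
    )
    n = config.n_per_group
    sample_ids = [f"Duroc_{i+1:02d}" for i in range(n)] + [f"PiNN_{i+1:02d}" for i in range(n)]
    breeds = ["Duroc"] * n + ["PiNN"] * n
    sexes = ["F" if i % 2 == 0 else "M" for i in range(2 * n)]
    samples = SampleTable(pd.DataFrame({"sample_id": sample_ids, "breed": breeds, "sex": sexes}))
    is_duroc = np.array([b == "Duroc" for b in breeds])

    mirna_ids = [f"mir_probe_{i:04d}" for i in range(config.n_mirna_probes)]
    gene_ids = [f"GENE{i:04d}" for i in range(config.n_mrna_probes)]

    # planted DE sets and chain membership (fixed-order draws from rng_assign)
    de_mirna = [str(x) for x in rng_assign.choice(mirna_ids, size=config.n_de_mirna, replace=False)]
    de_mrna = [str(x) for x in rng_assign.choice(gene_ids, size=config.n_de_mrna, replace=False)]
    mirna_pool = de_mirna if config.chains_in_de else [m for m in mirna_ids if m not in set(de_mirna)]
    gene_pool = de_mrna if config.chains_in_de else [g for g in gene_ids if g not in set(de_mrna)]
    chain_mirnas = [str(x) for x in rng_assign.choice(mirna_pool, size=config.n_planted_pairs, replace=False)]
    chain_genes = [str(x) for x in rng_assign.choice(gene_pool, size=config.n_planted_pairs, replace=False)]

    # miRNA expression: baseline + breed shift (alternating direction) + noise
    mirna_vals = _expression_block(
        rng_mirna, mirna_ids, sample_ids, is_duroc, set(de_mirna),
        config.effect_size_log2, config.noise_sd_log2,
    )
    if config.sex_effect_log2 != 0.0:
        is_f = np.array([s == "F" for s in sexes])
        shift = rng_mirna.choice([-1.0, 1.0], size=len(mirna_ids))
        mirna_vals += np.outer(shift, np.where(is_f, 0.5, -0.5)) * config.sex_effect_log2

    # mRNA expression; planted chain genes inherit variance from their miRNA
    mrna_vals = _expression_block(
        rng_mrna, gene_ids, sample_ids, is_duroc, set(de_mrna),
        config.effect_size_log2, config.noise_sd_log2,
    )
    mirna_index = {m: i for i, m in enumerate(mirna_ids)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    rho = config.reg_strength
    for mir, gene in zip(chain_mirnas, chain_genes):
        m_row = mirna_vals[mirna_index[mir]]
        centered = m_row - m_row.mean()
        sd_m = centered.std()
        resid_sd = config.noise_sd_log2
        base = mrna_vals[gene_index[gene]].mean()
        noise = rng_mrna.normal(0.0, resid_sd, size=len(sample_ids))
        if rho >= 1.0 and sd_m > 0:  # perfect anticorrelation, no residual noise
            mrna_vals[gene_index[gene]] = base - centered
            continue
        if rho == 0.0 or sd_m == 0.0:
            coef = 0.0
        else:
            coef = np.sqrt(rho / (1.0 - rho)) * resid_sd / sd_m
        mrna_vals[gene_index[gene]] = base - coef * centered + noise

    # sequences: mature miRNAs (1-2 probes per mature) and transcripts
    annotation = _mirna_annotation(rng_seqs, mirna_ids, config.mirna_length)
    seq_of = dict(zip(annotation["probe_id"], annotation["sequence"]))
    transcripts: dict[str, Transcript] = {}
    lengths = _REGION_LENGTHS
    total_len = sum(lengths.values())
    bounds = {}
    off = 0
    for reg in ("5UTR", "CDS", "3UTR"):
        bounds[reg] = (off, off + lengths[reg])
        off += lengths[reg]
    for gid in gene_ids:
        transcripts[gid] = Transcript(gid, _random_rna(rng_seqs, total_len), dict(bounds))
    planted_pairs: list[tuple[str, str, str, int]] = []
    for mir, gene in zip(chain_mirnas, chain_genes):
        seq = seq_of[mir]
        region = "3UTR"
        max_off = lengths[region] - len(seq)
        pos = int(rng_seqs.integers(0, max_off + 1))
        transcripts[gene] = plant_target_site(transcripts[gene], seq, region, pos, kind="full")
        planted_pairs.append((mir, gene, region, pos + seed_site_offset(seq, "full")))

    # presence flags
    mirna_pres = rng_pres.random((len(mirna_ids), len(sample_ids))) < config.presence_rate
    mrna_pres = rng_pres.random((len(gene_ids), len(sample_ids))) < config.presence_rate
    for k in range(min(config.n_low_presence, len(mirna_ids))):
        mirna_pres[k] = rng_pres.random(len(sample_ids)) < 0.3

    mirna_mat = ExpressionMatrix(
        pd.DataFrame(mirna_vals, index=mirna_ids, columns=sample_ids),
        pd.DataFrame(mirna_pres, index=mirna_ids, columns=sample_ids),
    )
    mrna_mat = ExpressionMatrix(
        pd.DataFrame(mrna_vals, index=gene_ids, columns=sample_ids),
        pd.DataFrame(mrna_pres, index=gene_ids, columns=sample_ids),
    )

    # phenotypes: chain genes drive traits round-robin; link strength sets the
    # expected trait-driver correlation, remaining traits are pure noise
    traits = list(TRAIT_NAMES[: config.n_phenotypes])
    loadings: dict[str, dict[str, float]] = {t: {} for t in traits}
    link = config.pheno_link_strength
    for k, gene in enumerate(chain_genes):
        trait = traits[k % len(traits)]
        g_row = mrna_vals[gene_index[gene]]
        sd_g = g_row.std()
        coef = 0.0 if sd_g == 0 or link == 0 else link / sd_g
        loadings[trait][gene] = coef
    noise_sd = float(np.sqrt(max(1.0 - link**2, 0.0))) if link < 1 else 0.0
    pheno = simulate_phenotypes(mrna_mat, loadings, noise_sd, rng=rng_pheno)
    # pure-noise traits and standardization to mean 0, SD 1
    for t in traits:
        if not loadings[t]:
            pheno.loc[t] = rng_pheno.normal(0.0, 1.0, size=len(sample_ids))
    pheno = pheno.sub(pheno.mean(axis=1), axis=0)
    sds = pheno.std(axis=1, ddof=0).replace(0.0, 1.0)
    pheno = pheno.div(sds, axis=0)
    pheno = pheno.loc[traits]

    truth = GroundTruth(
        de_mirna_ids=sorted(de_mirna),
        de_mrna_ids=sorted(de_mrna),
        planted_pairs=planted_pairs,
        pheno_loadings={t: sorted(loadings[t]) for t in traits},
    )
    return SyntheticStudy(
        config, mirna_mat, mrna_mat, annotation, transcripts, samples, pheno, truth
    )


def _expression_block(rng, probe_ids, sample_ids, is_duroc, de_set, effect, noise_sd):
    n_probes, n_samples = len(probe_ids), len(sample_ids)
    baseline = rng.uniform(4.0, 12.0, size=n_probes)
    direction = rng.choice([-1.0, 1.0], size=n_probes)
    vals = np.tile(baseline[:, None], (1, n_samples))
    breed_sign = np.where(is_duroc, 0.5, -0.5)
    for i, probe in enumerate(probe_ids):
        if probe in de_set:
            vals[i] += direction[i] * effect * breed_sign
    vals += rng.normal(0.0, noise_sd, size=vals.shape)
    return vals


def _mirna_annotation(rng, mirna_ids, length) -> pd.DataFrame:
    """Assign probes to mature miRNAs (alternating 2 and 1 probes per mature)."""
    rows = []
    mature_idx = 0
    i = 0
    while i < len(mirna_ids):
        take = 2 if mature_idx % 2 == 0 else 1
        name = f"ssc-miR-{1000 + mature_idx}"
        seq = _random_rna(rng, length)
        for probe in mirna_ids[i : i + take]:
            rows.append({"probe_id": probe, "mature_name": name, "sequence": seq})
        i += take
        mature_idx += 1
    df = pd.DataFrame(rows)
    df["length"] = df["sequence"].str.len()
    return df


def write_bundle(study: SyntheticStudy, outdir) -> None:
    """Write the complete bundle as plain-text TSV/FASTA/JSON files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(study.mirna, out / "mirna_expression.tsv", out / "mirna_presence.tsv")
    write_expression(study.mrna, out / "mrna_expression.tsv", out / "mrna_presence.tsv")
    write_annotations(study.mirna_annotation, out / "mirna_annotation.tsv")
    write_transcripts(study.transcripts, out / "transcripts.fasta", out / "regions.tsv")
    write_samples(study.samples, out / "samples.tsv")
    write_phenotypes(study.phenotypes, out / "phenotypes.tsv")
    (out / "ground_truth.json").write_text(study.truth.to_json())
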