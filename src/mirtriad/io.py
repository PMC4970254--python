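"""Readers, writers and probe quality filters.

All expression values are normalized log2 intensities (normalization itself
happens upstream and is not part of this package).  Presence calls are 0/1
detection flags per probe x sample.  Sequences are handled on the RNA
alphabet {A, C, G, U}; DNA input is transcribed (T -> U) on read.
Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

REGIONS = ("5UTR", "CDS", "3UTR")

_RNA_BASES = frozenset("ACGU")


def as_rna(seq: str) -> str:
    """Uppercase and transcribe a sequence to RNA; reject non-nucleotide letters."""
    s = str(seq).strip().upper().replace("T", "U")
    bad = set(s) - _RNA_BASES
    if bad:
        raise FormatError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 expression with optional presence flags.

    ``values`` is a DataFrame indexed by probe id with sample ids as columns.
    NaN marks a missing measurement; infinities are rejected.
    """

    values: pd.DataFrame
    presence: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if np.isinf(arr).any():
            raise FormatError("expression values must be finite")
        if self.presence is not None:
            p = self.presence
            if list(p.index) != list(v.index) or list(p.columns) != list(v.columns):
                raise FormatError("presence table must share probe and sample ids with values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, probe_ids) -> "ExpressionMatrix":
        probe_ids = list(probe_ids)
        pres = self.presence.loc[probe_ids] if self.presence is not None else None
        return ExpressionMatrix(self.values.loc[probe_ids], pres)


@dataclass
class SampleTable:
    """Sample metadata: breed (group) and optional sex."""

    frame: pd.DataFrame  # columns: sample_id, breed[, sex]

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("sample_id", "breed"):
            if col not in f.columns:
                raise FormatError(f"sample table missing column {col!r}")
        if f["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in sample table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def groups(self) -> dict[str, list[str]]:
        """Breed -> ordered sample ids."""
        return {
            breed: list(sub["sample_id"])
            for breed, sub in self.frame.groupby("breed", sort=True)
        }


@dataclass
class Transcript:
    """A transcript sequence with 5'UTR / CDS / 3'UTR boundaries.

    ``regions`` maps region name to a 0-based half-open (start, end) slice of
    ``sequence``.  Any region may be absent (empty subsequence).
    """

    gene_id: str
    sequence: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = as_rna(self.sequence)
        L = len(self.sequence)
        spans = []
        for name, (start, end) in self.regions.items():
            if name not in REGIONS:
                raise FormatError(f"{self.gene_id}: unknown region {name!r}")
            if not (0 <= start <= end <= L):
                raise FormatError(
                    f"{self.gene_id}: region {name} [{start},{end}) outside record of length {L}"
                )
            spans.append((start, end, name))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise FormatError(f"{self.gene_id}: regions {n1} and {n2} overlap")

    def region_seq(self, region: str) -> str:
        if region not in REGIONS:
            raise KeyError(region)
        if region not in self.regions:
            return ""
        start, end = self.regions[region]
        return self.sequence[start:end]


# ---------------------------------------------------------------------------
# Tabular readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, presence_path=None) -> ExpressionMatrix:
    """Read a probes x samples TSV (first column probe id, header sample ids)."""
    values = _read_matrix_tsv(path)
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = values.index[
            values.apply(lambda r: pd.to_numeric(r, errors="coerce").isna().any(), axis=1)
        ].tolist()
        raise FormatError(f"{path}: non-numeric cells in rows {bad[:5]}")
    presence = None
    if presence_path is not None:
        presence = _read_matrix_tsv(presence_path).astype(bool)
        presence = presence.reindex(index=values.index, columns=values.columns)
        if presence.isna().any().any():
            raise FormatError(f"{presence_path}: presence ids do not match expression ids")
    return ExpressionMatrix(values, presence)


def _read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated probe id(s) {dups}")
    if df.isna().all(axis=1).any():
        # a fully-empty row usually indicates a ragged file
        bad = df.index[df.isna().all(axis=1)].tolist()
        raise FormatError(f"{path}: empty/ragged row(s) {bad[:5]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_expression(matrix: ExpressionMatrix, path, presence_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.6f", index_label="probe_id")
    if presence_path is not None:
        if matrix.presence is None:
            raise FormatError("matrix has no presence table to write")
        matrix.presence.astype(int).to_csv(path_or_buf=presence_path, sep="\t", index_label="probe_id")


def read_samples(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype=str))


def write_samples(samples: SampleTable, path) -> None:
    samples.frame.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Probe annotation TSV: probe_id, mature_name, sequence (RNA or DNA)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "mature_name", "sequence"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotation missing column {col!r}")
    if df["probe_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated probe ids in annotation")
    df = df.copy()
    df["sequence"] = df["sequence"].map(as_rna)
    df["length"] = df["sequence"].str.len()
    return df


def write_annotations(annotations: pd.DataFrame, path) -> None:
    cols = [c for c in ("probe_id", "mature_name", "sequence") if c in annotations.columns]
    annotations[cols].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV: traits as rows, samples as columns."""
    return _read_matrix_tsv(path)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", float_format="%.6f", index_label="trait")


def read_transcripts(fasta_path, regions_path) -> dict[str, Transcript]:
    """Load transcript FASTA plus a region table (gene_id, region, start, end)."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    regions = pd.read_csv(regions_path, sep="\t")
    for col in ("gene_id", "region", "start", "end"):
        if col not in regions.columns:
            raise FormatError(f"{regions_path}: region table missing column {col!r}")
    per_gene: dict[str, dict[str, tuple[int, int]]] = {g: {} for g in seqs}
    for row in regions.itertuples(index=False):
        gid = str(row.gene_id)
        if gid not in seqs:
            raise FormatError(f"{regions_path}: region row references unknown record {gid!r}")
        if row.region in per_gene[gid]:
            raise FormatError(f"{gid}: duplicate region row {row.region}")
        per_gene[gid][row.region] = (int(row.start), int(row.end))
    return {gid: Transcript(gid, seqs[gid], per_gene[gid]) for gid in seqs}


def write_transcripts(transcripts: dict[str, Transcript], fasta_path, regions_path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.gene_id, description="")
        for t in transcripts.values()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {"gene_id": t.gene_id, "region": name, "start": s, "end": e}
        for t in transcripts.values()
        for name, (s, e) in sorted(t.regions.items(), key=lambda kv: kv[1])
    ]
    pd.DataFrame(rows, columns=["gene_id", "region", "start", "end"]).to_csv(
        regions_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Probe quality filters
# ---------------------------------------------------------------------------

def presence_filter(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    min_fraction: float = 0.70,
    rule: str = "all_groups",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop probes detected in too few samples per breed.

    Under ``all_groups`` (default) a probe is kept iff its present-fraction is
    >= ``min_fraction`` (inclusive) in every breed; under ``any_group`` one
    qualifying breed suffices.  Returns the filtered matrix and a per-probe
    report with the per-breed fractions and kept status.
    """
    if matrix.presence is None:
        raise ValueError("presence_filter requires presence flags on the matrix")
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    if rule not in ("all_groups", "any_group"):
        raise ValueError(f"unknown rule {rule!r}")

    report = pd.DataFrame(index=matrix.values.index)
    fractions = []
    for breed, ids in samples.groups().items():
        frac = matrix.presence[ids].mean(axis=1)
        report[f"fraction_{breed}"] = frac
        fractions.append(frac >= min_fraction)
    ok = pd.concat(fractions, axis=1)
    kept = ok.all(axis=1) if rule == "all_groups" else ok.any(axis=1)
    report["kept"] = kept
    return matrix.subset(report.index[kept]), report


def length_filter(annotations: pd.DataFrame, max_len: int = 29) -> pd.DataFrame:
    """Keep probes whose mature sequence is <= ``max_len`` nt (default drops >= 30 nt)."""
    if "length" not in annotations.columns:
        annotations = annotations.assign(length=annotations["sequence"].str.len())
    return annotations[annotations["length"] <= max_len].copy()
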