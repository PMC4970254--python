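import numpy as np
import pandas as pd
import pytest

from mirtriad.io import ExpressionMatrix, SampleTable, Transcript
from mirtriad.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study used across modules."""
    return generate_dataset(
        SimConfig(
            seed=11,
            n_mirna_probes=40,
            n_mrna_probes=60,
            n_de_mirna=8,
            n_de_mrna=10,
            n_planted_pairs=6,
            reg_strength=0.8,
            pheno_link_strength=0.8,
        )
    )


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    """The full pipeline run once on the small study."""
    from mirtriad.pipeline import run_pipeline

    return run_pipeline(small_study, with_de_integration=True)


@pytest.fixture()
def two_breed_samples():
    ids = [f"D{i}" for i in range(1, 11)] + [f"P{i}" for i in range(1, 11)]
    return SampleTable(
        pd.DataFrame({"sample_id": ids, "breed": ["Duroc"] * 10 + ["PiNN"] * 10})
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_matrix(values, probe_ids=None, sample_ids=None, presence=None):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"p{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    vals = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    pres = (
        pd.DataFrame(np.asarray(presence, dtype=bool), index=probe_ids, columns=sample_ids)
        if presence is not None
        else None
    )
    return ExpressionMatrix(vals, pres)


def make_transcript(gene_id="G1", utr5="A" * 20, cds="C" * 30, utr3="G" * 25):
    seq = utr5 + cds + utr3
    regions = {}
    off = 0
    for name, part in (("5UTR", utr5), ("CDS", cds), ("3UTR", utr3)):
        if part:
            regions[name] = (off, off + len(part))
        off += len(part)
    return Transcript(gene_id, seq, regions)
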