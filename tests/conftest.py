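import numpy as np
import pandas as pd
import pytest

from geqtl import ExpressionMatrix, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotypes(values, snp_ids=None, sample_ids=None, chrom=None, pos=None):
    """Small GenotypeMatrix builder for tests."""
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    snp_ids = snp_ids or [f"snp{j+1}" for j in range(s)]
    sample_ids = sample_ids or [f"ind{i+1}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * s,
            "pos": pos if pos is not None else [100 * (j + 1) for j in range(s)],
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(sample_ids, snp_ids, values, meta)


def make_expression(values, probe_ids=None, sample_ids=None, gene_ids=None,
                    chrom=None, source=None):
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    probe_ids = probe_ids or [f"probe{j+1}" for j in range(t)]
    sample_ids = sample_ids or [f"ind{i+1}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "gene_id": gene_ids if gene_ids is not None else ["G1"] * t,
            "chrom": chrom if chrom is not None else ["1"] * t,
            "source_db": source if source is not None else ["RefSeq"] * t,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ExpressionMatrix(sample_ids, probe_ids, values, meta)


def genotypes_from_counts(n_aa: int, n_ab: int, n_bb: int) -> np.ndarray:
    """Additive codes from genotype counts."""
    return np.array([0.0] * n_aa + [1.0] * n_ab + [2.0] * n_bb)
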