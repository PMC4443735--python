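import numpy as np
import pandas as pd
import pytest

from smallherd.genotype_io import SAMPLE_COLUMNS, GenotypeMatrix


def make_genotypes(
    calls,
    positions=None,
    chromosomes=None,
    sample_ids=None,
    allele_a="G",
    allele_b="A",
    roh_qc_applied=False,
):
    """Build a valid GenotypeMatrix from raw arrays for tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    positions = np.asarray(
        positions if positions is not None else (np.arange(m) + 1) * 1000
    )
    chromosomes = np.asarray(
        chromosomes if chromosomes is not None else np.ones(m, dtype=int)
    )
    markers = pd.DataFrame(
        {
            "snp_id": [f"snp{k}" for k in range(m)],
            "chromosome": chromosomes,
            "position_bp": positions,
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    sample_ids = sample_ids or [f"ind{i}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sire_id": "0",
            "dam_id": "0",
            "birth_year": 2000,
            "breed": "TST",
            "sex": "U",
        }
    )[SAMPLE_COLUMNS]
    g = GenotypeMatrix(calls=calls, markers=markers, samples=samples)
    g = g.sort_markers()  # fixtures may hand positions in any order
    g.roh_qc_applied = roh_qc_applied
    g.validate()
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
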