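import numpy as np
import pandas as pd
import pytest

from famvc.genio import GenotypeMatrix, Pedigree
from famvc.simgen import PedigreeDesign, build_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def trio_pedigree():
    """Father, mother and one child."""
    return Pedigree(pd.DataFrame({
        "iid": ["dad", "mum", "kid"],
        "father": ["", "", "dad"],
        "mother": ["", "", "mum"],
        "sex": [1, 2, 1],
        "family": ["f1", "f1", "f1"],
    }))


def make_geno(dosage, chrom=None):
    """GenotypeMatrix from a raw dosage array (freq derived, minor-oriented)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    meta = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(m)],
        "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
        "pos": np.arange(m) + 1,
        "a1": ["A"] * m,
        "a2": ["B"] * m,
    })
    return GenotypeMatrix.from_dosage(dosage, [f"i{j}" for j in range(n)], meta)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort for engine tests: 40 families (2+2) + 40 singletons."""
    return build_cohort(PedigreeDesign(n_families=40, n_singletons=40),
                        n_snps=800, seed=7)
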