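import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mdrkit.io_model import Dataset, SnpMeta
from mdrkit import studydata

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table3_dataset() -> Dataset:
    """Individual-level expansion of the study's published genotype counts."""
    return studydata.counts_to_dataset(seed=0)


@pytest.fixture()
def toy_dataset() -> Dataset:
    """Tiny two-SNP dataset with covariates for plumbing tests."""
    geno = np.array(
        [[0, 1], [1, 2], [2, 0], [0, 0], [1, 1], [2, 2], [0, 2], [1, 0]],
        dtype=np.int8,
    )
    pheno = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.int8)
    cov = pd.DataFrame(
        {
            "age": [55, 48, 62, 41, 39, 44, 58, 47],
            "sex": ["female", "male", "female", "female", "male", "female", "male", "female"],
            "bmi": [28.0, 31.5, 26.2, 24.0, 22.8, 27.7, 25.1, 29.9],
        }
    )
    metas = [
        SnpMeta("rs_a", gene="GENEA", ref_allele="C", minor_allele="T", maf=0.3),
        SnpMeta("rs_b", gene="GENEB", ref_allele="G", minor_allele="A", maf=0.2),
    ]
    return Dataset(
        individuals=[f"i{k}" for k in range(8)],
        genotypes=geno,
        phenotype=pheno,
        covariates=cov,
        snp_meta=metas,
    )


def random_dataset(rng: np.random.Generator, n: int, p: int, missing_rate: float = 0.0) -> Dataset:
    """Small random dataset helper shared by oracle-equivalence tests."""
    geno = rng.integers(0, 3, size=(n, p)).astype(np.int8)
    if missing_rate:
        geno[rng.random((n, p)) < missing_rate] = -1
    pheno = np.zeros(n, dtype=np.int8)
    n_cases = int(rng.integers(max(2, n // 4), n - max(2, n // 4)))
    pheno[rng.permutation(n)[:n_cases]] = 1
    return Dataset(
        individuals=[f"r{k}" for k in range(n)],
        genotypes=geno,
        phenotype=pheno,
        snp_meta=[
            SnpMeta(f"rs{j:03d}", ref_allele="A", minor_allele="B") for j in range(p)
        ],
    )
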