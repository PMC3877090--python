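import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from inflamsig import CovariateTable, GenotypeMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_genotypes(codes, rs_ids=None, chrom="1", sample_ids=None) -> GenotypeMatrix:
    """Small GenotypeMatrix from a plain array."""
    codes = np.asarray(codes, dtype=np.int8)
    n, p = codes.shape
    if rs_ids is None:
        rs_ids = [f"rs{j}" for j in range(p)]
    chroms = [chrom] * p if isinstance(chrom, str) else list(chrom)
    snps = pd.DataFrame({
        "rs": rs_ids, "gene": [f"G{j}" for j in range(p)], "chrom": chroms,
        "pos": 100 * (np.arange(p) + 1), "allele_a": "A", "allele_b": "B",
        "func": "",
    })
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(codes, snps, sample_ids)


def make_covariates(labels, age=60.0) -> CovariateTable:
    """Labels-only covariate table (other covariates held constant)."""
    labels = np.asarray(labels)
    return CovariateTable(pd.DataFrame({
        "label": labels, "gender": "female", "smoking": "never",
        "region": "Barcelona", "age": age,
    }))


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort reused across read-only tests."""
    from inflamsig import SimConfig, simulate_cohort
    cfg = SimConfig(n_cases=150, n_controls=150, p_snps=60, n_causal=3,
                    missing_rate=0.02, seed=1234)
    return simulate_cohort(cfg)
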