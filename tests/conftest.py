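import numpy as np
import pytest

from mesodx.core import CodeSet, CountMatrix, Probe, SampleMeta, Stage, \
    default_codeset
from mesodx.normalization import normalize
from mesodx.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def codeset():
    return default_codeset()


@pytest.fixture
def mini_codeset():
    """2 endogenous, 2 housekeeping, 2 positive, 3 negative probes."""
    return CodeSet(probes=(
        Probe("G1", "Endogenous"),
        Probe("G2", "Endogenous"),
        Probe("HK1", "Housekeeping"),
        Probe("HK2", "Housekeeping"),
        Probe("POS1", "Positive"),
        Probe("POS2", "Positive"),
        Probe("NEG1", "Negative"),
        Probe("NEG2", "Negative"),
        Probe("NEG3", "Negative"),
    ), name="mini")


def make_matrix(codeset, counts, labels=None, stage=Stage.RAW, ages=None):
    n = np.asarray(counts).shape[1]
    labels = labels or ["UNKNOWN"] * n
    ages = ages or [None] * n
    samples = [SampleMeta(sample_id=f"s{j+1}", label=labels[j], age=ages[j])
               for j in range(n)]
    return CountMatrix(codeset=codeset, samples=samples,
                       counts=np.asarray(counts, float), stage=stage)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture(scope="session")
def seeded_cohort():
    """Raw 25 MPM + 15 MH cohort with 66 planted effects, seed 42."""
    cfg = SimConfig(seed=42)
    matrix, truth = simulate_cohort(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def normalized_cohort(seeded_cohort):
    cfg, matrix, truth = seeded_cohort
    normed, report = normalize(matrix)
    return cfg, normed, truth, report
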