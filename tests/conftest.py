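import numpy as np
import pytest

from csftoolkit import GeneratorConfig, PatientRecord, generate


@pytest.fixture
def median_record() -> PatientRecord:
    """A 50-year-old patient at the cohort-median analyte values
    (CSF albumin 260 mg/L, CSF IgG 50 mg/L, serum albumin 36 g/L,
    serum IgG 11 g/L)."""
    return PatientRecord(
        patient_id="median",
        age=50,
        sex="female",
        isi_positive=False,
        cns_ad=False,
        csf_albumin=260.0,
        csf_igg=50.0,
        serum_albumin=36.0,
        serum_igg=11.0,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (n=266), fixed seed, shared across tests."""
    return generate(GeneratorConfig(), seed=20260919)


@pytest.fixture(scope="session")
def big_cohort():
    """Large synthetic cohort for distribution-level checks."""
    return generate(GeneratorConfig(n=50_000), seed=20260919)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
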