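import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Duplex-association parameters of the unmodified 11-mer reference duplex
# (enthalpy kcal/mol, entropy cal/(mol*K)) used as generating values
# throughout the thermodynamics tests.
REF_DH = -118.8
REF_DS = -350.9

#: total single-strand concentration series (mol/L): 3-12 uM per strand
CONC_SERIES = (6e-6, 12e-6, 18e-6, 24e-6)

GUIDE_21MER = "ACUGCUAGCUGAAUGGUCAAU"


@pytest.fixture(scope="session")
def ref_params():
    return REF_DH, REF_DS


@pytest.fixture(scope="session")
def big_truth_and_records():
    """5150-transcript UTR set with exactly 150 planted seed matches.

    Session-scoped: shared by the statistical power and type-I error tests.
    """
    from seedscreen.seed_match import extract_seed
    from seedscreen.synthetic import TranscriptomeSimSpec, gen_utr_set

    motif = extract_seed(GUIDE_21MER).target_match
    spec = TranscriptomeSimSpec(
        n_transcripts=5150,
        motif=motif,
        planted_fraction=150 / 5150,
        utr_length_range=(200, 800),
        seed=101,
    )
    records, truth = gen_utr_set(spec)
    assert truth.n_sm == 150
    return records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
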