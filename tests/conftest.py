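import numpy as np
import pytest
from hypothesis import settings

import stagenet as sn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """One synthetic cohort at reduced size (fast unit-test fixture)."""
    cfg = sn.default_scenario(seed=11, samples_per_group=40)["SYNTH-A"]
    return sn.generate(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """One cohort at the study conditions (100 samples/group, strength 0.95)."""
    cfg = sn.default_scenario(seed=5)["SYNTH-A"]
    return sn.generate(cfg)


@pytest.fixture(scope="session")
def study_profile(study_cohort):
    return sn.stage_profile(study_cohort.expression, study_cohort.annotations,
                            study_cohort.truth.cohort, "MYC")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def expr_tsv(tmp_path):
    """A tiny Firehose-dialect expression TSV with the datatype-tag row."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "Hybridization REF\tTCGA-B0-0001-01A-11R\tTCGA-B0-0002-11A-11R\n"
        "gene_id\tnormalized_count\tnormalized_count\n"
        "MYC|4609\t120.5\t30.25\n"
        "?|10357\t5.0\t7.0\n"
        "TP53|7157\t88.0\t91.0\n"
    )
    return path
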