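import warnings

import pytest

import thyromir as tm


@pytest.fixture(scope="session")
def analysis_cohort():
    """Default synthetic analysis cohort (494 samples, panel mode)."""
    return tm.generate_cohort(tm.default_config(seed=7))


@pytest.fixture(scope="session")
def cohort_with_classes(analysis_cohort):
    """Analysis cohort with molecular class and binary label columns."""
    g = tm.molecular_grouping(analysis_cohort)
    return analysis_cohort.assign(
        molecular_class=g.reindex(analysis_cohort["sample_id"]).values,
        molecular_binary=tm.binary_labels(g).reindex(analysis_cohort["sample_id"]).values,
    )


@pytest.fixture(scope="session")
def raw_cohort():
    """Same cohort in raw-Cq mode (same seed, same level draws)."""
    return tm.generate_cohort(tm.default_config(seed=7, emit_raw_cq=True))


@pytest.fixture()
def benign_panel():
    """A panel on the all-benign path of the malignancy tree."""
    return {
        "sample_id": "S-benign",
        "level_hmga2": -8.0,     # linear 2^-8 << 0.0918
        "level_mir375": -15.0,   # < -12.1213
        "level_mir221": -9.0,    # linear << 0.0105
        "level_mir146b": -5.0,   # linear << 1.5362
        "mtdna_ratio": 300.0,
    }


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
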