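import dataclasses

import numpy as np
import pytest

import restcm as rc


@pytest.fixture(scope="session")
def model():
    return rc.HeadModel()


@pytest.fixture(scope="session")
def cap63():
    return rc.standard_cap63()


@pytest.fixture(scope="session")
def scalp61(cap63):
    return cap63.drop(["VEOG", "HEOG"])


@pytest.fixture(scope="session")
def cm59():
    return rc.cm_montage()


@pytest.fixture(scope="session")
def grid1994():
    return rc.build_dipole_grid()


@pytest.fixture(scope="session")
def lf61(model, scalp61, grid1994):
    """Infinity-referenced lead field on the 61-channel scalp montage."""
    return rc.leadfield_infinity(model, scalp61, grid1994)


@pytest.fixture(scope="session")
def sim_result(model, scalp61, grid1994, lf61):
    """Full 1994-dipole x 3-orientation reference comparison."""
    return rc.run_reference_comparison(model=model, montage=scalp61,
                                       grid=grid1994, lf=lf61)


@pytest.fixture(scope="session")
def default_cohort():
    return rc.generate_cohort()


@pytest.fixture(scope="session")
def oddball_results(default_cohort):
    """REST/AR/LM analysis of the default 12-subject cohort (the expensive
    end-to-end fixture; computed once per session)."""
    return rc.run_oddball_analysis(default_cohort,
                                   references=("REST", "AR", "LM"))


@pytest.fixture()
def tiny_cfg():
    """A small, fast cohort configuration for unit tests."""
    return dataclasses.replace(
        rc.SynthConfig(), n_subjects=2, n_sessions=1, trials_per_session=20,
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
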