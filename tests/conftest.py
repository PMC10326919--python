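import numpy as np
import pytest

import easi

TRAIN_SEED = 11
TRAIN_N = 128
PANEL_K = 20


@pytest.fixture(scope="session")
def spec():
    return easi.default_spec()


@pytest.fixture(scope="session")
def train_nominal(spec):
    return easi.nominalize(easi.simulate_replicates(spec, TRAIN_N, seed=TRAIN_SEED))


@pytest.fixture(scope="session")
def panel(train_nominal):
    return easi.select_top_k(train_nominal, PANEL_K)


@pytest.fixture(scope="session")
def train_matrix(train_nominal, panel):
    return easi.assemble_matrix(train_nominal, panel)


@pytest.fixture(scope="session")
def easi_model(train_matrix):
    return easi.fit_easi(train_matrix)


@pytest.fixture(scope="session")
def cov_model(train_matrix):
    return easi.fit_covariance(train_matrix)


def make_record(predicted, measured, spectrum_id="q", approach="easi", truth="unknown",
                channels=None):
    """Build a PredictionRecord from raw vectors for metric tests."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if channels is None:
        channels = tuple(range(100, 100 + len(predicted)))
    return easi.PredictionRecord(
        spectrum_id=spectrum_id,
        approach=approach,
        channels=tuple(channels),
        measured=measured,
        predicted=predicted,
        residuals=predicted - measured,
        truth=truth,
    )
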