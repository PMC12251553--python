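"""Shared fixtures: simulated campaigns and fitted soft sensors.

Session scope amortizes the expensive pieces (240-h simulations, network
training) across the suite; everything is seeded and deterministic.
"""

import warnings

import numpy as np
import pytest

from fermsense.model import ModelConfig, default_rate_laws
from fermsense.soft_sensor import SoftSensorRegressor
from fermsense.synthetic import NOISELESS, CampaignConfig, generate_campaign


@pytest.fixture(scope="session")
def noisefree_campaign():
    """Noise-free single-batch reference campaign (240 h, 60 offline pairs)."""
    cfg = CampaignConfig(noise=NOISELESS, jitter_frac=0.0, ramp_frac=0.05, seed=3, dt=0.05)
    return generate_campaign(cfg)[0], cfg


@pytest.fixture(scope="session")
def noisy_campaign():
    """Same campaign at the printed instrument noise levels."""
    cfg = CampaignConfig(jitter_frac=0.0, ramp_frac=0.05, seed=3, dt=0.05)
    return generate_campaign(cfg)[0], cfg


def _fit_on_chronological_train(batch, max_epochs=4000, random_state=0):
    ds = batch.dataset
    if ds.split is None:
        ds.assign_chronological_split(0.7)
    _, y_tr, _ = ds.rows("train")
    model = SoftSensorRegressor(max_epochs=max_epochs, random_state=random_state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant environment channels
        model.fit(ds.X.iloc[: len(y_tr)], y_tr)
    return model


@pytest.fixture(scope="session")
def trained_noisefree(noisefree_campaign):
    batch, _ = noisefree_campaign
    return _fit_on_chronological_train(batch)


@pytest.fixture(scope="session")
def trained_noisy(noisy_campaign):
    batch, _ = noisy_campaign
    return _fit_on_chronological_train(batch)


@pytest.fixture()
def default_rates():
    return default_rate_laws()


@pytest.fixture()
def default_config():
    return ModelConfig()


@pytest.fixture()
def mid_induction_point(noisefree_campaign):
    """State and feeds halfway through the induction phase."""
    batch, _ = noisefree_campaign
    i = len(batch.traj) // 2
    return batch.traj.states[i], batch.traj.feeds[i]
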