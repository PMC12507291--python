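"""Shared fixtures.

The two expensive computations - the full TRF derivation and the
synthetic trial battery - are session-scoped so that every test builds
on the same fit and the same simulated trials.
"""

import numpy as np
import pytest

from streakvision.normalization import NormalizationSpec
from streakvision.spatial import BankSpec, build_bank
from streakvision.stimulus import COARSE_SCALE
from streakvision.switch import run_battery
from streakvision.temporal import TemporalFilterModel

#: trial count per direction x streak cell of the session battery
BATTERY_PER_CELL = 4
BATTERY_STATIC = 6
BATTERY_SEED = 11


@pytest.fixture(scope="session")
def trf_result():
    """Full TRF derivation: 31 per-SF fits plus the spline surface."""
    return TemporalFilterModel().fit()


@pytest.fixture(scope="session")
def coarse_bank():
    return build_bank(BankSpec(), pitch=COARSE_SCALE.pitch)


@pytest.fixture(scope="session")
def battery(trf_result, coarse_bank):
    """Seeded synthetic battery at coarse scale.

    Returns (table, store): the switch-time table and per-trial
    artifacts (channel engagement, retinal trajectory angle,
    prediction-error series) for all five directions x streak
    present/absent.
    """
    kernels = trf_result.kernels_for(coarse_bank.sf_set, COARSE_SCALE.rate)
    store = {}
    table = run_battery(n_per_cell=BATTERY_PER_CELL, seed=BATTERY_SEED,
                        scale=COARSE_SCALE, bank=coarse_bank,
                        kernels=kernels, spec=NormalizationSpec(),
                        n_static=BATTERY_STATIC, store=store,
                        trial_kwargs=dict(pre_time=0.010, post_time=0.120))
    return table, store


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
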