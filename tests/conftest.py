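"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

from axontune import gp, synthetic as syn

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_protocol():
    """Compact protocol (5 SF x 5 TF x 4 dir, 4 repeats) for fast fits."""
    return syn.make_grating_protocol(directions=(0.0, 90.0, 180.0, 270.0),
                                     n_repeats=4, seed=11)


@pytest.fixture(scope="session")
def tuned_roi(small_protocol):
    """One well-tuned synthetic ROI with its fitted GP."""
    tuning = syn.GroundTruthTuning(
        sf_pref=np.log2(0.08), tf_pref=np.log2(2.0), sf_sigma=1.0,
        tf_sigma=1.0, dir_pref=90.0, dir_kappa=2.0, gain=1.0,
        baseline=0.1, noise_sd=0.1)
    recs, table = syn.simulate_tuned_responses(small_protocol, [tuning],
                                               seed=21)
    fit = gp.fit_gp(table, seed=0)
    return tuning, recs[0], table, fit


@pytest.fixture(scope="session")
def opto_roi():
    """One suppressed ROI under the laser-interleaved protocol."""
    protocol = syn.make_opto_protocol(n_repeats=6, seed=13)
    tuning = syn.GroundTruthTuning(
        sf_pref=np.log2(0.08), tf_pref=np.log2(2.0), dir_pref=90.0,
        dir_kappa=1.5, gain=1.0, baseline=0.1, noise_sd=0.1,
        laser_factor=0.4)
    recs, table = syn.simulate_tuned_responses(protocol, [tuning], seed=17)
    fit = gp.fit_gp(table, seed=0)
    return tuning, table, fit


@pytest.fixture(scope="session")
def toy_atlas():
    return syn.make_toy_atlas()
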