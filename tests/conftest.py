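import numpy as np
import pytest
from hypothesis import settings

from dirlfp.clinical import ContactClinicalScore, HemisphereDataset
from dirlfp.lead import default_lead
from dirlfp.spectral import NormalizedBeta

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

SEGMENT_IDS = (2, 3, 4, 5, 6, 7)


@pytest.fixture
def lead():
    return default_lead()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_hemisphere(
    hid="H1",
    beta=(0.6, 0.5, 0.4, 0.3, 0.2, 0.1),
    efficacy=(30, 25, 20, 15, 10, 5),
    tw=(1.5, 1.2, 1.0, 0.8, 0.6, 0.4),
    has_beta_peak=True,
    rigidity_baseline=3.0,
    stn_level="dorsal",
):
    """Hand-built hemisphere: vectors are in contact-id order 2..7."""
    beta_map = {
        cid: NormalizedBeta(cid, float(v), False, (15.0, 21.0))
        for cid, v in zip(SEGMENT_IDS, beta)
    }
    clin = {
        cid: ContactClinicalScore(cid, float(e), float(t))
        for cid, e, t in zip(SEGMENT_IDS, efficacy, tw)
    }
    return HemisphereDataset(
        hemisphere_id=hid, beta=beta_map, clinical=clin,
        has_beta_peak=has_beta_peak, rigidity_baseline=rigidity_baseline,
        stn_level=stn_level,
    )


@pytest.fixture
def make_hemi():
    return make_hemisphere
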