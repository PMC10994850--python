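import numpy as np
import pytest

import mobactag as m


@pytest.fixture(scope="session")
def oligos():
    return m.default_oligo_set()


@pytest.fixture(scope="session")
def oligo_map(oligos):
    return {o.label: o for o in oligos}


@pytest.fixture
def spike_design():
    return m.SpikeDesign(
        spike_16s_feature="spike_16S",
        spike_plant_feature="spike_pITS",
        secondary_spike_feature="spike2",
    )


def random_amplicon(rng, length=250):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def make_reference_set():
    """Factory for well-separated random reference sets."""

    def _make(feature_specs, seed=0, length=250):
        rng = np.random.default_rng(seed)
        features = [
            m.ReferenceFeature(fid, cls, random_amplicon(rng, length), source)
            for fid, cls, source in feature_specs
        ]
        return m.build_reference_set(features)

    return _make
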