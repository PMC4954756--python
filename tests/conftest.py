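import numpy as np
import pytest

import hcsquant as hq

NOISELESS = hq.NoiseParams(photon_scale=None, read_sd=0.0)


@pytest.fixture(scope="session")
def noiseless():
    return NOISELESS


@pytest.fixture(scope="session")
def eres_field_clean():
    """One noise-free 2-cell ERES field with full co-occurrence, shared by
    detection/measurement tests."""
    spec = hq.eres_scene(
        n_cells=2,
        seed=3,
        eres=hq.EresParams(
            n_puncta_per_cell=15, target_rho=1.0, coloc_fraction=1.0, peak_cv=0.0
        ),
        noise=NOISELESS,
    )
    images, truth = hq.generate_eres_field(spec)
    return spec, {im.channel: im for im in images}, truth


def channel_image(pixels, pixel_size_um=1.0, channel="atf6", **kw):
    return hq.ChannelImage(
        pixels=np.asarray(pixels, dtype=float),
        pixel_size_um=pixel_size_um,
        channel=channel,
        **kw,
    )
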