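import numpy as np
import pytest

from spinalgaba import synthetic as syn


@pytest.fixture(scope="session")
def puncta_field():
    """Standard fixture: 50 well-separated high-SNR puncta on a 512x512 frame."""
    rng = np.random.default_rng(0)
    pos = []
    while len(pos) < 50:
        y, x = rng.uniform(25, 487, 2)
        if all((y - p[0]) ** 2 + (x - p[1]) ** 2 > 25**2 for p in pos):
            pos.append((y, x))
    amps = tuple(rng.uniform(500, 900, 50))
    truth = syn.ImageTruth(
        positions=tuple(pos), amplitudes=amps, sizes=(3.5,) * 50, seed=3
    )
    image, truth = syn.gen_puncta_image(truth)
    return image, truth


@pytest.fixture(scope="session")
def calibrated_anion():
    """Anion-model constants calibrated against the printed anchor triple."""
    from spinalgaba import chloride as chl

    params, report = chl.calibrate_anion_constants(chl.AnionAnchors())
    return params, report


@pytest.fixture(scope="session")
def effect_params():
    from spinalgaba import chloride as chl

    return chl.calibrate_effect([(26.0, 25.0), (67.0, 42.0)])
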