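import numpy as np
import pytest

from ecgwaves import (
    RenderConfig,
    render_ecg,
    sample_config,
    synthesize_ecg,
)


@pytest.fixture(scope="session")
def sr_signal():
    """A clean sinus-rhythm record with regular R-R (jitter 0)."""
    cfg = sample_config(
        1,
        {
            "rhythm": "SR",
            "phenotype": "NORMAL",
            "mean_heart_rate": 60.0,
            "rr_jitter": 0.0,
        },
    )
    return synthesize_ecg(cfg)


@pytest.fixture(scope="session")
def af_signal():
    cfg = sample_config(2, {"rhythm": "AF", "phenotype": "NORMAL"})
    return synthesize_ecg(cfg)


@pytest.fixture(scope="session")
def rendered(sr_signal):
    """One clean render at 8 px/mm: (signal, image, mask, layout)."""
    image, mask, layout = render_ecg(sr_signal, RenderConfig(px_per_mm=8))
    return sr_signal, image, mask, layout


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
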