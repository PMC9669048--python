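import numpy as np
import pytest

from ecgpeaks.augment import NoiseTemplates
from ecgpeaks.synth import SynthConfig, gen_ecg, gen_noise_templates


@pytest.fixture(scope="session")
def clean_record():
    """60 s of regular, non-inverted synthetic ECG with exact R truth."""
    cfg = SynthConfig(duration_s=60.0, seed=7, inverted_prob=0.0, ectopic_prob=0.0)
    return gen_ecg(cfg)


@pytest.fixture(scope="session")
def templates():
    n = 30 * 360
    return NoiseTemplates(
        baseline_wander=gen_noise_templates("baseline_wander", n, 360.0, 11),
        muscle=gen_noise_templates("muscle", n, 360.0, 12),
        electrode_motion=gen_noise_templates("electrode_motion", n, 360.0, 13),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
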