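import numpy as np
import pytest

import dcemcs


@pytest.fixture()
def default_cfg():
    return dcemcs.default_config()


@pytest.fixture()
def noiseless_cfg():
    cfg = dcemcs.default_config()
    cfg["phantom"]["noise_frac"] = 0.0
    return cfg


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Seed-7 noiseless four-lesion cohort on the default 32x32x10 grid."""
    cfg = dcemcs.default_config()
    cfg["phantom"]["noise_frac"] = 0.0
    return dcemcs.generate_cohort(2, 2, cfg, seed=7)


@pytest.fixture()
def times_10():
    """Scan times for 1 pre + 9 post frames at 60 s spacing."""
    return np.arange(10, dtype=float) * 60.0
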