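import numpy as np
import pytest

from issiol import EyeBiometry


@pytest.fixture
def rng():
    return np.random.default_rng(20220120)


def random_valid_eyes(n, rng, with_radii=False):
    """Randomized but optically valid post-LASIK biometry."""
    L = rng.uniform(22.5, 31.0, n)
    kpost = rng.uniform(34.0, 43.0, n)
    eyes = []
    for i in range(n):
        r_ant = 337.5 / kpost[i] + rng.normal(0, 0.05) if with_radii else None
        r_post = rng.uniform(5.8, 7.2) if with_radii else None
        eyes.append(
            EyeBiometry(
                axial_length_mm=float(L[i]),
                kpost_d=float(kpost[i]),
                r_anterior_mm=r_ant,
                r_posterior_mm=r_post,
            )
        )
    return eyes
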