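from dataclasses import dataclass

import numpy as np
import pytest

from decomb.centres import CentreFinderConfig, find_centres
from decomb.synthetic import CombMask, CombSpec, apply_comb, generate_comb, make_target


@pytest.fixture(scope="session")
def small_comb():
    """~80-fibrelet comb on a 120 px frame, default geometry."""
    return generate_comb(CombSpec(image_side=120, n_fibrelets=80, seed=3))


@dataclass
class RecoveryFixture:
    """Planted comb viewed as a cropped interior capture.

    Real calibration frames are crops of the bundle interior, with no dark
    rim; the crop removes the generator's empty border so no spurious
    rim candidates exist, and the planted truth keeps only centres whose
    detection neighbourhood lies inside the crop.  Geometry (gap 3 px,
    position jitter 0.06) keeps adjacent true centres farther apart than
    the exclusion diameter plus twice the localisation error, the
    precondition for full recovery.
    """

    comb: CombMask
    crop: tuple[slice, slice]
    truth: np.ndarray  # (n, 2) in cropped coordinates

    def capture(self, noise_sigma: float = 0.0, seed: int = 0) -> np.ndarray:
        target = make_target(
            "uniform", {"value": 255.0}, blur_sigma=0.0, shape=self.comb.shape
        )
        full = apply_comb(target, self.comb, noise_sigma=noise_sigma, seed=seed)
        return full[self.crop]


def make_recovery_fixture(seed: int = 1, side: int = 180, crop_margin: int = 14):
    spec = CombSpec(
        image_side=side,
        mean_diameter=8.0,
        cladding_gap=3.0,
        position_jitter=0.06,
        diameter_jitter=0.05,
        seed=seed,
    )
    comb = generate_comb(spec)
    c = crop_margin
    border = 5  # detection neighbourhood half-size + localisation slack
    sel = np.all(
        (comb.true_centres >= c + border) & (comb.true_centres <= side - c - border),
        axis=1,
    )
    crop = (slice(c, side - c), slice(c, side - c))
    return RecoveryFixture(comb=comb, crop=crop, truth=comb.true_centres[sel] - c)


@pytest.fixture(scope="session")
def recovery_fixture():
    """~200 planted 8 px fibrelets, cropped interior view."""
    return make_recovery_fixture(seed=1)


@pytest.fixture(scope="session")
def recovery_calibration(recovery_fixture):
    """Noise-free bright-field frame of the recovery comb (cropped)."""
    return recovery_fixture.capture()


@pytest.fixture(scope="session")
def small_centre_map(small_comb):
    cal = apply_comb(
        make_target("uniform", {"value": 255.0}, blur_sigma=0.0, shape=small_comb.shape),
        small_comb,
        noise_sigma=0.0,
    )
    return find_centres(cal, CentreFinderConfig(D=9, I_min=20.0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
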