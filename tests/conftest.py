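import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ghostcore as g

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom (true NWU 7.2%)."""
    return g.generate_phantom(g.PhantomSpec())


@pytest.fixture(scope="session")
def noisy_phantom():
    return g.generate_phantom(g.PhantomSpec(noise_sd_hu=1.5, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Default-size simulated cohort (n=284, all effects active)."""
    return g.simulate_cohort(g.EffectConfig(seed=3))


def single_effect_config(n, seed, **overrides):
    """EffectConfig with only the overridden risk effects active and no
    missing data, for clean parameter-recovery experiments."""
    base = dict(
        n_subjects=n, seed=seed,
        rr_nwu_per_pct=1.0, rr_pcore_per_ml=1.0, rr_aspects_per_point=1.0,
        missing_mrs90_prob=0.0, missing_nihss_prob=0.0, missing_etici_prob=0.0,
    )
    base.update(overrides)
    return g.EffectConfig(**base)


@pytest.fixture
def uniform_ct():
    """Tiny CT with a lesion ROI at one density and mirror tissue at another."""
    def make(d_ischemic, d_normal, shape=(11, 8, 6)):
        vox = np.full(shape, d_normal, dtype=float)
        mask = np.zeros(shape, dtype=bool)
        mask[8:10, 3:5, 2:4] = True
        vox[mask] = d_ischemic
        ct = g.CTVolume(vox, (1.0, 1.0, 1.0), midsagittal_axis=0)
        return ct, g.ROISet.from_lesion(mask, axis=0)
    return make
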