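import numpy as np
import pytest

from hospprod import CobbDouglasParams, GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def calibrated_dataset():
    """Synthetic 94-hospital cross-section with the calibrated profile."""
    return generate_dataset(GeneratorConfig(seed=0))


@pytest.fixture()
def two_input_cd_config():
    """Small two-input Cobb-Douglas data-generating process (known truth)."""
    def make(seed=0, noise=0.15, outlier_fraction=0.0, outlier_scale=10.0, n=94):
        true = CobbDouglasParams(log_alpha0=0.5,
                                 alphas={"electricity": 0.5, "nurses": 0.3})
        return GeneratorConfig(
            n_hospitals=n, seed=seed, true_params=true, noise_log_sd=noise,
            outlier_fraction=outlier_fraction, outlier_scale=outlier_scale,
        )
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
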