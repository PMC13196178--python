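import numpy as np
import pytest

import predsize as ps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_spec():
    """Five independent standard-normal predictors."""
    return ps.CaseMixSpec.standard_normal(5)


@pytest.fixture(scope="session")
def small_sample(small_spec):
    return ps.generate_casemix(small_spec, 20_000, np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_reference(small_spec, small_sample):
    """Reference model calibrated to C=0.72, prevalence 0.3 on the sample."""
    skeleton = ps.ReferenceModel(alpha=0.0, delta=1.0, beta=np.ones(5))
    return ps.calibrate_reference(
        skeleton, small_sample, 0.72, 0.30, rng=np.random.default_rng(12)
    )


@pytest.fixture(scope="session")
def small_dev(small_spec, small_reference):
    return ps.draw_development(
        small_spec, small_reference, 400, np.random.default_rng(13)
    )


@pytest.fixture(scope="session")
def small_population(small_spec, small_reference):
    return ps.make_population(
        small_spec, small_reference, 20_000, np.random.default_rng(14)
    )
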