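import pytest

import thyrodca as tdc


@pytest.fixture(scope="session")
def paper_cohort():
    """The deterministic 325-nodule cohort matching the published counts."""
    return tdc.exact_paper_cohort()


@pytest.fixture(scope="session")
def big_cohort():
    """A large synthetic cohort for Monte-Carlo recovery checks
    (published operating profiles, sizes 1.54 +/- 0.16 cm)."""
    config = tdc.SynthConfig(
        n_nodules=100_000,
        n_patients=77_000,
        size_mean_cm=1.54,
        size_sd_cm=0.16,
        seed=20260919,
    )
    return config, tdc.generate_cohort(config)
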