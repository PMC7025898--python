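import pytest

from pancankit.simulate import CallerProfile, TumourConfig, simulate_tumour


@pytest.fixture(scope="session")
def event_truth():
    """One tumour with all three clustered processes injected."""
    cfg = TumourConfig(seed=11, n_kataegis=3, n_chromothripsis=2,
                       n_chromoplexy=2)
    return simulate_tumour(cfg)


@pytest.fixture(scope="session")
def quiet_truth():
    """A tumour with background mutations only (no clustered events)."""
    cfg = TumourConfig(seed=23)
    return simulate_tumour(cfg)


@pytest.fixture
def three_callers():
    return [CallerProfile(name=n, sensitivity=0.85, fp_per_mb=0.1)
            for n in ("sanger", "dkfz", "broad")]
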