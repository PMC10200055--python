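import pytest

from sefkit import FixtureSpec, generate_fixtures


@pytest.fixture(scope="session")
def small_fixtures():
    """30 deterministic synthetic molecules with composition truth."""
    return generate_fixtures(FixtureSpec(n_molecules=30, seed=11))


@pytest.fixture(scope="session")
def regression_fixtures():
    """200 molecules, target = 2*S_m + N(0, 0.01) — the RF benchmark set."""
    return generate_fixtures(
        FixtureSpec(n_molecules=200, seed=0, noise_sigma=0.01, slope=2.0)
    )
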