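import pytest

from amescade import FixtureSpec, default_rulebase, generate, stratified_split, train_cascade


@pytest.fixture(scope="session")
def rulebase():
    return default_rulebase()


@pytest.fixture(scope="session")
def synthetic_set():
    """A mid-size labelled synthetic set shared across tests."""
    return generate(FixtureSpec(n=400, seed=11))


@pytest.fixture(scope="session")
def trained(synthetic_set, rulebase):
    """A cascade trained on the synthetic training split."""
    train_recs, test_recs = stratified_split(synthetic_set, 0.2, seed=11, rulebase=rulebase)
    return train_cascade(train_recs, rulebase, seed=11), train_recs, test_recs
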