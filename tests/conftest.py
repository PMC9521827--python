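import pytest

from biggdraft import fixtures


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic fixture bundle shared across tests."""
    return fixtures.generate(fixtures.FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """The same bundle written to disk (templates/, query.faa, annotations/,
    reference.xml, ground_truth.json)."""
    out = tmp_path_factory.mktemp("fixture")
    bundle = fixtures.generate(fixtures.FixtureSpec(seed=11), out_dir=out)
    return out, bundle
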