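import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1():
    """The packaged herb compound table (15 entries)."""
    from phytonet import load_plantaginis_ingredients

    return load_plantaginis_ingredients()


@pytest.fixture(scope="session")
def literature5():
    """The five literature-reported compounds."""
    from phytonet import load_plantaginis_literature

    return load_plantaginis_literature()


@pytest.fixture(scope="session")
def synth17(tmp_path_factory):
    """A default synthetic dataset written to disk (seed 17)."""
    from phytonet import generate_dataset

    outdir = tmp_path_factory.mktemp("synth17")
    return generate_dataset(seed=17, outdir=outdir)
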