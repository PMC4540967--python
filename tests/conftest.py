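import pytest

from mitosoup.simulate import make_assembly_variants, make_community


@pytest.fixture(scope="session")
def small_community():
    """Six related species, two haplotypes each — shared by many tests."""
    return make_community(6, haplotypes_per_species=2, seed=11)


@pytest.fixture(scope="session")
def small_variants(small_community):
    return make_assembly_variants(small_community, seed=13)
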