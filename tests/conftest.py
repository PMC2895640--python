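import pytest

from dsbrec import AlleleMap, Karyotype


@pytest.fixture(scope="session")
def haploid_karyotype():
    return Karyotype.yeast()


@pytest.fixture(scope="session")
def g2_tetraploid():
    """G2/M-arrested tetraploid: 8 haploid genome equivalents."""
    return Karyotype.yeast(ploidy=4, replicated=True)


@pytest.fixture(scope="session")
def allele_map():
    return AlleleMap.default()
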