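import pytest

import odirasim as od


@pytest.fixture(scope="session")
def fixture():
    """Curated amplicon-locus ancestor with planted features."""
    return od.make_sul1_like_fixture()


@pytest.fixture(scope="session")
def dogbone(fixture):
    return od.extrude_dog_bone(fixture.chrom, *fixture.iirs, fixture.origins)


@pytest.fixture(scope="session")
def plasmid(dogbone):
    return od.replicate_dog_bone(dogbone)


@pytest.fixture(scope="session")
def triplication(fixture, plasmid):
    return od.integrate_plasmid(fixture.chrom, plasmid)


@pytest.fixture(scope="session")
def designed_fork():
    lead, lag = od.design_fork_oligos(seed=1)
    return od.assemble_fork(lead, lag)
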