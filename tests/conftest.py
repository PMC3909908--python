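import numpy as np
import pytest

from ctlp.genome import MB, GenomeAssembly


@pytest.fixture(scope="session")
def toy_assembly():
    """One 100 Mb chromosome with a centromere at [45,55] Mb."""
    return GenomeAssembly(
        name="toy1",
        chromosomes=(("A", 100 * MB),),
        centromeres={"A": (45 * MB, 55 * MB)},
    )


@pytest.fixture(scope="session")
def toy_multi_assembly():
    """Six 130 Mb chromosomes; used for probe-level simulation studies."""
    chroms = tuple((f"c{i}", 130 * MB) for i in range(1, 7))
    cens = {f"c{i}": (60 * MB, 65 * MB) for i in range(1, 7)}
    return GenomeAssembly(name="toy6", chromosomes=chroms, centromeres=cens)


@pytest.fixture(scope="session")
def hg18():
    return GenomeAssembly.hg18()


@pytest.fixture
def rng():
    return np.random.default_rng(20240129)
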