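import numpy as np
import pytest

from mitodip.refgenome import ReferenceGenome, build_nuclear_only
from mitodip.simulate import (
    SimulationConfig,
    simulate_medip_reads,
    simulate_methylomes,
    simulate_reference,
)
from mitodip.tables import load_fixture_tables, load_mito_annotation


@pytest.fixture(scope="session")
def fixture_tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def mito_annotation():
    return load_mito_annotation()


@pytest.fixture()
def toy_reference():
    """Tiny two-record reference with a duplicated 60 bp block shared between
    chrM (at position 101) and chr1 (at position 201) to exercise tie logic."""
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    mito = "".join(rng.choice(bases, 400))
    chr1 = "".join(rng.choice(bases, 600))
    shared = "".join(rng.choice(bases, 60))
    mito = mito[:100] + shared + mito[160:]
    chr1 = chr1[:200] + shared + chr1[260:]
    return ReferenceGenome(records={"chr1": chr1, "chrM": mito}, mito_name="chrM")


@pytest.fixture(scope="session")
def default_simulation():
    """The default study-condition simulation, one sample, 10,000 read pairs."""
    cfg = SimulationConfig()
    rng = np.random.default_rng(1)
    full, nuclear, truth = simulate_reference(cfg, rng)
    meth = simulate_methylomes(cfg, rng)
    pairs, origins = simulate_medip_reads(
        full, meth[("ind1", "BA8")], cfg, rng, truth=truth, sample_key="s1"
    )
    return cfg, full, nuclear, truth, meth, pairs, origins
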