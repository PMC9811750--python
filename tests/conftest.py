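import numpy as np
import pytest

from scimeth import methalign, simdata


@pytest.fixture(scope="session")
def small_genome():
    return simdata.simulate_genome(1, 50_000, 0.42, seed=11)


@pytest.fixture(scope="session")
def small_methylomes(small_genome):
    methylomes, dmr_table = simdata.simulate_methylomes(
        small_genome, 2, 6, 1000, cph_rate=0.01, baseline_cpg=0.8, seed=3
    )
    return methylomes, dmr_table


@pytest.fixture(scope="session")
def small_index(small_genome):
    return methalign.build_index(small_genome.contigs, seed_k=12)


@pytest.fixture(scope="session")
def clean_chemistry():
    """Perfect conversion, no errors: reads are deterministic genome images."""
    return simdata.ChemistryModel(conversion_rate=1.0, overconversion_rate=0.0)


@pytest.fixture(scope="session")
def small_run(small_genome, small_methylomes, clean_chemistry):
    """A small emitted run with clean chemistry and no contamination."""
    methylomes, _ = small_methylomes
    cells = [("c0", "type0", 150), ("c1", "type1", 150)]
    design = simdata.design_barcodes([c[0] for c in cells], seed=5)
    run = simdata.emit_run(
        cells, small_genome, methylomes, design, clean_chemistry,
        read_length=100, seed=17,
    )
    return run
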