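import numpy as np
import pytest

from cystra.simulate import (
    ClusterSpec,
    ReadSimSpec,
    make_cluster_panel,
    make_reference_loci,
    make_trna_template,
    simulate_reads,
)


@pytest.fixture(scope="session")
def template():
    """Default tRNA template sequence and its cloverleaf pairing map."""
    return make_trna_template(7)


@pytest.fixture(scope="session")
def default_panel():
    """The default five-accession synthetic cluster panel (seed 1)."""
    return make_cluster_panel(ClusterSpec(seed=1))


@pytest.fixture(scope="session")
def decomposed_panel(default_panel):
    """Regions and gene-anchored units for every panel accession."""
    from cystra.repeats import decompose_cluster

    units = {}
    for acc, pa in sorted(default_panel.items()):
        genes = [a for a in pa.annotations if a.category == "gene"]
        units[acc] = decompose_cluster(pa.record, genes)
    regions = {acc: pa.record for acc, pa in default_panel.items()}
    return regions, units


@pytest.fixture(scope="session")
def loci_panel():
    """16-locus / 13-variant reference panel (seed 1)."""
    return make_reference_loci(seed=1)


@pytest.fixture(scope="session")
def clean_read_sim(loci_panel):
    """Error-free, contaminant-free simulated libraries at depth 20k."""
    spec = ReadSimSpec(error_rate=0.0, contaminant_fraction=0.0, depth=20000, seed=1)
    return simulate_reads(loci_panel, spec)
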