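import pytest

from orgpopgen.simulate import SimulationConfig, build_reference, simulate_population


@pytest.fixture(scope="session")
def plastome():
    return build_reference("plastome", seed=7)


@pytest.fixture(scope="session")
def plastome_truth(plastome):
    cfg = SimulationConfig.calibrated(plastome, seed=7)
    return cfg, simulate_population(plastome, cfg)


@pytest.fixture(scope="session")
def mito_regions():
    return build_reference("mitogenome", seed=7)


def variant_key(v):
    """Identity of a variant for exact truth-vs-called comparisons."""
    return (
        v.vtype,
        v.columns,
        v.ref_position,
        v.ref_allele,
        v.alt_alleles,
        tuple(sorted(v.alleles.items())),
        v.alt_count,
        v.ref_gapped,
    )
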