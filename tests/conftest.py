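import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from corrsoil import (
    ExtractionGeometry,
    GenomeAnnotation,
    gen_community,
    gen_extraction_series,
)


@pytest.fixture(scope="session")
def geometry():
    """Default extraction geometry: 10 ml buffer over 1 g (1 ml) of soil."""
    return ExtractionGeometry(vol_aq=0.01, vol_soil=0.001, soil_mass=1.0)


@pytest.fixture(scope="session")
def rule_case_genomes():
    """One genome per cell of the role rule table."""
    return {
        "producer": GenomeAnnotation("gp", frozenset({"K06042", "K00548"})),
        "producer_non_user": GenomeAnnotation("gpn", frozenset({"K03394"})),
        "dependent": GenomeAnnotation("gd", frozenset({"PF08471"})),
        "independent": GenomeAnnotation("gi", frozenset()),
    }


@pytest.fixture(scope="session")
def noiseless_series(geometry):
    """Forward-simulated extraction at K_d = 0.04 from a 34 pmol/g pool."""
    return gen_extraction_series(
        true_kd=0.04, initial_pool_pmol_per_g=34.0, geometry=geometry,
        n_rounds=12, noise_sd=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_microcosm():
    """Small microcosm-design table with one strong responder zOTU."""
    return gen_community(
        "microcosm",
        n_taxa=60,
        responders={"zotu1": {"[Ade]Cba": 8.0}},
        depth=5000,
        timepoints=(0, 3),
        seed=11,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
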