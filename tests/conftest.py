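import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Suite-wide base seed for every stochastic fixture.
SEED = 2026


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


def random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def small_lineage():
    """A small evolved lineage shared by clustering tests: 2 families x 2
    genera x 3 species x 2 variants, 5-8 kb genomes."""
    from votuforge.synthetic_data import LineageSpec, evolve_lineages

    spec = LineageSpec(n_families=2, genera_per_family=2, species_per_genus=3,
                       variants_per_species=2, genome_len_range=(5000, 8000))
    genomes, truth = evolve_lineages(spec, seed=SEED)
    return spec, genomes, truth
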