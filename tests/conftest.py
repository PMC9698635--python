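import numpy as np
import pytest

from specmir.core_io import MiRNALocus, ReadProfile
from specmir.synthetic import SimConfig, simulate_dataset, simulate_hairpin


def make_locus(locus_id: str, species: str, mature: str, *, seed: int = 0,
               reads: ReadProfile | None = None, **kw) -> MiRNALocus:
    """A structurally valid locus around a given mature sequence."""
    rng = np.random.default_rng(seed)
    hairpin, star = simulate_hairpin(mature, rng, target_len=120)
    return MiRNALocus(locus_id=locus_id, species=species, mature_seq=mature,
                      star_seq=star, hairpin_seq=hairpin,
                      read_profile=reads or ReadProfile(100, 70, 12, 3), **kw)


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 species, 5 conserved + 2 specific families per species, noise-free."""
    cfg = SimConfig(n_species=3, n_conserved_families=5,
                    n_specific_per_species=2, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 5 species, 30 conserved families,
    10 species-specific loci per species, noise-free, seed 1."""
    return simulate_dataset(SimConfig(seed=1))
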