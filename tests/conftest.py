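import numpy as np
import pytest

from tricontact import fragmap
from tricontact.quant4c import FragmentProfile, ViewpointSpec
from tricontact.simulate import (
    SimulationConfig,
    build_contact_model,
    default_primer_tag,
    simulate_genome,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(
        chrom_length=200_000, viewpoint_pos=100_000, n_reads=2_000, seed=1234
    )


@pytest.fixture(scope="session")
def sim_world(sim_config):
    """Genome + digest + contact model shared across tests (read-only)."""
    genome = simulate_genome(sim_config)
    fmap = fragmap.digest(genome)
    model = build_contact_model(fmap, sim_config)
    return genome, fmap, model


@pytest.fixture(scope="session")
def viewpoint(sim_world, sim_config):
    genome, fmap, _ = sim_world
    frag = fmap.fragment_at(sim_config.chrom_name, sim_config.viewpoint_pos)
    return ViewpointSpec(
        name="vp",
        chrom=sim_config.chrom_name,
        bait_start=frag.start,
        bait_end=frag.end,
        primer_tag=default_primer_tag(genome, fmap, sim_config),
    )


def make_profile(fmap, vp, scores, stage="normalized", mask=None, window=0):
    scores = np.asarray(scores, dtype=float)
    if mask is None:
        mask = np.zeros(len(scores), dtype=bool)
    return FragmentProfile(
        viewpoint=vp,
        fragment_map=fmap,
        scores=scores,
        stage=stage,
        excluded_mask=mask,
        window=window,
    )


@pytest.fixture
def profile_factory(sim_world, viewpoint):
    _, fmap, _ = sim_world

    def factory(scores, stage="normalized", mask=None):
        return make_profile(fmap, viewpoint, scores, stage=stage, mask=mask)

    return factory
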