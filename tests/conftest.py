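import pytest

from mirspan.energetics import EnergyParams, load_default_params
from mirspan.seedscan import SeedType
from mirspan.seqmodel import RegionKind
from mirspan.synthetic import SynthSpec, generate_corpus


@pytest.fixture(scope="session")
def toy_params():
    """Uniform stacks (-3), linear loops (+4/nt), no initiation terms."""
    return EnergyParams.uniform(stack=-3.0, loop_per_nt=4.0)


@pytest.fixture(scope="session")
def default_params():
    return load_default_params()


@pytest.fixture(scope="session")
def demo_corpus():
    """Small deterministic corpus with planted sites, shared across
    scoring and CLI tests."""
    spec = SynthSpec(
        n_mirnas=3,
        n_genes=6,
        region_lengths={r: 150 for r in RegionKind},
        planted_sites=[
            (SeedType.T2t8A1, RegionKind.UTR3, 1),
            (SeedType.T2t8, RegionKind.CDS, 1),
        ],
        rng_seed=42,
    )
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def demo_scores(demo_corpus, default_params):
    """PairScores of every demo pair under the bundled weight table."""
    from mirspan.background import load_bundled_weights
    from mirspan.scoring import predict_pair

    weights = load_bundled_weights()
    by_id = {m.id: m for m in demo_corpus.mirnas}
    return [
        predict_pair(by_id[mid], demo_corpus.genes[gid], weights, default_params)
        for mid, gid in demo_corpus.pairs
    ]
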