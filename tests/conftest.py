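"""Shared fixtures: synthetic recognition codes, small selections, and a
session-scoped memorization pair model (trained once, reused by the design
and acceptance tests)."""

from __future__ import annotations

import numpy as np
import pytest

from zfhelix.model import (
    ModelConfig,
    PairModel,
    TrainedModel,
    encode_bases,
    encode_residues,
)
from zfhelix.nn import Adam
from zfhelix.synthetic import (
    SimulationParams,
    make_library_contexts,
    sample_code,
    simulate_single_selection,
)
from zfhelix.training import _draw_masks, _masked_loss_and_hits

#: (7-mer target, helix pair) associations memorised by the toy pair model.
MEMO_ASSOCIATIONS = [
    ("ACGTACG", "RDHTNKQSGELV"),
    ("TTTTTTT", "WYYAMCFIPQRD"),
    ("GGGGCCC", "KKEDSTVHNLGA"),
    ("CATGCAT", "MNPQRSTVWYAC"),
]


@pytest.fixture(scope="session")
def additive_code():
    """Context-free code: pair energies decompose exactly over fingers."""
    return sample_code(seed=1, context_strength=0.0)


@pytest.fixture(scope="session")
def coupled_code():
    """Code with a strong neighbour-context coupling."""
    return sample_code(seed=1, context_strength=2.0)


@pytest.fixture(scope="session")
def library_context(additive_code):
    return make_library_contexts(additive_code, 1)[0]


@pytest.fixture(scope="session")
def small_selection(coupled_code):
    """One simulated single-finger selection with a few hundred records."""
    context = make_library_contexts(coupled_code, 1)[0]
    params = SimulationParams(seed=11, n_candidates=50_000_000, max_survivors=300)
    return simulate_single_selection(
        coupled_code, context, context.overlap_base + "GCT", params
    )


@pytest.fixture(scope="session")
def memo_pair_model() -> TrainedModel:
    """A toy pair model trained to memorise four (target, pair)
    associations; masked predictions on these pairs are near-deterministic."""
    rng = np.random.default_rng(3)
    config = ModelConfig.toy()
    network = PairModel(config, rng)
    bases = np.repeat(
        np.stack([encode_bases(t) for t, _ in MEMO_ASSOCIATIONS]), 32, axis=0
    )
    seqs = np.repeat(
        np.stack([encode_residues(s) for _, s in MEMO_ASSOCIATIONS]), 32, axis=0
    )
    optimizer = Adam(
        [p for p in network.parameters() if p.requires_grad], lr=3e-3
    )
    for _ in range(300):
        mask = _draw_masks(seqs, 0.5, rng)
        loss, _, _ = _masked_loss_and_hits(network, bases, seqs, mask)
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
    return TrainedModel(network=network, config=config, metadata={"task": "memo"})


@pytest.fixture(scope="session")
def memo_profile(memo_pair_model):
    """Specificity profile of the first memorised pair (16384 7-mers)."""
    from zfhelix.design import specificity_profile

    return specificity_profile(
        memo_pair_model, MEMO_ASSOCIATIONS[0][1], chunk=4096
    )
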