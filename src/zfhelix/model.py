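"""The hierarchical masked-residue attention model.

Two *single-helix modules* -- each a small encoder-decoder transformer --
learn which residues bind a nucleotide 4-mer in a given neighbour
environment.  For a 7-mer two-finger target, module 1 reads the last four
bases (finger1's sub-target) and module 2 the first four bases (finger2's
sub-target, sharing base 4).  Their per-residue embeddings are concatenated
and refined by a *pair-compatibility module* of repeated self-attention and
feedforward layers, which learns how the two helices constrain each other
across the overlap.  The whole stack is trained with a masked
language-model objective: predict masked core residues from the target and
the unmasked residues.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from zfhelix.nn import Dropout, Embedding, Linear, Module, Tensor, TransformerBlock, no_grad
from zfhelix.types import AA_INDEX, AMINO_ACIDS, BASE_INDEX, DnaTarget, InputError

#: Input-vocabulary index of the mask token (after the 20 residues).
MASK_TOKEN: int = 20


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the full-scale settings: embedding dimension 128, four
    heads per attention layer, every attention block repeated three times,
    key/value dimensions 256, feedforward hidden size 128, dropout 0.3.
    ``toy()`` returns a configuration small enough to train in seconds on
    one CPU, used throughout the tests and worked examples.
    """

    d_model: int = 128
    n_heads: int = 4
    n_layer_repeats: int = 3
    d_k: int = 256
    d_v: int = 256
    d_ff: int = 128
    dropout: float = 0.3
    n_residues: int = 20
    n_bases: int = 4

    def __post_init__(self) -> None:
        for name in ("d_model", "n_heads", "n_layer_repeats", "d_k", "d_v", "d_ff"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise InputError("dropout must be in [0, 1)")

    @classmethod
    def toy(cls, dropout: float = 0.0) -> "ModelConfig":
        return cls(
            d_model=32, n_heads=2, n_layer_repeats=1, d_k=16, d_v=16, d_ff=64,
            dropout=dropout,
        )


def encode_bases(target: str | DnaTarget) -> np.ndarray:
    return np.array([BASE_INDEX[b] for b in str(target)], dtype=np.int64)


def encode_residues(seq: str, mask_char: str = "_") -> np.ndarray:
    """Token indices of a residue string; ``mask_char`` becomes the mask token."""
    out = []
    for c in seq:
        if c == mask_char:
            out.append(MASK_TOKEN)
        elif c in AA_INDEX:
            out.append(AA_INDEX[c])
        else:
            raise InputError(f"unknown residue symbol {c!r}")
    return np.array(out, dtype=np.int64)


def decode_residues(tokens: np.ndarray) -> str:
    return "".join(
        "_" if t == MASK_TOKEN else AMINO_ACIDS[t] for t in np.asarray(tokens).ravel()
    )


class SingleHelixModule(Module):
    """Encoder-decoder module mapping a 4-mer target to residue predictions.

    The encoder builds a representation of each base with repeated
    self-attention; the decoder runs repeated self-attention over the six
    (partially masked) residue tokens, cross-attention onto the base
    representations, and a feedforward layer, all bidirectional.
    """

    N_BASES_IN = 4
    N_RESIDUES = 6

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        d = config.d_model
        self.base_emb = Embedding(config.n_bases, d, rng)
        self.base_pos = Embedding(self.N_BASES_IN, d, rng)
        self.res_emb = Embedding(config.n_residues + 1, d, rng)  # +1 mask token
        self.res_pos = Embedding(self.N_RESIDUES, d, rng)
        self.drop = Dropout(config.dropout, rng)
        args = (config.d_model, config.n_heads, config.d_k, config.d_v,
                config.d_ff, config.dropout, rng)
        self.encoder = [TransformerBlock(*args) for _ in range(config.n_layer_repeats)]
        self.decoder = [
            TransformerBlock(*args, cross=True) for _ in range(config.n_layer_repeats)
        ]
        # zero-initialised head: an untrained model predicts the uniform
        # distribution over residues
        self.head = Linear(d, config.n_residues, rng)
        self.head.weight.data[:] = 0.0

    def encode(self, bases: np.ndarray) -> Tensor:
        bases = np.atleast_2d(bases)
        pos = np.broadcast_to(np.arange(bases.shape[1]), bases.shape)
        x = self.drop(self.base_emb(bases) + self.base_pos(pos))
        for block in self.encoder:
            x = block(x)
        return x

    def hidden(self, bases: np.ndarray, residues: np.ndarray) -> Tensor:
        """Residue embeddings ``(B, 6, d_model)`` for a batch of targets and
        partially masked residue token rows."""
        residues = np.atleast_2d(residues)
        memory = self.encode(bases)
        pos = np.broadcast_to(np.arange(residues.shape[1]), residues.shape)
        x = self.drop(self.res_emb(residues) + self.res_pos(pos))
        for block in self.decoder:
            x = block(x, memory=memory)
        return x

    def logits(self, bases: np.ndarray, residues: np.ndarray) -> Tensor:
        return self.head(self.hidden(bases, residues))


class PairModel(Module):
    """The full hierarchical model for 7-mer two-finger targets.

    ``module1`` reads bases 4-7 and finger1 residue tokens, ``module2``
    bases 1-4 and finger2 tokens.  Their residue embeddings are concatenated
    (12 positions) and refined by the pair-compatibility stack.
    """

    N_RESIDUES = 12

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.module1 = SingleHelixModule(config, rng)
        self.module2 = SingleHelixModule(config, rng)
        self.pair_pos = Embedding(self.N_RESIDUES, config.d_model, rng)
        args = (config.d_model, config.n_heads, config.d_k, config.d_v,
                config.d_ff, config.dropout, rng)
        self.pair_blocks = [
            TransformerBlock(*args) for _ in range(config.n_layer_repeats)
        ]
        self.head = Linear(config.d_model, config.n_residues, rng)
        self.head.weight.data[:] = 0.0

    def logits(self, bases: np.ndarray, residues: np.ndarray) -> Tensor:
        bases = np.atleast_2d(bases)
        residues = np.atleast_2d(residues)
        if bases.shape[1] != 7:
            raise InputError("pair model expects 7-mer targets")
        if residues.shape[1] != 12:
            raise InputError("pair model expects 12 residue tokens")
        h1 = self.module1.hidden(bases[:, 3:], residues[:, :6])
        h2 = self.module2.hidden(bases[:, :4], residues[:, 6:])
        x = Tensor.concat([h1, h2], axis=1)
        pos = np.broadcast_to(np.arange(self.N_RESIDUES), residues.shape)
        x = x + self.pair_pos(pos)
        for block in self.pair_blocks:
            x = block(x)
        return self.head(x)


@dataclass
class TrainedModel:
    """A trained module with its configuration and training metadata."""

    network: SingleHelixModule | PairModel
    config: ModelConfig
    metadata: dict = field(default_factory=dict)

    @property
    def n_residue_positions(self) -> int:
        return self.network.N_RESIDUES

    @property
    def target_length(self) -> int:
        return 7 if isinstance(self.network, PairModel) else 4

    def predict_probs(self, target, residue_tokens: np.ndarray) -> np.ndarray:
        """Per-position probability rows over the 20 residues.

        ``target`` is a 4-mer (single module) or 7-mer (pair model) --
        or a pre-encoded integer array, batched or not.  Dropout is off;
        rows sum to 1.
        """
        bases = encode_bases(target) if isinstance(target, (str, DnaTarget)) else np.asarray(target)
        squeeze = np.asarray(residue_tokens).ndim == 1
        if np.atleast_2d(bases).shape[1] != self.target_length:
            raise InputError(
                f"model expects {self.target_length}-mer targets, "
                f"got length {np.atleast_2d(bases).shape[1]}"
            )
        self.network.eval()
        with no_grad():
            logits = self.network.logits(bases, residue_tokens)
            probs = logits.softmax().data
        return probs[0] if squeeze else probs

    def save(self, path: str | Path) -> None:
        path = Path(path if str(path).endswith(".npz") else str(path) + ".npz")
        np.savez(path, **self.network.state_dict())
        meta = {
            "format_version": 1,
            "kind": "pair" if isinstance(self.network, PairModel) else "single",
            "config": asdict(self.config),
            "metadata": self.metadata,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path if str(path).endswith(".npz") else str(path) + ".npz")
        meta = json.loads(path.with_suffix(".json").read_text())
        config = ModelConfig(**meta["config"])
        rng = np.random.default_rng(0)
        network = (
            PairModel(config, rng) if meta["kind"] == "pair"
            else SingleHelixModule(config, rng)
        )
        archive = np.load(path)
        network.load_state_dict({k: archive[k] for k in archive.files})
        return cls(network=network, config=config, metadata=meta["metadata"])
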