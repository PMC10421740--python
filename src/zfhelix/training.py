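"""Masked language-model training, validation splitting and evaluation.

Training examples are (nucleotide target, helix residues) associations from
filtered selections.  At each step a fraction of the core residues is
masked, the model predicts the masked residues from the target plus the
unmasked residues, and cross-entropy loss is evaluated at masked positions
only.  Optimisation uses Adam; early stopping tracks validation loss and
returns the parameters at its minimum, not the last iterate.

For the full pair model, validation targets are chosen by a graph rule so
that they are genuinely dissimilar from training targets: 7-mers are nodes,
edges connect 7-mers within two base substitutions, components disjoint
from the main component go to validation first, then lowest-degree nodes
together with their neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from zfhelix.model import (
    MASK_TOKEN,
    ModelConfig,
    PairModel,
    SingleHelixModule,
    TrainedModel,
    encode_bases,
    encode_residues,
)
from zfhelix.nn import Adam, Tensor, no_grad
from zfhelix.types import DnaTarget, InputError, SelectionDataset


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults follow the full-scale regime (Adam at 1e-4, minibatch 128, 50%
    masking); ``max_epochs`` and ``max_iterations`` bound the run and are
    scaled down for desk-size experiments.
    """

    learning_rate: float = 1e-4
    batch_size: int = 128
    mask_fraction: float = 0.5
    max_epochs: int = 200
    max_iterations: int | None = None
    patience: int = 5
    init_mode: str = "random"  # random | transfer | transfer_frozen
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mask_fraction <= 1.0:
            raise InputError("mask_fraction must be in (0, 1]")
        if self.patience < 1:
            raise InputError("patience must be >= 1")
        if self.init_mode not in ("random", "transfer", "transfer_frozen"):
            raise InputError(f"unknown init_mode {self.init_mode!r}")


@dataclass(frozen=True)
class MaskedExample:
    """One partially masked training example."""

    sequence: str
    masked_positions: tuple[int, ...]
    tokens: np.ndarray  # residue tokens with MASK_TOKEN at masked positions
    target: str | None = None


def n_masked_positions(length: int, mask_fraction: float) -> int:
    """Exactly round(fraction * length) positions, floored at one."""
    return max(1, int(round(mask_fraction * length)))


def mask_residues(
    sequence, mask_fraction: float, seed: int, target=None
) -> MaskedExample:
    """Mask a fixed fraction of residue positions, uniformly without
    replacement under ``seed``."""
    seq = str(sequence)
    if len(seq) not in (6, 12):
        raise InputError("sequences have 6 (single) or 12 (pair) residues")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), len(seq)]))
    m = n_masked_positions(len(seq), mask_fraction)
    positions = tuple(sorted(rng.choice(len(seq), size=m, replace=False).tolist()))
    tokens = encode_residues(seq)
    tokens[list(positions)] = MASK_TOKEN
    return MaskedExample(
        sequence=seq,
        masked_positions=positions,
        tokens=tokens,
        target=str(target) if target is not None else None,
    )


# ---------------------------------------------------------------------------
# Validation splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    train: tuple[str, ...]
    validation: tuple[str, ...]
    split_axis: str
    proportions: tuple[float, float]

    def __post_init__(self) -> None:
        if set(self.train) & set(self.validation):
            raise InputError("train and validation sets overlap")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_validation_split(
    targets: Sequence[str],
    proportions: tuple[float, float] = (0.9, 0.1),
    radius: int = 2,
) -> SplitSpec:
    """Split target sequences into train/validation by graph dissimilarity.

    Targets are nodes; edges connect targets within ``radius`` base
    substitutions.  Components disjoint from the largest component go to
    validation first; then nodes with the lowest degree, *together with
    their neighbours* (added as a whole, so near-duplicate targets never
    straddle the split), until the validation proportion is reached.
    """
    targets = sorted(set(str(t) for t in targets))
    if len(targets) < 2:
        raise InputError("need at least two targets to split")
    if abs(sum(proportions) - 1.0) > 1e-9 or any(p < 0 for p in proportions):
        raise InputError("proportions must be nonnegative and sum to 1")
    n = len(targets)
    adj: dict[str, set[str]] = {t: set() for t in targets}
    for i, a in enumerate(targets):
        for b in targets[i + 1 :]:
            if _hamming(a, b) <= radius:
                adj[a].add(b)
                adj[b].add(a)

    # connected components; the largest (ties: containing the lexicographically
    # smallest node) is the main component
    unvisited = set(targets)
    components: list[set[str]] = []
    while unvisited:
        seed_node = min(unvisited)
        comp, stack = {seed_node}, [seed_node]
        unvisited.discard(seed_node)
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb in unvisited:
                    unvisited.discard(nb)
                    comp.add(nb)
                    stack.append(nb)
        components.append(comp)
    main = max(components, key=lambda c: (len(c), min(c)))

    validation: list[str] = []
    for comp in components:
        if comp is not main:
            validation.extend(sorted(comp))
    n_val_target = max(1, int(round(proportions[1] * n)))
    remaining = sorted(main)
    taken = set(validation)
    while len(validation) < n_val_target and remaining:
        seed_node = min(
            (t for t in remaining if t not in taken),
            key=lambda t: (len(adj[t]), t),
            default=None,
        )
        if seed_node is None:
            break
        unit = [seed_node] + sorted(nb for nb in adj[seed_node] if nb not in taken)
        validation.extend(unit)
        taken.update(unit)
        remaining = [t for t in remaining if t not in taken]
    train = tuple(t for t in targets if t not in set(validation))
    return SplitSpec(
        train=train,
        validation=tuple(sorted(validation)),
        split_axis="by_target",
        proportions=tuple(proportions),
    )


# ---------------------------------------------------------------------------
# Example preparation
# ---------------------------------------------------------------------------

Example = tuple[str, str]  # (target sequence, residue sequence)


def examples_from_datasets(
    datasets: Iterable[SelectionDataset | Example],
) -> list[Example]:
    """Flatten selections (or raw (target, sequence) tuples) into examples."""
    out: list[Example] = []
    for item in datasets:
        if isinstance(item, SelectionDataset):
            out.extend((str(item.target), rec.sequence) for rec in item.records)
        else:
            target, seq = item
            out.append((str(DnaTarget(str(target))), str(seq)))
    return out


def split_examples(
    examples: Sequence[Example],
    proportions: tuple[float, float] = (0.9, 0.1),
    axis: str = "by_helix",
    seed: int = 0,
) -> tuple[list[Example], list[Example]]:
    """Split examples into train/validation.

    ``by_helix`` keeps every distinct residue sequence on one side (the
    pretraining convention); ``by_target`` uses the dissimilarity-graph rule
    on targets; ``random`` splits records independently.
    """
    examples = list(examples)
    if not examples:
        raise InputError("no training examples")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    if axis == "by_target":
        spec = build_validation_split(
            [t for t, _ in examples], proportions=proportions
        )
        val_targets = set(spec.validation)
        train = [e for e in examples if e[0] not in val_targets]
        val = [e for e in examples if e[0] in val_targets]
        return train, val
    if axis == "by_helix":
        keys = sorted({s for _, s in examples})
    elif axis == "random":
        keys = [f"{i}" for i in range(len(examples))]
    else:
        raise InputError(f"unknown split axis {axis!r}")
    perm = rng.permutation(len(keys))
    n_val = max(1, int(round(proportions[1] * len(keys))))
    val_keys = {keys[i] for i in perm[:n_val]}
    if axis == "random":
        train = [e for i, e in enumerate(examples) if f"{i}" not in val_keys]
        val = [e for i, e in enumerate(examples) if f"{i}" in val_keys]
    else:
        train = [e for e in examples if e[1] not in val_keys]
        val = [e for e in examples if e[1] in val_keys]
    return train, val


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def _encode_examples(examples: Sequence[Example]) -> tuple[np.ndarray, np.ndarray]:
    targets = np.stack([encode_bases(t) for t, _ in examples])
    seqs = np.stack([encode_residues(s) for _, s in examples])
    return targets, seqs


def _draw_masks(
    seqs: np.ndarray, mask_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n, L) mask with exactly the configured count per row."""
    n, L = seqs.shape
    m = n_masked_positions(L, mask_fraction)
    scores = rng.random((n, L))
    order = np.argsort(scores, axis=1)
    mask = np.zeros((n, L), dtype=bool)
    np.put_along_axis(mask, order[:, :m], True, axis=1)
    return mask


def _masked_loss_and_hits(
    network, bases: np.ndarray, seqs: np.ndarray, mask: np.ndarray
) -> tuple[Tensor, int, int]:
    tokens = seqs.copy()
    tokens[mask] = MASK_TOKEN
    logits = network.logits(bases, tokens)
    logp = logits.log_softmax()
    n, L = seqs.shape
    onehot = np.zeros((n, L, logits.shape[-1]))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], seqs] = 1.0
    picked = (logp * Tensor(onehot)).sum(axis=-1)  # (n, L)
    w = mask.astype(float)
    loss = -(picked * Tensor(w)).sum() * (1.0 / w.sum())
    hits = int((logits.data.argmax(axis=-1)[mask] == seqs[mask]).sum())
    return loss, hits, int(w.sum())


def evaluate_masked(
    network, examples: Sequence[Example], mask_fraction: float, seed: int
) -> tuple[float, float]:
    """(loss, accuracy) on fixed seed-derived masks, dropout off."""
    bases, seqs = _encode_examples(examples)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    mask = _draw_masks(seqs, mask_fraction, rng)
    network.eval()
    with no_grad():
        loss, hits, total = _masked_loss_and_hits(network, bases, seqs, mask)
    return float(loss.data), hits / total


def _fit(
    network,
    train_examples: Sequence[Example],
    val_examples: Sequence[Example],
    cfg: TrainConfig,
) -> dict:
    if not train_examples:
        raise InputError("empty training set")
    if not val_examples:
        raise InputError("empty validation set")
    bases, seqs = _encode_examples(train_examples)
    params = [p for p in network.parameters() if p.requires_grad]
    optimizer = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 17]))

    history: list[dict] = []
    best = {"val_loss": np.inf, "state": network.state_dict(), "epoch": -1}
    stale = 0
    iterations = 0
    n = len(train_examples)
    for epoch in range(cfg.max_epochs):
        network.train()
        perm = rng.permutation(n)
        mask = _draw_masks(seqs, cfg.mask_fraction, rng)
        epoch_loss, epoch_hits, epoch_total = 0.0, 0, 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            loss, hits, total = _masked_loss_and_hits(
                network, bases[idx], seqs[idx], mask[idx]
            )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            iterations += 1
            epoch_loss += float(loss.data) * total
            epoch_hits += hits
            epoch_total += total
            if cfg.max_iterations is not None and iterations >= cfg.max_iterations:
                break
        val_loss, val_acc = evaluate_masked(
            network, val_examples, cfg.mask_fraction, cfg.seed
        )
        history.append(
            {
                "epoch": epoch,
                "iterations": iterations,
                "train_loss": epoch_loss / max(1, epoch_total),
                "train_accuracy": epoch_hits / max(1, epoch_total),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_loss < best["val_loss"] - 1e-12:
            best = {"val_loss": val_loss, "state": network.state_dict(), "epoch": epoch}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
        if cfg.max_iterations is not None and iterations >= cfg.max_iterations:
            break
    network.load_state_dict(best["state"])
    return {
        "history": history,
        "best_val_loss": float(best["val_loss"]),
        "best_epoch": best["epoch"],
        "iterations": iterations,
    }


def pretrain_single_module(
    datasets: Iterable[SelectionDataset | Example],
    model_config: ModelConfig,
    train_config: TrainConfig,
    split_axis: str = "by_helix",
) -> TrainedModel:
    """Pretrain one single-helix module on 4-mer selection data."""
    examples = examples_from_datasets(datasets)
    if not examples:
        raise InputError("empty training set")
    if any(len(s) != 6 or len(t) != 4 for t, s in examples):
        raise InputError("single-module examples must be (4-mer, 6 residues)")
    train, val = split_examples(examples, axis=split_axis, seed=train_config.seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(train_config.seed), 23]))
    network = SingleHelixModule(model_config, rng)
    summary = _fit(network, train, val, train_config)
    return TrainedModel(
        network=network,
        config=model_config,
        metadata={"task": "single-pretrain", **summary},
    )


def train_full_model(
    datasets: Iterable[SelectionDataset | Example],
    model_config: ModelConfig,
    train_config: TrainConfig,
    pretrained: tuple[TrainedModel, TrainedModel] | None = None,
) -> TrainedModel:
    """Train the hierarchical pair model on 7-mer selection data.

    ``init_mode`` controls the lower modules: ``random`` initialises them
    fresh, ``transfer`` copies the pretrained single-module parameters, and
    ``transfer_frozen`` additionally freezes them so fine-tuning touches
    only the pair-compatibility module and head.
    """
    examples = examples_from_datasets(datasets)
    if not examples:
        raise InputError("empty training set")
    if any(len(s) != 12 or len(t) != 7 for t, s in examples):
        raise InputError("pair examples must be (7-mer, 12 residues)")
    train, val = split_examples(
        examples, axis="by_target", seed=train_config.seed
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(train_config.seed), 29]))
    network = PairModel(model_config, rng)
    if train_config.init_mode in ("transfer", "transfer_frozen"):
        if pretrained is None:
            raise InputError("transfer init requires pretrained single modules")
        network.module1.load_state_dict(pretrained[0].network.state_dict())
        network.module2.load_state_dict(pretrained[1].network.state_dict())
        if train_config.init_mode == "transfer_frozen":
            for module in (network.module1, network.module2):
                for p in module.parameters():
                    p.requires_grad = False
    summary = _fit(network, train, val, train_config)
    return TrainedModel(
        network=network,
        config=model_config,
        metadata={
            "task": "pair",
            "init_mode": train_config.init_mode,
            "n_train_targets": len({t for t, _ in train}),
            "n_val_targets": len({t for t, _ in val}),
            **summary,
        },
    )


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------


def reconstruction_accuracy(
    model: TrainedModel,
    examples: Iterable[SelectionDataset | Example],
    mask_fraction: float = 0.5,
    seed: int = 0,
    n_masked: int | None = None,
    per_sequence: bool = False,
) -> float:
    """Fraction of masked residues predicted correctly (argmax).

    ``n_masked`` overrides the mask fraction with an exact masked count, for
    accuracy-vs-masking curves.  ``per_sequence`` averages the per-example
    accuracies instead of pooling all masked positions.
    """
    examples = examples_from_datasets(examples)
    bases, seqs = _encode_examples(examples)
    L = seqs.shape[1]
    frac = mask_fraction if n_masked is None else n_masked / L
    if n_masked is not None and not 1 <= n_masked <= L:
        raise InputError("n_masked out of range")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    mask = _draw_masks(seqs, frac, rng)
    model.network.eval()
    with no_grad():
        logits = model.network.logits(bases, np.where(mask, MASK_TOKEN, seqs))
    pred = logits.data.argmax(axis=-1)
    correct = (pred == seqs) & mask
    if per_sequence:
        return float((correct.sum(axis=1) / mask.sum(axis=1)).mean())
    return float(correct.sum() / mask.sum())


def accuracy_by_masked_count(
    model: TrainedModel, examples, seed: int = 0
) -> list[float]:
    """Reconstruction accuracy at every masked count 1..L."""
    examples = examples_from_datasets(examples)
    L = len(examples[0][1])
    return [
        reconstruction_accuracy(model, examples, seed=seed, n_masked=m)
        for m in range(1, L + 1)
    ]


def pwm_mse(p: np.ndarray, q: np.ndarray) -> float:
    """Mean squared elementwise difference of two column-normalized PWMs."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise InputError(f"PWM shapes differ: {p.shape} vs {q.shape}")
    p = p / p.sum(axis=1, keepdims=True)
    q = q / q.sum(axis=1, keepdims=True)
    return float(np.mean((p - q) ** 2))


def predicted_pwm(
    model: TrainedModel,
    target,
    n_samples: int = 500,
    seed: int = 0,
    temperature: float = 1.0,
) -> np.ndarray:
    """PWM of designs sampled from the model at the given temperature."""
    from zfhelix.design import sample_designs

    draws = sample_designs(model, target, n_samples, temperature=temperature, seed=seed)
    L = draws.shape[1]
    pwm = np.zeros((L, model.config.n_residues))
    for pos in range(L):
        pwm[pos] = np.bincount(draws[:, pos], minlength=model.config.n_residues)
    return pwm / pwm.sum(axis=1, keepdims=True)
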