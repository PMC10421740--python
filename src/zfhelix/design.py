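"""Incremental de novo design of zinc-finger helices.

Sequences are generated residue by residue: the model is run on a partially
masked helix (pair), each masked position is scored, one (position, residue)
choice is fixed, and the process repeats.  Two decoding strategies are
provided:

* **A\\*** best-first search over partially masked sequences.  A candidate
  with realized step probabilities :math:`p_1..p_j` has priority
  :math:`\\sum_i \\log p_i + (L - j)\\log p^\\*`, where :math:`p^\\*` is the
  expected maximum probability of future predictions; with
  :math:`p^\\* = 1` the heuristic is admissible and the first completed
  sequence is the exact path-probability argmax.
* **Temperature sampling**: at every iteration the joint distribution over
  all remaining (masked position, residue) choices is sharpened as
  :math:`p^{1/T}` and renormalized over both indices; one choice is drawn
  and fixed.  Many pairs are sampled and the highest-likelihood one kept.

Binding specificity of a designed pair is estimated by pseudolog-likelihood:
each residue in turn is masked and its log-probability computed given the
rest; the per-7-mer sums are normalized into a distribution over all
:math:`4^7 = 16384` targets.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass

import numpy as np

from zfhelix.model import MASK_TOKEN, TrainedModel, decode_residues, encode_bases, encode_residues
from zfhelix.types import BASES, DnaTarget, HelixPair, InputError

__all__ = [
    "AStarParams",
    "DesignCandidate",
    "TemperatureParams",
    "SpecificityProfile",
    "CallableModel",
    "priority",
    "astar_design",
    "temperature_sample",
    "sample_designs",
    "pseudolog_likelihood",
    "specificity_profile",
    "concatenated_baseline_design",
    "concatenated_pwm",
    "all_kmers",
]


@dataclass(frozen=True)
class AStarParams:
    """A* search knobs.

    ``p_star`` is the expected maximum probability the network will assign
    to future predictions (0.1 in production use; 1.0 makes the heuristic
    admissible).  Labels with probability above ``accept_threshold`` are
    expanded.
    """

    p_star: float = 0.1
    accept_threshold: float = 0.05
    n_complete: int = 10
    max_queue: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.p_star <= 1.0:
            raise InputError("p_star must be in (0, 1]")
        if not 0.0 <= self.accept_threshold < 1.0:
            raise InputError("accept_threshold must be in [0, 1)")


@dataclass(frozen=True)
class TemperatureParams:
    """Temperature-biased sampling knobs (T = 0.6, 1e5 samples in
    production use)."""

    temperature: float = 0.6
    n_samples: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise InputError("temperature must be positive")


@dataclass
class DesignCandidate:
    """A partially generated sequence on the A* queue."""

    tokens: np.ndarray  # masked positions hold the mask token
    step_probs: tuple[float, ...] = ()
    mask_token: int = MASK_TOKEN

    @property
    def n_predicted(self) -> int:
        return int((self.tokens != self.mask_token).sum())

    @property
    def complete(self) -> bool:
        return bool((self.tokens != self.mask_token).all())

    @property
    def log_prob(self) -> float:
        return float(sum(math.log(p) for p in self.step_probs))


def priority(candidate: DesignCandidate, p_star: float, n_positions: int | None = None) -> float:
    """Natural-log priority: realized step log-probabilities plus
    ``(L - j) * log(p_star)`` for the unpredicted remainder."""
    if any(p <= 0 for p in candidate.step_probs):
        raise InputError("step probabilities must be positive")
    L = len(candidate.tokens) if n_positions is None else n_positions
    j = candidate.n_predicted
    return candidate.log_prob + (L - j) * math.log(p_star)


class CallableModel:
    """Adapter exposing an arbitrary conditional-probability function as a
    design model (used for frozen toy models and oracles).

    ``fn(tokens)`` must map an ``(n, L)`` token array (masked entries hold
    ``MASK_TOKEN``... i.e. ``n_labels``) to ``(n, L, n_labels)`` rows of
    probabilities.
    """

    def __init__(self, fn, n_positions: int, n_labels: int):
        self.fn = fn
        self.n_residue_positions = n_positions
        self.n_labels = n_labels
        self.target_length = 0

    def predict_probs(self, target, tokens: np.ndarray) -> np.ndarray:
        tokens = np.asarray(tokens)
        squeeze = tokens.ndim == 1
        out = self.fn(np.atleast_2d(tokens))
        return out[0] if squeeze else out


def _n_labels(model) -> int:
    return getattr(model, "n_labels", None) or model.config.n_residues


def _mask_token(model) -> int:
    # toy models use n_labels as their mask token; the trained models use 20
    if isinstance(model, CallableModel):
        return model.n_labels
    return MASK_TOKEN


@dataclass
class DesignResult:
    sequences: list[DesignCandidate]
    exhausted: bool = False  # queue ran dry before n_complete finished

    def helix_pairs(self) -> list[HelixPair]:
        return [HelixPair.from_string(decode_residues(c.tokens)) for c in self.sequences]


def astar_design(model, target, params: AStarParams | None = None) -> DesignResult:
    """Best-first incremental design.

    Maintains a priority queue of partially masked sequences; at every
    iteration the top candidate is passed through the network once, every
    (masked position, label) with probability above the acceptance threshold
    is pushed as an extension, and completed sequences are collected until
    ``n_complete`` of them are generated.  Ties in priority break FIFO by
    insertion order.
    """
    params = params or AStarParams()
    L = model.n_residue_positions
    mask = _mask_token(model)
    root = DesignCandidate(tokens=np.full(L, mask, dtype=np.int64), mask_token=mask)
    counter = itertools.count()
    heap: list[tuple[float, int, DesignCandidate]] = [
        (-priority(root, params.p_star), next(counter), root)
    ]
    completed: dict[str, DesignCandidate] = {}
    ordered: list[DesignCandidate] = []
    # closed set: the same partially masked sequence is reachable through
    # many generation orders; expand each state only once (at its best
    # priority, since the queue is popped best-first)
    expanded: set[bytes] = set()
    while heap and len(ordered) < params.n_complete:
        _, _, cand = heapq.heappop(heap)
        if cand.complete:
            key = ",".join(map(str, cand.tokens))
            if key not in completed or cand.log_prob > completed[key].log_prob:
                if key not in completed:
                    ordered.append(cand)
                completed[key] = cand
            continue
        state = cand.tokens.tobytes()
        if state in expanded:
            continue
        expanded.add(state)
        probs = model.predict_probs(target, cand.tokens)
        for pos in np.flatnonzero(cand.tokens == mask):
            for label in range(_n_labels(model)):
                p = float(probs[pos, label])
                if p > params.accept_threshold:
                    tokens = cand.tokens.copy()
                    tokens[pos] = label
                    child = DesignCandidate(
                        tokens=tokens, step_probs=cand.step_probs + (p,),
                        mask_token=mask,
                    )
                    heapq.heappush(
                        heap, (-priority(child, params.p_star), next(counter), child)
                    )
        if len(heap) > params.max_queue:  # evict worst-priority candidates
            heap = heapq.nsmallest(params.max_queue, heap)
            heapq.heapify(heap)
    ordered.sort(key=lambda c: -c.log_prob)
    return DesignResult(sequences=ordered, exhausted=len(ordered) < params.n_complete)


# ---------------------------------------------------------------------------
# Temperature sampling
# ---------------------------------------------------------------------------


def temperature_adjusted(probs: np.ndarray, mask: np.ndarray, temperature: float) -> np.ndarray:
    """The printed temperature transform: raise every (masked position,
    residue) probability to 1/T and normalize jointly over both indices.

    ``probs`` is ``(.., L, A)``; ``mask`` a boolean ``(.., L)`` of still-open
    positions.  Returns the joint sampling distribution, zero at fixed
    positions.
    """
    w = np.where(mask[..., None], probs, 0.0) ** (1.0 / temperature)
    total = w.sum(axis=(-2, -1), keepdims=True)
    return w / total


def sample_designs(
    model,
    target,
    n_samples: int,
    temperature: float = 1.0,
    seed: int = 0,
    return_logprobs: bool = False,
):
    """Vectorized incremental sampling of ``n_samples`` sequences.

    At each of L iterations the joint temperature-adjusted distribution over
    the remaining (position, residue) choices is formed per sample, one
    choice is drawn and fixed, and the model is re-run with the enlarged
    context.  Returns an ``(n_samples, L)`` token array (plus, optionally,
    the raw-model generation-path log-probabilities).
    """
    L = model.n_residue_positions
    A = _n_labels(model)
    mask_token = _mask_token(model)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 37]))
    tokens = np.full((n_samples, L), mask_token, dtype=np.int64)
    path_logprob = np.zeros(n_samples)
    bases = None
    if isinstance(model, TrainedModel):
        bases = np.broadcast_to(encode_bases(str(target)), (n_samples, model.target_length))
    rows_idx = np.arange(n_samples)
    for _ in range(L):
        probs = (
            model.predict_probs(bases, tokens)
            if bases is not None
            else model.predict_probs(target, tokens)
        )
        open_mask = tokens == mask_token
        joint = temperature_adjusted(probs, open_mask, temperature)
        flat = joint.reshape(n_samples, L * A)
        cdf = np.cumsum(flat, axis=1)
        u = rng.random((n_samples, 1)) * cdf[:, -1:]
        choice = (u > cdf).sum(axis=1)
        pos, label = np.divmod(choice, A)
        tokens[rows_idx, pos] = label
        path_logprob += np.log(np.clip(probs[rows_idx, pos, label], 1e-300, None))
    if return_logprobs:
        return tokens, path_logprob
    return tokens


def temperature_sample(
    model,
    target,
    params: TemperatureParams | None = None,
    score: str = "pseudo",
) -> tuple[DesignCandidate, np.ndarray]:
    """Sample many designs and return the maximum-likelihood one.

    ``score`` selects how the best sample is chosen: ``"pseudo"``
    (pseudolog-likelihood of each unique sample, the default) or ``"path"``
    (best raw-model generation-path log-probability).
    """
    params = params or TemperatureParams()
    draws, path_logprobs = sample_designs(
        model, target, params.n_samples, params.temperature, params.seed,
        return_logprobs=True,
    )
    if score == "path":
        best_row = int(np.argmax(path_logprobs))
        return DesignCandidate(tokens=draws[best_row]), draws
    if score != "pseudo":
        raise InputError(f"unknown score {score!r}")
    unique = np.unique(draws, axis=0)
    scores = _pll_batch(model, target, unique)
    best = int(np.argmax(scores))
    return DesignCandidate(tokens=unique[best]), draws


# ---------------------------------------------------------------------------
# Specificity profiles
# ---------------------------------------------------------------------------


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def _pll_batch(model, target, rows: np.ndarray) -> np.ndarray:
    """Pseudolog-likelihoods of many token rows against one target: for
    each position in turn, mask it in every row and accumulate
    log P(token | target, all other tokens)."""
    rows = np.atleast_2d(rows)
    n, L = rows.shape
    mask = _mask_token(model)
    bases = None
    if isinstance(model, TrainedModel):
        bases = np.broadcast_to(encode_bases(str(target)), (n, model.target_length))
    out = np.zeros(n)
    for pos in range(L):
        masked = rows.copy()
        masked[:, pos] = mask
        probs = (
            model.predict_probs(bases, masked)
            if bases is not None
            else model.predict_probs(target, masked)
        )
        out += np.log(np.clip(probs[np.arange(n), pos, rows[:, pos]], 1e-300, None))
    return out


def _pll_tokens(model, target, tokens: np.ndarray) -> float:
    """Pseudolog-likelihood of one token row: sum over positions of
    log P(token | target, all other tokens)."""
    return float(_pll_batch(model, target, np.asarray(tokens))[0])


def pseudolog_likelihood(model: TrainedModel, pair: HelixPair | str, target) -> float:
    """Pseudolog-likelihood of a helix pair against one 7-mer."""
    tokens = encode_residues(str(pair))
    return _pll_tokens(model, str(DnaTarget(str(target))), tokens)


@dataclass
class SpecificityProfile:
    """Normalized binding-specificity distribution over all 7-mer targets."""

    targets: list[str]
    probabilities: np.ndarray
    pseudolog_likelihoods: np.ndarray
    normalization: str = "softmax"

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.targets, self.probabilities.tolist()))

    @property
    def argmax_target(self) -> str:
        return self.targets[int(np.argmax(self.probabilities))]


def specificity_profile(
    model: TrainedModel,
    pair: HelixPair | str,
    normalization: str = "softmax",
    chunk: int = 2048,
) -> SpecificityProfile:
    """Pseudolog-likelihood of ``pair`` with every 7-mer, normalized to a
    distribution.

    For each of the 12 residues in turn, the residue is masked and its
    log-probability computed with the remaining residues as context, for
    all 4^7 targets in one batched pass; the 12 terms are summed per target.
    ``normalization`` is ``"softmax"`` (default) or ``"shift_scale"``
    (subtract the minimum, divide by the sum).
    """
    tokens = encode_residues(str(pair))
    if len(tokens) != model.n_residue_positions:
        raise InputError("pair length does not match the model")
    targets = all_kmers(7)
    bases_all = np.stack([encode_bases(t) for t in targets])
    n = len(targets)
    pll = np.zeros(n)
    for pos in range(len(tokens)):
        masked = tokens.copy()
        masked[pos] = MASK_TOKEN
        for start in range(0, n, chunk):
            batch = bases_all[start : start + chunk]
            rows = np.broadcast_to(masked, (len(batch), len(tokens)))
            probs = model.predict_probs(batch, rows)
            pll[start : start + chunk] += np.log(
                np.clip(probs[:, pos, tokens[pos]], 1e-300, None)
            )
    if normalization == "softmax":
        z = pll - pll.max()
        p = np.exp(z)
        p /= p.sum()
    elif normalization == "shift_scale":
        z = pll - pll.min()
        p = z / z.sum() if z.sum() > 0 else np.full(n, 1.0 / n)
    else:
        raise InputError(f"unknown normalization {normalization!r}")
    return SpecificityProfile(
        targets=targets,
        probabilities=p,
        pseudolog_likelihoods=pll,
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# Concatenated single-finger baseline
# ---------------------------------------------------------------------------


def _greedy_design(model, target) -> np.ndarray:
    """Deterministic greedy decoding: repeatedly fix the single most
    confident (position, residue) choice."""
    L = model.n_residue_positions
    mask = _mask_token(model)
    tokens = np.full(L, mask, dtype=np.int64)
    for _ in range(L):
        probs = model.predict_probs(target, tokens)
        open_pos = tokens == mask
        joint = np.where(open_pos[:, None], probs, -1.0)
        pos, label = np.unravel_index(int(np.argmax(joint)), joint.shape)
        tokens[pos] = label
    return tokens


def _split_target(target) -> tuple[str, str]:
    """Sub-targets of a 6/7-mer for the two single modules.

    A 6-mer (two bare triplets) is promoted to a 7-mer by prepending an
    ambiguous environment base, fixed to A.
    """
    t = str(target)
    if len(t) == 6:
        t = "A" + t
    target = DnaTarget(t)
    if len(target) != 7:
        raise InputError("baseline design needs a 6- or 7-mer target")
    sub1, sub2 = target.subtargets()
    return str(sub1), str(sub2)


def concatenated_baseline_design(
    single_modules: tuple[TrainedModel, TrainedModel], target
) -> HelixPair:
    """Design each finger independently from its sub-4-mer with the
    pretrained single modules and concatenate -- the modular baseline that
    ignores interhelix compatibility."""
    sub1, sub2 = _split_target(target)
    m1, m2 = single_modules
    f1 = _greedy_design(m1, sub1)
    f2 = _greedy_design(m2, sub2)
    return HelixPair.from_string(decode_residues(np.concatenate([f1, f2])))


#: Default Cys2His2 finger scaffold; ``{helix}`` receives the seven helix
#: residues (six designable positions with the invariant +4 leucine
#: restored).  Two fingers are joined by the canonical TGEKP linker.
DEFAULT_SCAFFOLD = "PYKCPECGKSFS{helix}HQRTH"
FINGER_LINKER = "TGEKP"


def render_fasta(
    pairs: list[HelixPair],
    names: list[str] | None = None,
    scaffold: str = DEFAULT_SCAFFOLD,
) -> str:
    """FASTA of designed helix pairs embedded in a finger scaffold.

    Each finger's six designable residues are placed in ``scaffold`` at the
    ``{helix}`` slot (with the +4 leucine restored); the two fingers are
    joined with the canonical TGEKP linker, finger1 first.
    """
    if "{helix}" not in scaffold:
        raise InputError("scaffold template needs a {helix} placeholder")
    lines = []
    for i, pair in enumerate(pairs):
        name = names[i] if names else f"design_{i + 1}"
        fingers = []
        for finger in (pair.finger1, pair.finger2):
            h = finger.residues
            fingers.append(scaffold.format(helix=h[:4] + "L" + h[4:]))
        lines.append(f">{name}")
        lines.append(FINGER_LINKER.join(fingers))
    return "\n".join(lines) + "\n"


def concatenated_pwm(
    single_modules: tuple[TrainedModel, TrainedModel],
    target,
    n_samples: int = 500,
    seed: int = 0,
    temperature: float = 1.0,
) -> np.ndarray:
    """(12, 20) PWM from sampling each single module on its own sub-target
    and concatenating -- the PWM-space version of the modular baseline."""
    from zfhelix.training import predicted_pwm

    sub1, sub2 = _split_target(target)
    m1, m2 = single_modules
    p1 = predicted_pwm(m1, sub1, n_samples=n_samples, seed=seed, temperature=temperature)
    p2 = predicted_pwm(m2, sub2, n_samples=n_samples, seed=seed + 1, temperature=temperature)
    return np.vstack([p1, p2])
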