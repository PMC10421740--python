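"""Selection-level analytics.

Helices recovered in one selection typically mix several distinct binding
strategies, so a single PWM is a poor summary.  Sequences are clustered with
an EM-fitted mixture of product-multinomial PWMs (responsibility-based
assignment in the style of multiple-specificity motif tools), selections are
quality-controlled on the information content of their strongest cluster,
libraries are compared by mean minimum normalized Hamming distance, and
promiscuity of binding is quantified as summed positional entropy of the
targets a set of core residues was recovered against.  The same machinery,
over the nucleotide alphabet, drives the 8-bp specificity-library pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from zfhelix.types import AMINO_ACIDS, BASES, InputError

# ---------------------------------------------------------------------------
# Mixture of PWMs
# ---------------------------------------------------------------------------


@dataclass
class PwmCluster:
    """One mixture component: a PWM with its mixture weight and entropies."""

    pwm: np.ndarray  # (L, A), columns (rows here) sum to 1
    weight: float
    alphabet: str

    @property
    def per_position_entropy(self) -> np.ndarray:
        """Shannon entropy (bits) of each position of the PWM."""
        p = np.clip(self.pwm, 1e-300, None)
        return -(p * np.log2(p)).sum(axis=1)

    @property
    def max_information_content(self) -> float:
        """log2(alphabet size) minus the minimum positional entropy (bits)."""
        return math.log2(len(self.alphabet)) - float(self.per_position_entropy.min())


@dataclass
class ClusterModel:
    """An EM-fitted mixture of PWMs over a set of weighted sequences."""

    clusters: list[PwmCluster]
    responsibilities: np.ndarray  # (n, k), rows sum to 1
    log_likelihood_trace: list[float]
    sequences: list[str]
    weights: np.ndarray

    @property
    def k(self) -> int:
        return len(self.clusters)

    @property
    def assignments(self) -> np.ndarray:
        """Hard assignment by maximum responsibility (ties -> lowest index)."""
        return self.responsibilities.argmax(axis=1)

    @property
    def log_likelihood(self) -> float:
        return self.log_likelihood_trace[-1]


def _encode(sequences: Sequence[str], alphabet: str) -> np.ndarray:
    index = {a: i for i, a in enumerate(alphabet)}
    try:
        return np.array([[index[c] for c in s] for s in sequences], dtype=np.int64)
    except KeyError as exc:
        raise InputError(f"symbol {exc} outside alphabet {alphabet!r}") from None


def _em_once(
    x: np.ndarray,
    w: np.ndarray,
    k: int,
    n_aa: int,
    pseudocount: float,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    n, L = x.shape
    resp = rng.dirichlet(np.ones(k), size=n)
    onehot = np.zeros((n, L, n_aa))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], x] = 1.0
    trace: list[float] = []
    pi = np.full(k, 1.0 / k)
    pwm = np.full((k, L, n_aa), 1.0 / n_aa)
    for _ in range(max_iter):
        # M step from current responsibilities
        wr = resp * w[:, None]  # (n, k)
        pi = wr.sum(axis=0)
        pi = pi / pi.sum()
        counts = np.einsum("nk,nla->kla", wr, onehot) + pseudocount
        pwm = counts / counts.sum(axis=2, keepdims=True)
        # E step
        logp = np.einsum("nla,kla->nk", onehot, np.log(pwm))
        logp = logp + np.log(pi)[None, :]
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        resp = np.exp(logp - lse[:, None])
        # objective: weighted log-likelihood plus the pseudocount (Dirichlet)
        # prior on the PWMs -- the quantity EM increases monotonically
        obj = float((w * lse).sum() + pseudocount * np.log(pwm).sum())
        trace.append(obj)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1 + abs(trace[-2])):
            break
    return pi, pwm, resp, trace


def fit_pwm_mixture(
    helices: Sequence[str],
    read_weights: Sequence[float] | None = None,
    k: int | str = 2,
    alphabet: str = AMINO_ACIDS,
    pseudocount: float = 0.5,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-9,
    seed: int = 0,
    max_k: int = 5,
) -> ClusterModel:
    """EM fit of a mixture of product-multinomial PWMs to weighted sequences.

    With ``k=1`` the fitted PWM is exactly the weighted position frequency
    matrix with pseudocounts.  With ``k="auto"`` the component count in
    ``1..max_k`` is selected by BIC.  Restarts use fixed, seed-derived
    initialisations; the best penalised log-likelihood wins.
    """
    helices = list(helices)
    if not helices:
        raise InputError("cannot fit a mixture to an empty set of helices")
    lengths = {len(h) for h in helices}
    if len(lengths) != 1:
        raise InputError("all sequences must share one length")
    x = _encode(helices, alphabet)
    w = (
        np.ones(len(helices))
        if read_weights is None
        else np.asarray(read_weights, dtype=float)
    )
    if len(w) != len(helices) or (w <= 0).any():
        raise InputError("read_weights must be positive and match helices")

    if k == "auto":
        best = None
        for kk in range(1, max_k + 1):
            if kk > len(set(helices)):
                break
            model = fit_pwm_mixture(
                helices, read_weights, kk, alphabet, pseudocount,
                n_restarts, max_iter, tol, seed,
            )
            n_params = (kk - 1) + kk * x.shape[1] * (len(alphabet) - 1)
            bic = -2.0 * model.log_likelihood + n_params * math.log(w.sum())
            if best is None or bic < best[0]:
                best = (bic, model)
        return best[1]

    k = int(k)
    if k < 1:
        raise InputError("k must be >= 1")
    if k > len(set(helices)):
        raise InputError(f"k={k} exceeds the {len(set(helices))} distinct sequences")

    best_fit = None
    for restart in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), restart]))
        pi, pwm, resp, trace = _em_once(
            x, w, k, len(alphabet), pseudocount, rng, max_iter, tol
        )
        if best_fit is None or trace[-1] > best_fit[3][-1]:
            best_fit = (pi, pwm, resp, trace)
    pi, pwm, resp, trace = best_fit
    order = np.argsort(-pi)  # strongest component first
    clusters = [PwmCluster(pwm=pwm[i], weight=float(pi[i]), alphabet=alphabet) for i in order]
    return ClusterModel(
        clusters=clusters,
        responsibilities=resp[:, order],
        log_likelihood_trace=trace,
        sequences=helices,
        weights=w,
    )


@dataclass(frozen=True)
class QcResult:
    passed: bool
    max_information_content: float
    strongest_cluster: int


def selection_qc(model: ClusterModel, entropy_threshold: float = 2.0) -> QcResult:
    """Pass a selection iff some cluster has some position with Shannon
    entropy at or below ``entropy_threshold`` bits (equivalently, information
    content of at least log2(A) - threshold at that position).

    Also reports the maximum information content at one position of the
    strongest (highest-weight) cluster, the per-selection enrichment
    statistic used to compare libraries.
    """
    passed = any(
        float(c.per_position_entropy.min()) <= entropy_threshold
        for c in model.clusters
    )
    return QcResult(
        passed=passed,
        max_information_content=model.clusters[0].max_information_content,
        strongest_cluster=0,
    )


# ---------------------------------------------------------------------------
# Library comparison and promiscuity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryComparison:
    distance: float
    a_to_b: np.ndarray  # per-helix directed minima, A -> B
    b_to_a: np.ndarray


def library_distance(
    helix_set_a: Iterable[str],
    helix_set_b: Iterable[str],
    deduplicate: bool = True,
    weights_a: Sequence[float] | None = None,
    weights_b: Sequence[float] | None = None,
) -> LibraryComparison:
    """Mean of directed minimum normalized Hamming distances between two
    helix sets.

    For each helix in A the minimum normalized Hamming distance to any helix
    in B is computed, and vice versa; the overall distance is the mean of all
    these minima (read-weighted when weights are given).
    """
    a = list(helix_set_a)
    b = list(helix_set_b)
    if not a or not b:
        raise InputError("both helix sets must be nonempty")
    if deduplicate:
        if weights_a is not None or weights_b is not None:
            raise InputError("weights require deduplicate=False")
        a, b = sorted(set(a)), sorted(set(b))
    if len({len(s) for s in a + b}) != 1:
        raise InputError("all helices must share one length")
    xa = np.array([[ord(c) for c in s] for s in a])
    xb = np.array([[ord(c) for c in s] for s in b])
    dist = (xa[:, None, :] != xb[None, :, :]).mean(axis=2)  # (|A|, |B|)
    a_min = dist.min(axis=1)
    b_min = dist.min(axis=0)
    wa = np.ones(len(a)) if weights_a is None else np.asarray(weights_a, float)
    wb = np.ones(len(b)) if weights_b is None else np.asarray(weights_b, float)
    # pooled mean over all |A| + |B| directed minima
    overall = float(((a_min * wa).sum() + (b_min * wb).sum()) / (wa.sum() + wb.sum()))
    return LibraryComparison(distance=overall, a_to_b=a_min, b_to_a=b_min)


@dataclass(frozen=True)
class PromiscuityScore:
    target_3mer: str
    entropy_bits: float  # in [0, 6]


def promiscuity_entropy(
    core_to_targets: Mapping[str, Iterable[str]],
) -> dict[str, PromiscuityScore]:
    """Target-selection entropy of binding, per 3-mer.

    ``core_to_targets`` maps a set of core residues (positions -1, 2, 3, 6)
    to the multiset of 3-mer targets it was recovered against.  For each
    3-mer, the 3-mers bound by every core set recovered against it are
    pooled into a position frequency matrix; entropy is computed
    position-wise in bits and summed.  0 bits = perfectly specific;
    6 bits = uniform recovery over all 64 3-mers.
    """
    if not core_to_targets:
        raise InputError("core_to_targets must not be empty")
    pooled: dict[str, list[str]] = {}
    for core, targets in core_to_targets.items():
        targets = [str(t) for t in targets]
        if not targets:
            raise InputError(f"empty target multiset for core residues {core!r}")
        for t in set(targets):
            pooled.setdefault(t, []).extend(targets)
    out = {}
    for t, pool in pooled.items():
        x = _encode(pool, BASES)
        h = 0.0
        for pos in range(3):
            counts = np.bincount(x[:, pos], minlength=4).astype(float)
            p = counts / counts.sum()
            p = p[p > 0]
            h += float(-(p * np.log2(p)).sum())
        out[t] = PromiscuityScore(target_3mer=t, entropy_bits=h)
    return out


# ---------------------------------------------------------------------------
# 8-bp specificity-library pipeline
# ---------------------------------------------------------------------------


@dataclass
class EightMerTable:
    """Reads of an 8-bp specificity library: per-8-mer, per-plasmid counts,
    plus the sequenced background library."""

    counts: dict[str, dict[str, int]]  # 8-mer -> plasmid barcode -> reads
    background: dict[str, int] = field(default_factory=dict)

    def total(self, kmer: str) -> int:
        return sum(self.counts[kmer].values())


@dataclass
class EightMerResult:
    weights: dict[str, float]  # background-normalized enrichment weights
    model: ClusterModel  # 2-motif nucleotide mixture
    dropped: dict[str, str]  # 8-mer -> reason


def plasmid_entropy(plasmid_counts: Mapping[str, int], normalized: bool = True) -> float:
    """Shannon entropy (bits) of the read distribution across plasmids,
    normalized by log2 of the number of plasmids observed for the 8-mer."""
    counts = np.array([c for c in plasmid_counts.values() if c > 0], dtype=float)
    if counts.size <= 1:
        return 0.0
    p = counts / counts.sum()
    h = float(-(p * np.log2(p)).sum())
    if normalized:
        h /= math.log2(counts.size)
    return h


def filter_8mer_reads(
    table: EightMerTable,
    min_reads: int = 10,
    entropy_threshold: float = 0.1,
    reapply_reads_filter: bool = True,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
) -> EightMerResult:
    """Filter and background-normalize an 8-bp specificity library, then
    cluster the surviving 8-mers into ``k`` motifs.

    Filters, in order: (1) drop 8-mers with fewer than ``min_reads`` total
    reads; (2) drop 8-mers recovered on a single unique plasmid; (3) if the
    plasmid-read entropy of an 8-mer is below ``entropy_threshold``, drop the
    reads of its most frequent plasmid (so escapee plasmids cannot dominate),
    then re-apply the reads filter.  Surviving read totals are divided by the
    background-library frequency of the 8-mer.
    """
    dropped: dict[str, str] = {}
    kept: dict[str, dict[str, int]] = {}
    for kmer, plasmids in table.counts.items():
        plasmids = {p: c for p, c in plasmids.items() if c > 0}
        if sum(plasmids.values()) < min_reads:
            dropped[kmer] = "reads"
            continue
        if len(plasmids) < 2:
            dropped[kmer] = "single-plasmid"
            continue
        if plasmid_entropy(plasmids) < entropy_threshold:
            top = max(plasmids, key=lambda p: (plasmids[p], p))
            plasmids = {p: c for p, c in plasmids.items() if p != top}
            if reapply_reads_filter and sum(plasmids.values()) < min_reads:
                dropped[kmer] = "reads-after-escapee-drop"
                continue
        kept[kmer] = plasmids

    if not kept:
        raise InputError("no 8-mers survive filtering")
    bg_total = sum(table.background.values())
    weights: dict[str, float] = {}
    for kmer, plasmids in kept.items():
        bg = table.background.get(kmer, 0)
        if bg <= 0:
            raise InputError(f"background library has no reads for retained 8-mer {kmer}")
        weights[kmer] = sum(plasmids.values()) / (bg / bg_total)
    model = fit_pwm_mixture(
        sorted(weights),
        read_weights=[weights[s] for s in sorted(weights)],
        k=min(k, len(set(weights))),
        alphabet=BASES,
        seed=seed,
        n_restarts=n_restarts,
    )
    return EightMerResult(weights=weights, model=model, dropped=dropped)


# ---------------------------------------------------------------------------
# Motif export
# ---------------------------------------------------------------------------


def write_meme(model: ClusterModel, path, name_prefix: str = "cluster") -> None:
    """Write the mixture components in MEME minimal motif format."""
    alphabet = model.clusters[0].alphabet
    kind = "ACGT" if alphabet == BASES else "protein"
    lines = ["MEME version 4", "", f"ALPHABET= {alphabet}", ""]
    if kind == "ACGT":
        lines.insert(3, "strands: +")
        lines.insert(4, "")
    for i, cluster in enumerate(model.clusters):
        L = cluster.pwm.shape[0]
        lines.append(f"MOTIF {name_prefix}_{i + 1}")
        lines.append(
            f"letter-probability matrix: alength= {len(alphabet)} w= {L} "
            f"nsites= {max(1, int(round(model.weights.sum() * cluster.weight)))} E= 0"
        )
        for row in cluster.pwm:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        lines.append("")
    from pathlib import Path

    Path(path).write_text("\n".join(lines))
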