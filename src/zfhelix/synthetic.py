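"""Synthetic B1H selection simulator with a known ground-truth recognition code.

Real selection data are gated behind a material-transfer agreement, so the
package carries a statistical stand-in: a random *recognition code* assigns a
binding energy to every (helix, target, neighbour-environment) combination,
and selections are simulated as Boltzmann survival of randomly drawn
candidates plus a small rate of selection escapees.

The energy model is deliberately structured so that every quantity of
interest has a closed form:

* each helix position contributes an independent energy against the base it
  contacts (positions -1/1 read triplet base 1, positions 2/3 read triplet
  base 2, positions 5/6 read triplet base 3 of the ``[overlap, t1, t2, t3]``
  sub-target);
* one three-way *context* term couples the neighbouring finger's position-6
  residue, the overlap base, and this finger's positions -1/2 -- the minimal
  structure under which the selected helix population depends on the
  neighbour-finger environment.

Because the couplings touch small, disjoint groups of positions, the
Boltzmann survivor distribution factorises into independent categorical
factors.  Ground-truth PWMs are therefore exact, and survivors can be drawn
directly from the conditional distribution instead of rejection-sampling
billions of plated cells.

This is a statistical test harness, not a physical model: no structure, no
solvent, no affinity scale -- just a reproducible nonlinear code with the
neighbour-context phenomenology of real selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from zfhelix.types import (
    AMINO_ACIDS,
    BASE_INDEX,
    CoreHelix,
    DnaTarget,
    HelixPair,
    InputError,
    LibraryContext,
    SelectionDataset,
    SelectionRecord,
)

#: 4-mer base index contacted by each helix position (-1, 1, 2, 3, 5, 6).
#: The overlap base (index 0) is contacted only through the context term.
CONTACT_MAP: tuple[int, ...] = (1, 1, 2, 2, 3, 3)

# Codons with G or C in the wobble position (NNS degeneracy), keyed by the
# residue they encode.  TAG (amber) is the single stop in the NNS set.
_NNS_BY_AA: dict[str, tuple[str, ...]] | None = None


def nns_codons(aa: str) -> tuple[str, ...]:
    """All NNS codons (third base G/C) encoding amino acid ``aa``."""
    global _NNS_BY_AA
    if _NNS_BY_AA is None:
        from Bio.Seq import Seq

        table: dict[str, list[str]] = {}
        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "GC":
                    codon = b1 + b2 + b3
                    res = str(Seq(codon).translate())
                    if res != "*":
                        table.setdefault(res, []).append(codon)
        _NNS_BY_AA = {k: tuple(v) for k, v in table.items()}
    return _NNS_BY_AA[aa]


def _rng(seed: int, *tags: int) -> np.random.Generator:
    """Counter-split generator: one integer seed plus purpose tags."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, tags)]))


@dataclass(frozen=True)
class RecognitionCode:
    """A ground-truth protein-DNA recognition code.

    Attributes
    ----------
    single_energy
        ``(6, A, 4)`` energy (arbitrary units) of residue *a* at helix
        position *p* against its contacted base.
    context_energy
        ``(A, 4, A, A)`` coupling of (neighbour position-6 residue,
        overlap base, this finger's position -1 residue, position 2 residue).
        Scaled by ``context_strength``; at strength 0 pair binding energies
        are exactly additive over fingers.
    stringency
        Inverse temperature of Boltzmann survival.
    alphabet
        Amino-acid alphabet (a prefix of the 20 standard residues when
        reduced for exhaustive checks).
    """

    single_energy: np.ndarray
    context_energy: np.ndarray
    context_strength: float
    stringency: float
    seed: int
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.single_energy)):
            raise InputError("single_energy must be finite")
        if not np.all(np.isfinite(self.context_energy)):
            raise InputError("context_energy must be finite")
        if self.context_strength < 0:
            raise InputError("context_strength must be nonnegative")

    @property
    def n_aa(self) -> int:
        return len(self.alphabet)

    def aa_index(self, seq: str) -> np.ndarray:
        idx = np.array([self.alphabet.find(a) for a in seq], dtype=np.int64)
        if (idx < 0).any():
            raise InputError(f"residues of {seq!r} outside code alphabet {self.alphabet!r}")
        return idx


def sample_code(
    seed: int,
    context_strength: float,
    n_aa: int = 20,
    stringency: float = 2.0,
) -> RecognitionCode:
    """Draw a reproducible random recognition code.

    Energies are i.i.d. standard normal in arbitrary units; ``stringency``
    (default 2.0) concentrates survivor populations to the high-information
    regime typical of successful selections.  ``n_aa < 20`` restricts the
    alphabet to the first ``n_aa`` standard residues for exhaustive checks.
    """
    if context_strength < 0:
        raise InputError("context_strength must be nonnegative")
    if not 2 <= n_aa <= 20:
        raise InputError("n_aa must be in [2, 20]")
    rng = _rng(seed, 0xC0DE)
    single = rng.standard_normal((6, n_aa, 4))
    context = rng.standard_normal((n_aa, 4, n_aa, n_aa))
    return RecognitionCode(
        single_energy=single,
        context_energy=context,
        context_strength=float(context_strength),
        stringency=float(stringency),
        seed=int(seed),
        alphabet=AMINO_ACIDS[:n_aa],
    )


def sample_deterministic_code(seed: int, stringency: float = 25.0) -> RecognitionCode:
    """A context-free code with one unambiguous best helix per target.

    Each (position, contacted base) has its minimum energy lowered well
    clear of the runner-up, so at high stringency every selection recovers
    exactly one helix -- the fixture behind learnable-by-construction
    training checks.
    """
    code = sample_code(seed, 0.0, stringency=stringency)
    single = code.single_energy.copy()
    for pos in range(6):
        for base in range(4):
            best = int(np.argmin(single[pos, :, base]))
            single[pos, best, base] -= 3.0
    return RecognitionCode(
        single_energy=single,
        context_energy=code.context_energy,
        context_strength=0.0,
        stringency=stringency,
        seed=code.seed,
        alphabet=code.alphabet,
    )


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of one simulated selection.

    Defaults mirror the scale of a real selection: >=5e8 double transformants
    plated, deep sequencing of the surviving pool, a handful of synonymous
    NNS encodings per recovered helix, and a tiny per-cell probability of
    escaping selective pressure.
    """

    n_candidates: int = 500_000_000
    read_depth: float = 50.0
    #: P(number of distinct NNS encodings = 1, 2, 3, 4) for a recovered helix.
    n_encodings_dist: tuple[float, ...] = (0.3, 0.35, 0.2, 0.15)
    escapee_rate: float = 5e-8
    seed: int = 0
    #: Sequencing/colony-picking cap: at most this many surviving cells are
    #: recovered per selection (None = recover everything).
    max_survivors: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.escapee_rate <= 1.0:
            raise InputError("escapee_rate must be in [0, 1]")
        if self.n_candidates < 0:
            raise InputError("n_candidates must be nonnegative")
        if self.read_depth <= 0:
            raise InputError("read_depth must be positive")
        p = np.asarray(self.n_encodings_dist, dtype=float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise InputError("n_encodings_dist must be a probability vector")


# ---------------------------------------------------------------------------
# Factorised log-weight model of Boltzmann survival
# ---------------------------------------------------------------------------


@dataclass
class EnergyModel:
    """Log Boltzmann weights over helix residues, factorised into disjoint
    independent factors.

    ``unary[i]`` holds per-residue log-weights for every position *i* not in a
    block; ``blocks`` is a list of ``(positions, table)`` joint factors whose
    tables already include those positions' unary terms.
    """

    n_positions: int
    n_aa: int
    unary: np.ndarray  # (L, A); rows covered by a block are zeroed
    blocks: list[tuple[tuple[int, ...], np.ndarray]] = field(default_factory=list)

    def logw(self, helices: np.ndarray) -> np.ndarray:
        """Log-weight of each helix in an ``(n, L)`` residue-index array."""
        helices = np.atleast_2d(helices)
        out = np.zeros(len(helices))
        free = self._free_positions()
        for i in free:
            out += self.unary[i, helices[:, i]]
        for pos, table in self.blocks:
            out += table[tuple(helices[:, p] for p in pos)]
        return out

    def _free_positions(self) -> list[int]:
        in_block = {p for pos, _ in self.blocks for p in pos}
        return [i for i in range(self.n_positions) if i not in in_block]

    def max_logw(self) -> float:
        total = sum(self.unary[i].max() for i in self._free_positions())
        total += sum(table.max() for _, table in self.blocks)
        return float(total)

    def argmax(self) -> np.ndarray:
        """The single highest-weight helix (ties broken by lowest index)."""
        out = np.zeros(self.n_positions, dtype=np.int64)
        for i in self._free_positions():
            out[i] = int(np.argmax(self.unary[i]))
        for pos, table in self.blocks:
            flat = int(np.argmax(table))
            for p, v in zip(pos, np.unravel_index(flat, table.shape)):
                out[p] = v
        return out

    def mean_acceptance(self) -> float:
        """Mean of ``exp(logw - max_logw)`` under uniform candidate draws.

        This is the per-cell Boltzmann survival probability averaged over the
        whole candidate space, and factorises over the disjoint factors.
        """
        acc = 1.0
        for i in self._free_positions():
            w = self.unary[i]
            acc *= float(np.exp(w - w.max()).mean())
        for _, table in self.blocks:
            acc *= float(np.exp(table - table.max()).mean())
        return acc

    def log_partition(self) -> float:
        """log of the sum of ``exp(logw)`` over all helices."""
        from scipy.special import logsumexp

        total = 0.0
        for i in self._free_positions():
            total += float(logsumexp(self.unary[i]))
        for _, table in self.blocks:
            total += float(logsumexp(table))
        return total

    def marginals(self) -> np.ndarray:
        """Exact per-position survivor distribution, ``(L, A)``, rows sum to 1."""
        pwm = np.zeros((self.n_positions, self.n_aa))
        for i in self._free_positions():
            w = np.exp(self.unary[i] - self.unary[i].max())
            pwm[i] = w / w.sum()
        for pos, table in self.blocks:
            w = np.exp(table - table.max())
            w /= w.sum()
            for axis, p in enumerate(pos):
                others = tuple(a for a in range(len(pos)) if a != axis)
                pwm[p] = w.sum(axis=others)
        return pwm

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """``n`` i.i.d. survivor draws from the factorised Gibbs distribution."""
        out = np.zeros((n, self.n_positions), dtype=np.int64)
        if n == 0:
            return out
        for i in self._free_positions():
            w = np.exp(self.unary[i] - self.unary[i].max())
            out[:, i] = rng.choice(self.n_aa, size=n, p=w / w.sum())
        for pos, table in self.blocks:
            w = np.exp(table - table.max()).ravel()
            flat = rng.choice(table.size, size=n, p=w / w.sum())
            for axis, p in enumerate(pos):
                out[:, p] = np.unravel_index(flat, table.shape)[axis]
        return out


def single_energy_model(
    code: RecognitionCode,
    context: LibraryContext,
    target: DnaTarget | str,
    stringency: float | None = None,
) -> EnergyModel:
    """Factorised log-weight model of one finger against a 4-mer.

    Base 1 of the 4-mer is the overlap base presented by the fixed neighbour
    context; the context term couples it with the neighbour's position-6
    residue and this finger's positions -1/2.
    """
    target = DnaTarget(str(target))
    if len(target) != 4:
        raise InputError("single-finger selections use 4-mer targets")
    beta = code.stringency if stringency is None else stringency
    bases = [BASE_INDEX[b] for b in str(target)]
    A = code.n_aa
    unary = np.zeros((6, A))
    for i in range(6):
        unary[i] = -beta * code.single_energy[i, :, bases[CONTACT_MAP[i]]]
    blocks: list[tuple[tuple[int, ...], np.ndarray]] = []
    if code.context_strength > 0:
        r6 = int(code.aa_index(context.neighbor_p6)[0])
        ctx = code.context_strength * code.context_energy[r6, bases[0]]  # (A, A)
        table = unary[0][:, None] + unary[2][None, :] - beta * ctx
        unary[0] = 0.0
        unary[2] = 0.0
        blocks.append(((0, 2), table))
    return EnergyModel(6, A, unary, blocks)


def _assemble_pair_model(
    code: RecognitionCode,
    unary_scale: float,
    couplings: dict[tuple[int, ...], np.ndarray],
    bases1: list[int],
    bases2: list[int],
) -> EnergyModel:
    """Build a 12-position model from scaled single energies plus coupling
    tables, using the fixed block layout {(6, 8), (11, 0, 2)}.

    ``couplings`` may address (6, 8), (11, 0, 2) and (0, 2); the last is
    broadcast into the (11, 0, 2) block.  With no couplings the model is
    fully additive.
    """
    A = code.n_aa
    unary = np.zeros((12, A))
    for i in range(6):
        unary[i] = -unary_scale * code.single_energy[i, :, bases1[CONTACT_MAP[i]]]
        unary[6 + i] = -unary_scale * code.single_energy[i, :, bases2[CONTACT_MAP[i]]]
    blocks: list[tuple[tuple[int, ...], np.ndarray]] = []
    if couplings:
        t68 = unary[6][:, None] + unary[8][None, :] + couplings.get((6, 8), 0.0)
        unary[6] = 0.0
        unary[8] = 0.0
        blocks.append(((6, 8), t68))
        t = (
            unary[11][:, None, None]
            + unary[0][None, :, None]
            + unary[2][None, None, :]
        )
        t = t + couplings.get((11, 0, 2), 0.0)
        if (0, 2) in couplings:
            t = t + couplings[(0, 2)][None, :, :]
        unary[11] = 0.0
        unary[0] = 0.0
        unary[2] = 0.0
        blocks.append(((11, 0, 2), t))
    return EnergyModel(12, A, unary, blocks)


def pair_selection_models(
    code: RecognitionCode,
    target: DnaTarget | str,
    anchor: LibraryContext,
) -> tuple[EnergyModel, EnergyModel, EnergyModel]:
    """(pool, joint, combined) log-weight models of a two-finger selection.

    Pair candidates are assembled from *marginally viable* single-finger
    pools -- each finger preselected against its own sub-4-mer at half the
    code stringency -- and then jointly selected at the other half, so the
    marginal statistics of a context-free code match single selections run
    at full stringency.

    Helix indices 0-5 are finger1 on bases 4-7 (overlap = shared base 4),
    indices 6-11 are finger2 on bases 1-4.  In the joint round finger2's
    position-6 residue is the neighbour presented to finger1's positions
    -1/2 at the shared base; finger2's own overlap (base 1 of the 7-mer) is
    always coupled with the fixed ``anchor`` context.  During pool selection
    finger1's environment is likewise the anchor.  The *combined* model
    (pool prior times joint survival) is the distribution of selected pairs.
    """
    target = DnaTarget(str(target))
    if len(target) != 7:
        raise InputError("pair selections use 7-mer targets")
    half = code.stringency / 2.0
    sub1, sub2 = target.subtargets()  # bases 4-7, bases 1-4
    bases1 = [BASE_INDEX[b] for b in str(sub1)]
    bases2 = [BASE_INDEX[b] for b in str(sub2)]
    pool_c: dict[tuple[int, ...], np.ndarray] = {}
    joint_c: dict[tuple[int, ...], np.ndarray] = {}
    if code.context_strength > 0:
        r6 = int(code.aa_index(anchor.neighbor_p6)[0])
        s = code.context_strength
        anchor2 = -half * s * code.context_energy[r6, bases2[0]]  # (A, A)
        anchor1 = -half * s * code.context_energy[r6, bases1[0]]  # (A, A)
        c4 = BASE_INDEX[target.overlap_base]
        inter = -half * s * code.context_energy[:, c4]  # (A, A, A)
        pool_c = {(6, 8): anchor2, (0, 2): anchor1}
        joint_c = {(6, 8): anchor2, (11, 0, 2): inter}
    pool = _assemble_pair_model(code, half, pool_c, bases1, bases2)
    joint = _assemble_pair_model(code, half, joint_c, bases1, bases2)
    comb_c: dict[tuple[int, ...], np.ndarray] = {}
    if code.context_strength > 0:
        comb_c = {
            (6, 8): pool_c[(6, 8)] + joint_c[(6, 8)],
            (0, 2): pool_c[(0, 2)],
            (11, 0, 2): joint_c[(11, 0, 2)],
        }
    combined = _assemble_pair_model(code, 2 * half, comb_c, bases1, bases2)
    return pool, joint, combined


def pair_energy_model(
    code: RecognitionCode,
    target: DnaTarget | str,
    anchor: LibraryContext,
) -> EnergyModel:
    """The combined (pool prior x joint survival) model whose marginals are
    the ground-truth pair PWM."""
    return pair_selection_models(code, target, anchor)[2]


# ---------------------------------------------------------------------------
# Selection simulation
# ---------------------------------------------------------------------------


def _attach_reads(
    survivors: np.ndarray,
    alphabet: str,
    params: SimulationParams,
    rng: np.random.Generator,
    pair: bool,
) -> list[SelectionRecord]:
    """Aggregate survivor draws into records with NNS encodings and reads."""
    if len(survivors) == 0:
        return []
    seqs: dict[str, int] = {}
    for row in survivors:
        s = "".join(alphabet[i] for i in row)
        seqs[s] = seqs.get(s, 0) + 1
    records = []
    n_enc_support = np.arange(1, len(params.n_encodings_dist) + 1)
    for seq, copies in seqs.items():
        # residues with the invariant +4 leucine restored, per finger
        fingers = [seq[:6], seq[6:]] if pair else [seq]
        full = "".join(f[:4] + "L" + f[4:] for f in fingers)
        n_enc = int(rng.choice(n_enc_support, p=params.n_encodings_dist))
        encodings: set[str] = set()
        for _ in range(4 * n_enc):
            if len(encodings) >= n_enc:
                break
            enc = "".join(
                nns_codons(a)[rng.integers(len(nns_codons(a)))] for a in full
            )
            encodings.add(enc)
        enc_list = sorted(encodings)
        total = max(1, int(rng.poisson(params.read_depth))) * copies
        split = rng.multinomial(total, np.full(len(enc_list), 1.0 / len(enc_list)))
        counts = {e: int(c) for e, c in zip(enc_list, split) if c > 0}
        if not counts:
            counts = {enc_list[0]: total}
        records.append(
            SelectionRecord(
                helix_or_pair=(
                    HelixPair.from_string(seq) if pair else CoreHelix(seq)
                ),
                encoding_counts=counts,
            )
        )
    return records


def _simulate(
    survivor_model: EnergyModel,
    acceptance: float,
    params: SimulationParams,
    rng: np.random.Generator,
    alphabet: str,
    pair: bool,
    escapee_model: EnergyModel | None = None,
) -> list[SelectionRecord]:
    """Draw survivors of a selection.

    A plated candidate survives with probability
    ``escapee_rate + (1 - escapee_rate) * acceptance-weighted Boltzmann
    survival``.  Instead of rejection-sampling ``n_candidates`` cells, the
    number of Boltzmann survivors and escapees are drawn from the matching
    binomials and the survivors themselves from the exact conditional
    distributions -- an equivalent but tractable scheme.  Escapees are drawn
    from ``escapee_model`` (the candidate prior) or uniformly when the
    candidates themselves are uniform.
    """
    eps = params.escapee_rate
    n = params.n_candidates
    n_binders = rng.binomial(n, (1.0 - eps) * acceptance) if n > 0 else 0
    n_escapees = rng.binomial(n, eps) if n > 0 else 0
    cap = params.max_survivors
    if cap is not None and n_binders + n_escapees > cap:
        # only `cap` colonies are picked; survivors are exchangeable, so the
        # picked binder count is hypergeometric
        n_binders_new = rng.hypergeometric(n_binders, n_escapees, cap)
        n_escapees = cap - n_binders_new
        n_binders = n_binders_new
    binders = survivor_model.sample(rng, int(n_binders))
    if escapee_model is None:
        escapees = rng.integers(
            0, survivor_model.n_aa, size=(int(n_escapees), survivor_model.n_positions)
        )
    else:
        escapees = escapee_model.sample(rng, int(n_escapees))
    survivors = np.concatenate([binders, escapees], axis=0)
    return _attach_reads(survivors, alphabet, params, rng, pair)


def simulate_single_selection(
    code: RecognitionCode,
    context: LibraryContext,
    target: DnaTarget | str,
    params: SimulationParams,
) -> SelectionDataset:
    """Simulate one single-finger B1H selection against a 4-mer target."""
    target = DnaTarget(str(target))
    model = single_energy_model(code, context, target)
    rng = _rng(params.seed, 1, _target_tag(target), _context_tag(context))
    records = _simulate(
        model, model.mean_acceptance(), params, rng, code.alphabet, pair=False
    )
    return SelectionDataset(
        target=target,
        records=records,
        context=context,
        metadata={"kind": "single", "seed": params.seed},
    )


def simulate_pair_selection(
    code: RecognitionCode,
    target: DnaTarget | str,
    params: SimulationParams,
    anchor: LibraryContext | None = None,
) -> SelectionDataset:
    """Simulate one two-finger B1H selection against a 7-mer target.

    Candidate pairs are assembled from marginally viable single-finger
    pools; joint survival uses the two fingers' energies plus the context
    coupling at the shared base-4 overlap (see
    :func:`pair_selection_models`).  ``anchor`` is the fixed finger pair
    that positions the library pair (defaults to :func:`default_anchor`).
    Escapees of the joint round are pool pairs, drawn from the pool prior.
    """
    target = DnaTarget(str(target))
    anchor = anchor or default_anchor(code)
    pool, joint, combined = pair_selection_models(code, target, anchor)
    # mean joint-round survival over pool draws
    acceptance = float(
        np.exp(combined.log_partition() - pool.log_partition() - joint.max_logw())
    )
    rng = _rng(params.seed, 2, _target_tag(target))
    records = _simulate(
        combined, acceptance, params, rng, code.alphabet, pair=True,
        escapee_model=pool,
    )
    return SelectionDataset(
        target=target,
        records=records,
        library_id="pair-pool",
        metadata={"kind": "pair", "seed": params.seed},
    )


def ground_truth_pwm(
    code: RecognitionCode,
    context: LibraryContext,
    target: DnaTarget | str,
) -> np.ndarray:
    """Exact per-position residue distribution of Boltzmann survivors of a
    single-finger selection (``(6, A)``, rows sum to 1)."""
    return single_energy_model(code, context, target).marginals()


def ground_truth_pair_pwm(
    code: RecognitionCode,
    target: DnaTarget | str,
    anchor: LibraryContext | None = None,
) -> np.ndarray:
    """Exact ``(12, A)`` survivor distribution of a pair selection."""
    anchor = anchor or default_anchor(code)
    return pair_energy_model(code, target, anchor).marginals()


# ---------------------------------------------------------------------------
# Library-context helpers
# ---------------------------------------------------------------------------


def _target_tag(target: DnaTarget) -> int:
    tag = 0
    for b in str(target):
        tag = tag * 4 + BASE_INDEX[b]
    return tag + 7


def _context_tag(context: LibraryContext) -> int:
    return sum(ord(c) for c in context.library_id) + 13


def default_anchor(code: RecognitionCode) -> LibraryContext:
    """The fixed anchor context used by pair selections."""
    helix = CoreHelix((code.alphabet * 6)[:6])
    return LibraryContext("anchor", (helix,), overlap_base="A")


def sample_pair_targets(seed: int, n: int) -> list[str]:
    """``n`` distinct random 7-mer targets (production-scale campaigns
    screen a couple of hundred of the 16384 possible 7-mers)."""
    rng = _rng(seed, 0x7E7)
    targets: set[str] = set()
    while len(targets) < n:
        targets.add("".join("ACGT"[i] for i in rng.integers(0, 4, 7)))
    return sorted(targets)


def simulate_single_campaign(
    code: RecognitionCode,
    contexts: list[LibraryContext],
    params: SimulationParams,
    triplets: list[str] | None = None,
) -> list[SelectionDataset]:
    """One single-finger selection per (library context, 3-mer target);
    the 4-mer screened is the library's overlap base plus the triplet."""
    from itertools import product

    triplets = triplets or ["".join(p) for p in product("ACGT", repeat=3)]
    out = []
    for context, triplet in product(contexts, triplets):
        target = context.overlap_base + triplet
        out.append(simulate_single_selection(code, context, target, params))
    return out


def simulate_pair_campaign(
    code: RecognitionCode,
    targets: list[str],
    params: SimulationParams,
    anchor: LibraryContext | None = None,
) -> list[SelectionDataset]:
    """One two-finger selection per 7-mer target."""
    return [
        simulate_pair_selection(code, t, params, anchor=anchor) for t in targets
    ]


def make_library_contexts(code: RecognitionCode, n: int = 6) -> list[LibraryContext]:
    """A panel of ``n`` library contexts with varied overlap side chains and
    overlap bases (A/C/G -- T is not sampled at the overlap, matching the
    design of real single-finger libraries)."""
    rng = _rng(code.seed, 0x11B)
    out = []
    bases = "ACG"
    for i in range(n):
        residues = "".join(code.alphabet[j] for j in rng.integers(0, code.n_aa, 6))
        out.append(
            LibraryContext(
                library_id=f"L{i + 1}",
                fixed_helices=(CoreHelix(residues),),
                overlap_base=bases[i % 3],
            )
        )
    return out
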