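# Methods

This note documents the models, conventions and numerical choices behind
`zfhelix`, and what the synthetic test harness does and does not show.

## The design problem

A Cys2His2 zinc finger reads roughly three base pairs of DNA through six
designable residues at recognition-helix positions −1, 1, 2, 3, 5 and 6
(position +4 is an invariant leucine).  Adjacent fingers are not
independent: the side chain at position 6 of the N-terminal-neighbouring
finger sits within hydrogen-bonding distance of positions −1/2 of the next
finger, at a shared *overlap base*.  A practical design model therefore has
to learn both per-finger base recognition and inter-finger compatibility.

Throughout the package a finger's nucleotide sub-target is written 5′→3′ as
a 4-mer `[overlap, t1, t2, t3]`: base 1 is the overlap base presented by
the neighbouring environment and bases 2–4 are the finger's triplet.  A
two-finger target is a 7-mer whose base 4 is shared between the two
sub-4-mers (bases 1–4 and bases 4–7).  The finger on bases 4–7 (called
`finger1`, handled by model module 1) receives the overlap environment
through its positions −1/2; the finger on bases 1–4 (`finger2`, module 2)
contributes its position-6 residue at the shared base.  Published
structural conventions label the contributing and receiving fingers
N-terminal and C-terminal respectively; the package avoids protein-side
labels in code because only the contact roles, not the labels, enter any
computation.

## Synthetic selection simulator

Real selection data are available only under a material-transfer
agreement, so the package ships a statistical stand-in with a known ground
truth.  A *recognition code* assigns to each helix `h` against 4-mer `t`
an energy

    E(h, t) = Σ_p E1[p, h_p, t_contact(p)] + γ · C[r6, t_overlap, h_-1, h_2]

where `E1` is a 6 × 20 × 4 table of i.i.d. standard-normal energies
(positions −1/1 contact triplet base 1, positions 2/3 base 2, positions
5/6 base 3), `C` is a 20 × 4 × 20 × 20 coupling between the neighbour's
position-6 residue `r6`, the overlap base, and this helix's positions
−1/2, and `γ ≥ 0` is the context strength.  At `γ = 0` pair energies are
exactly additive over fingers.

A plated candidate survives selection with probability
`ε + (1 − ε)·exp(−β (E − E_min))`, with stringency `β` (inverse
temperature, default 2.0 — chosen so that survivor distributions have the
high per-position information content of successful selections) and
escapee rate `ε` (default 5 × 10⁻⁸ per cell, giving tens of escapees per
5 × 10⁸ plated cells).  Because the couplings touch small disjoint groups
of positions, the survivor distribution factorises into independent
categorical factors; the package exploits this to compute exact
ground-truth PWMs, exact mean acceptance probabilities, and to draw
survivors directly from the conditional distribution instead of
rejection-sampling billions of candidates.  The number of Boltzmann
survivors and escapees are drawn from the corresponding binomials, and a
`max_survivors` cap models finite colony picking/sequencing depth
(hypergeometric subsampling, unbiased).

Two-finger selections mirror the experimental two-round procedure: pair
candidates are assembled from *marginally viable* single-finger pools
(each finger preselected against its own sub-4-mer at stringency β/2) and
then jointly selected at the other β/2, with the inter-finger coupling
active only in the joint round.  For a context-free code the combined
statistics match single selections at full stringency, which is what makes
the additive control (below) a fair comparison.  The combined
pool-times-survival distribution is again factorised, so pair ground-truth
PWMs are exact.

Recovered helices are emitted as records with synonymous NNS-codon
encodings (third base G/C; the invariant leucine restored at position +4)
and Poisson read counts — the raw material for the read filters.

A separate deterministic variant (`sample_deterministic_code`) lowers each
(position, base) energy minimum well clear of the runner-up, so that at
high stringency every selection recovers exactly one helix.  This is the
learnable-by-construction fixture behind the reconstruction-accuracy
checks.

The simulator is a statistical test harness, not a physical model: no
structure, no solvent, no affinity scale, no sequencing error beyond what
the filters are designed to absorb.  Passing tests show the pipeline
recovers a *known* nonlinear recognition code with neighbour-context
effects; they say nothing about the accuracy of any particular published
code on real selection data.

## Read recovery and filters

Reads are demultiplexed by exact 5′ barcode match and trimmed to 21-mer
inserts; 21-mers are translated under the standard genetic code, the
position +4 residue is dropped, and synonymous encodings are aggregated
per helix.  In-frame stops and non-ACGT symbols reject an encoding; NNS
violations only warn (sequencing error can produce them).

Two filters operate on records:

* **basic filter** — keep helices with ≥ 2 total reads *and* ≥ 2 distinct
  encodings;
* **entropy filter** (training-data grade) — keep helices with ≥ 10 reads
  and encoding-read Shannon entropy ≥ 0.07.

The entropy convention is a genuinely open choice (the defining prior work
does not restate it): the package computes entropy in bits over the
observed encodings and, by default, normalises by log₂ of the number of
possible NNS encodings of that helix, giving a [0, 1] statistic comparable
across helices of different codon degeneracy.  Raw bits are available via
`normalized=False`.  Note that because the invariant leucine always has
three NNS codons, no helix has fewer than three possible encodings.

## Selection analytics

**Mixture of PWMs.**  Multi-specificity clustering is an EM fit of a
mixture of product-multinomial PWMs with read-count weights, pseudocount
0.5, and by default 20 seeded random restarts; hard assignment is by
maximum responsibility (ties to the lowest component index).  The stored
objective trace is the weighted log-likelihood *plus the pseudocount
(Dirichlet) prior* on the PWMs — the quantity EM provably increases
monotonically; with a pseudocount the raw likelihood alone need not be
monotone.  `k = "auto"` selects the component count by BIC with the total
read weight as the effective sample size.  Selection QC passes a selection
iff some cluster has some position with entropy ≤ 2 bits (equivalently,
information content ≥ log₂20 − 2 there), and reports the maximum
information content at one position of the strongest cluster.

**Library comparison.**  For helix sets A and B, the distance is the
pooled mean of all |A| + |B| directed minimum normalized Hamming
distances.  Whether real analyses deduplicate helices or weight them by
reads is unstated in the defining work; the default is deduplicated and
unweighted, with `deduplicate=False` plus weight vectors available.

**Promiscuity.**  For each 3-mer, the 3-mers bound by every core-residue
set (positions −1, 2, 3, 6) recovered against it are pooled into a
position frequency matrix; entropy is computed per position in bits and
summed (0 = perfectly specific, 6 = uniform over all 64 triplets).

**8-bp specificity libraries.**  Three filters in order: drop 8-mers with
< 10 total reads; drop 8-mers on a single unique plasmid; if the plasmid
read distribution of an 8-mer has normalized entropy < 0.1, drop the
dominant plasmid's reads (escapee suppression) and re-apply the read
floor (on by default — an 8-mer rescued only by escapee reads should not
survive).  Plasmid entropy is bits normalized by log₂(number of observed
plasmids); the base and normalization are configurable because the
defining threshold's convention is unstated.  Under this convention a
98/2 split across two plasmids (normalized entropy ≈ 0.14) is *kept*;
only more extreme skews trigger the drop.  Surviving totals are divided by
the background-library frequency and clustered into two nucleotide motifs.

## The hierarchical model

The network has three modules.  Each *single-helix module* is a small
encoder–decoder transformer: the encoder builds a representation of each
base of a 4-mer with repeated self-attention; the decoder runs repeated
self-attention over the six (partially masked) residue tokens,
cross-attention onto the base representations, and a position-wise
feedforward layer.  Decoding is fully bidirectional — masked positions are
marked with a dedicated mask token in the input vocabulary and attention is
unmasked.  Learned positional embeddings are used for both bases and
residues (sequences are tiny and fixed-length).  The *pair-compatibility
module* takes the two single modules' residue embeddings, concatenated to
12 positions with their own learned positional embedding, and refines them
with repeated self-attention + feedforward blocks before a linear head
produces 20-way residue distributions.  Output heads are zero-initialised
so an untrained model predicts exactly the uniform distribution (masked
cross-entropy starts at ln 20).

Full-scale defaults mirror the production regime: d_model = 128, 4 heads
per attention layer, every block repeated three times, d_k = d_v = 256,
feedforward width 128, dropout 0.3 after every attention and feedforward
layer; Adam at learning rate 10⁻⁴ with minibatch 128 and 50 % residue
masking.  All desk-scale experiments and tests use `ModelConfig.toy()`
(d_model 32, 2 heads, 1 repeat, d_k = d_v = 16, feedforward 64) with
learning rate 3 × 10⁻³, minibatch 512 and dropout 0.1 for generalisation
experiments — sizes chosen so a full experiment trains in about two
minutes on one CPU.

The engine underneath is a reverse-mode autograd over numpy arrays written
for this package; with 4–12-token sequences the arithmetic is far below
the scale where specialised frameworks matter.

**Training.**  Cross-entropy is evaluated at masked positions only; exactly
`round(fraction × length)` positions are masked per example (floored at
one).  Early stopping tracks validation loss each epoch with patience 5
(default) and restores the parameters at the minimum, not the last
iterate.  Pretraining splits examples by helix sequence; pair training
splits by target with the dissimilarity graph: targets are nodes, edges
connect 7-mers within two substitutions, components disjoint from the main
component go to validation first, then lowest-degree nodes *together with
their whole neighbour unit* until the 10 % proportion is reached.  Units
are never truncated — near-duplicate targets must not straddle the split —
so the proportion is honoured approximately from below; in the degenerate
complete-graph case the entire unit (all targets) lands in validation, and
training then fails loudly on an empty training set rather than silently
leaking neighbours.

The pair model's lower modules can be randomly initialised, transferred
from pretraining, or transferred and frozen; frozen parameters are
excluded from the optimizer and verified bit-identical after training.

**Generalisation regime.**  Desk-scale experiments train on ~200 random
7-mer targets with ~40–60 filtered pairs each.  With many fewer targets
(≈ 50) the toy model memorises target identity instead of learning the
compositional base→residue code and fails on held-out targets — the same
data-diversity requirement, at much smaller scale, as production-size
campaigns that screen a couple of hundred targets.

## Design engine

**A\*.**  Partially masked sequences are kept on a priority queue with
priority `Σ_i log p_i + (L − j) log p*` (natural logarithms; `p*` is the
expected maximum probability of future predictions, 0.1 in production
use).  Each pop runs the model once on the whole partial sequence and
expands every (masked position, label) with probability above 0.05.  The
same partial sequence is reachable through many generation orders, so an
expanded-state closed set deduplicates states; because the queue is popped
best-first this keeps the best-priority path to each state.  With
`p* = 1` the heuristic is admissible (future log-probabilities are ≤ 0)
and the first completed sequence is provably the exact argmax of path
probability, which the tests verify against exhaustive enumeration.  Ties
break FIFO by insertion order; the queue is capped (default 10⁶) with
worst-priority eviction.

**Temperature sampling.**  At each of L iterations the joint distribution
over all remaining (masked position, residue) choices is formed by raising
each model probability to 1/T and normalizing over both indices jointly —
the literal form of the production equation; one choice is drawn and
fixed.  Whether production sampling renormalises per position or jointly
is not fully specified; the joint form is the default and the 12
sequential draws cover the remaining masked positions.  T = 1 recovers the
raw distribution as an algebraic identity; T → 0 concentrates on the
argmax.  Among the sampled pairs the best is selected by
pseudolog-likelihood (default) or by generation-path log-probability.

**Specificity.**  The pseudolog-likelihood of a pair against a 7-mer is
the sum over the 12 residues of log P(residue | target, all other
residues), computed by masking one position at a time (batched across all
16 384 7-mers).  The scores are normalized into a distribution by softmax
(default) or shift-and-scale; softmax is the default because it is the
unique choice that treats the pseudolog-likelihood as a log-score and is
invariant to additive constants.

**Baseline.**  The concatenated single-finger baseline designs each finger
independently from its sub-4-mer with the pretrained single modules
(greedy decoding for a single pair; temperature sampling at T = 1 for a
PWM) and concatenates.  A 6-mer target is promoted to a 7-mer by prefixing
a fixed `A` environment base.  This baseline captures everything except
inter-finger compatibility, which is exactly what the hierarchy-value
comparison isolates: with context coupling on, the full model's
predicted-PWM MSE against the exact ground truth beats the baseline on
held-out targets; with coupling off, both reduce to the same additive
problem and the gap sits inside seed-to-seed noise.

## Numerical conventions and degenerate inputs

* Natural logarithms in the A* priority and the temperature exponent;
  bits in all sequence-entropy statistics.
* PWM rows (per-position distributions) are normalized before MSE.
* EM ties in hard assignment break to the lowest component index; argmax
  ties in energy models break to the lowest residue index.
* Empty candidate pools simulate to empty datasets without error; empty
  training or validation sets raise input errors.
* All randomness flows from integer seeds through `numpy` seed sequences
  split per purpose; identical seeds give bitwise-identical codes,
  datasets, masks and training trajectories.

## Known limitations

* The synthetic code has one coupling term; real neighbour effects are
  richer (multiple contacts, backbone geometry, position-5 effects), so
  relative comparisons (full vs baseline) are meaningful but absolute
  accuracies on synthetic data do not transfer to real selections.
* The toy-scale model is far below production capacity; reported
  reconstruction accuracies on synthetic data are not comparable to
  accuracies achievable on MTA-gated selection data.
* The simulator draws escapees uniformly from candidates and treats read
  depth as Poisson per helix; PCR jackpotting, chimeras and sequencing
  error are not modelled.
* Finger-array assembly beyond one pair (6–8-finger proteins, linker
  registers) is out of scope.
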