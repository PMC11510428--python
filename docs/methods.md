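# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `azogen`. Nothing here states an empirical number that the
test suite or `scripts/acceptance.py` does not itself compute.

## The structural photoswitch criterion

The chemist criterion targets the azo photoswitch motif. Two variants
operate on the parsed molecular graph:

- **relaxed** — some bond joins two nitrogen atoms and that *bond* lies
  on no ring (the atoms may individually be ring members: an exocyclic
  N–N bond counts). Any bond order qualifies.
- **strict** — additionally the bond is a localized, non-aromatic double
  bond: -N=N-, the unit that actually photoisomerizes.

"Acyclic" qualifies the bond rather than the atoms because a ring-locked
N=N cannot rotate; aromatic N–N bonds (e.g. pyrazole) are excluded from
strict mode for the same reason. Strict ⊆ relaxed by construction.

## Synthetic corpora

No public corpus ships with the package; a generator emulates the two
training regimes.

- **Pretraining set** (default n = 2000, 4–16 heavy atoms over a
  carbon-weighted C/N/O/S/Cl/F alphabet): molecules are built as random
  spanning trees under per-element valence caps, with at most one ring
  closure and stochastic bond-order upgrades, then sanitized and
  canonicalized. Every emitted string is valid by construction — the
  generator never rejection-samples against a parser. The 4–16 range is
  a desk-scale choice: large enough that byte-pair statistics are
  non-trivial and the ≤7-atom subset is a strict subset, small enough
  that sequences stay short for a 64-token context.
- **Motif injection**: a seeded Bernoulli(motif_fraction) decides per
  molecule whether a pendant N–N unit (70% N=N, 30% N–N) is attached
  outside any ring, making the relaxed criterion true by construction;
  non-motif molecules are built with no N–N adjacency at all, making it
  false by construction. The default motif_fraction of 0.05 keeps the
  motif rare, as in general-purpose corpora.
- **Fine-tuning subset**: molecules with ≤7 heavy atoms drawn from
  {C, N, O, S, Cl} — the defining constitution of the QM7b-style
  small-molecule sets. Quantum-chemical property labels are not
  emulated; the fine-tuning objective is sequence likelihood only.

What the generator does *not* emulate: realistic functional-group
statistics, aromatic ring systems beyond what random closure produces,
stereochemistry, charge states, or the property distributions of real
screening libraries. Tests passing on this corpus demonstrate that the
*pipeline machinery* behaves as specified, not that the models would
reach any particular quality on PubChem-scale data.

## Tokenizer

Byte-pair encoding over a versioned 72-character alphabet (26 uppercase
letters, 26 lowercase, 10 digits, and `()[]=#+-/\`). Training merges the
most frequent adjacent pair; ties break lexicographically on the
concatenated pair string, so training is deterministic across platforms.
The printed tokenizer size is |alphabet| + |merges| = 72 + 1000 = 1072 at
the default budget; BOS/EOS/PAD are tracked separately and not counted.
Encoding applies merges in training order; decode∘encode is the identity
on any string over the alphabet.

The *pipeline* trains its sequence model on a 50-merge tokenizer rather
than the 1000-merge default. At a 2,000-molecule scale, heavy BPE turns
whole molecules into single rare tokens, which measurably lowers the
validity of sampled SMILES; near-character granularity gives the small
model enough signal per token and keeps the N–N motif localized to a
short token pattern, which also benefits preference transfer (below).

## Sequence model

One generic decoder-only attention architecture (token + learned position
embeddings; pre-LayerNorm blocks of multi-head causal self-attention and
a 4×-width GELU MLP; final LayerNorm and linear head), implemented in
numpy with manual backpropagation and verified against finite differences
in the test suite. Default desk-scale configuration: 2 layers, 128
dimensions, 4 heads, context 64 — it trains in minutes on one CPU while
exercising every pipeline stage. Optimization is AdamW (decoupled weight
decay on matrices only, gradient-norm clipping at 1.0) with cosine
annealing from 5·10⁻⁴ to 5·10⁻⁸; fine-tuning restarts the schedule from
2·10⁻⁴. Pretraining runs 16 epochs and fine-tuning 8 at batch 64 — past
that, sample validity gains flatten at this corpus size.

Sampling is ancestral from BOS with temperature 1.0 by default (greedy
at temperature 0), using a per-layer KV cache, deterministic given the
seed. Unparseable samples are counted in the generation report, never
raised.

A capacity note encoded in the tests: when a model memorizes k distinct
sequences, ln k nats of choice entropy are irreducible, so per-token NLL
can only approach ln k / (mean sequence length). The memorization test
therefore uses the character-level tokenizer and long strings, putting
the floor (~0.07 nats/token) below its 0.1-nat bound.

## Instruction training (DPO + LoRA)

Preference pairs encode the criterion: chosen = a valid sampled molecule
satisfying the relaxed criterion, rejected = a valid one that does not;
prompts are empty (the preference is over unconditional completions).
Pairs are drawn with replacement from a 2,000-sample generation pool —
at a ~5% positive rate, a 500-sample pool would carry only ~20 unique
positives, and the policy then memorizes them instead of generalizing to
the motif.

The loss is −log σ(β·margin) with margin = (chosen log-ratio − rejected
log-ratio) against a frozen reference (the fine-tuned checkpoint), with
length-unnormalized sequence log-probabilities. β defaults to 0.1, the
cited method's convention. Only low-rank adapters train: ΔW = A·B with
A ∼ N(0, 1/r) and B = 0 at initialization (the adapted model starts
exactly equal to the base) on the query/key/value/output projections,
rank 8 by default. Reference per-pair log-probabilities are precomputed
once; the base weights are bit-identical after training.

The DPO learning rate is the critical stability parameter. This
objective, optimized unconditionally, has a documented failure mode: the
margin grows mostly by pushing the *rejected* side down, which drags the
whole generative distribution off-manifold — at learning rates ≥10⁻⁴ the
final loss falls below 0.2 while sample validity collapses toward zero.
At the default 3·10⁻⁵ (AdamW, batch 64, 300 steps, cosine decay to 1%)
the loss converges to ≈0.5 and fresh samples stay fluent while the
criterion rate rises severalfold. The acceptance suite measures exactly
this: pooled over three seeds, the relaxed-criterion rate of 500 fresh
samples before vs after DPO, compared with a one-sided two-proportion
z-test at p < 0.01.

## Screening

**QED** is the geometric mean (unit weights) of eight desirability
values, each an asymmetric double sigmoid of one descriptor (MW, ALOGP,
HBA, HBD, PSA, ROTB, AROM, ALERTS) with the published parameter table
shipped as constants and desirabilities floored at 10⁻⁶ before the log.
Descriptor values come from the cheminformatics backend; the test suite
cross-checks the whole path against the backend's own unit-weight QED to
10⁻⁶ on the packaged fixture.

**SA score**: fragment contributions are the centered log relative
frequencies of radius-≤2 circular environments counted over the
package's own reference corpus (provenance hash recorded; fragments
never seen get the table floor − 1 nat). The raw score is the
count-weighted mean fragment contribution minus a complexity penalty
(size: n^1.005 − n; 2·log₁₀(spiro+1); 2·log₁₀(bridgeheads+1); log₁₀2 for
a macrocycle), mapped affinely onto [1, 10] (anchors 2.5 → 1, −6.5 → 10)
and clamped. `sa_raw` = 1 means easiest, following the cited method; the
opposite orientation (higher = easier) is carried explicitly as
`sa_ease` = 11 − `sa_raw` rather than silently flipped. Because the
fragment table comes from the synthetic corpus rather than a historical
reaction database, absolute values are calibrated only relative to this
corpus; orderings of simple-vs-complex structures are the meaningful
output.

**Shortlists** sort descending by QED, sa_ease, or PageRank, with ties
broken lexicographically by canonical SMILES for determinism.

## Recommendation

Features = Morgan fingerprint bits (radius 2, 256 bits by default,
element-level initial atom invariants) concatenated with z-scored
descriptor columns (constant columns dropped). The similarity graph is
the cosine of mean-centered PCA projections (components covering 95%
variance by default), clipped into [−1, 1] with diagonal 1 — cosine of
centered features is the standard similarity with that exact range,
whereas Tanimoto lives in [0, 1]. t-SNE is available for visualization
only and never enters the adjacency: a stochastic embedding inside the
ranking would break determinism.

PageRank clips negative weights to zero for the transition matrix
(dissimilarity should carry no recommendation flow; the absolute-value
alternative was rejected because it would reward dissimilarity),
row-normalizes, replaces dangling rows with the uniform distribution
over the *other* nodes (a molecule never recommends itself — this also
makes a fully-dissimilar node receive exactly the teleport mass
(1−d)/n), and power-iterates with damping 0.85 to an L1 tolerance of
10⁻¹⁰ (max 1000 iterations, flagged if not converged). Scores are
normalized to sum to 1. An independently coded power iteration serves as
the test oracle.

## Determinism and numerics

Every stochastic step takes an explicit seed (numpy Generator); corpora,
training traces, samples and t-SNE maps are bit-reproducible given the
seed on a fixed platform. Model arithmetic is float32 with float64
log-sum-exp for likelihoods; the gradient check runs in float64.
Degenerate inputs are contracts, not crashes: empty corpora warn, a
molecule set with fewer than two members refuses feature construction,
unparseable lines in input files are collected and reported, and a
non-finite training loss aborts with the step and learning rate.

## Known limitations

- The LM is orders of magnitude smaller than the production-scale
  architectures it stands in for; absolute sample quality is bounded by
  the synthetic corpus, and architecture identity (sparse attention
  variants etc.) is deliberately out of scope.
- Quantum chemistry is out of scope: no excitation energies, no
  photoisomerization surfaces. The criterion is structural only.
- Stereochemistry is parsed but ignored (no stereo-aware
  canonicalization or stereo complexity term in SA).
- The SA fragment table inherits the biases of the corpus it is built
  from; scores are not comparable across tables.
- Unconditional DPO remains sensitive to over-optimization; the shipped
  defaults are calibrated for the desk-scale configuration and should be
  revisited if the model or corpus size changes materially.
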