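# Methods

`dnaclr` implements species-aware DNA embedding learning by curriculum
contrastive training, together with the descriptive baselines and the
evaluation stack used to judge any embedding of anonymous DNA fragments:
species clustering, metagenomics binning, and few-shot classification. This
note records the model, the defaults and why they are what they are, the
numerical choices, and the limits of what the synthetic experiments show.

## The training objectives

A training example is a positive pair (x_i, x_i+): two non-overlapping
fragments of the same genome. The encoder f maps a fragment to a fixed-size
embedding (mean pooling of the last-layer hidden states over tokens). Batches
hold B pairs.

**Weighted SimCLR (phase I).** For anchor x_i, every other sample in the
batch except its positive is a negative. Each negative x_j is reweighted by

    α_ij = exp(s_ij/τ) / [ (1/(2B−2)) Σ_{k≠i,i+} exp(s_ik/τ) ],

with s the cosine similarity and τ the temperature; by construction the mean
of α over the 2B−2 negatives is exactly 1, and the positive keeps weight
α_ii+ = 1. The per-anchor loss is the negative log of the positive term over
the α-weighted sum over all j ≠ i; the batch loss averages both directions
(x_i and x_i+ as anchors) over all 2B anchors. Hard negatives (closer to the
anchor) therefore repel more strongly. Because the weighted denominator is
not a true probability normalizer, the per-anchor loss is not guaranteed
non-negative; the invariants we test are finiteness, the mean-1 weight
normalization, and monotone decrease as the positive similarity rises.

**MI-Mix (phase II).** For each step, a single layer m is drawn uniformly
from the eligible set S, per-anchor mixing weights λ_i ~ Beta(α, α), and a
uniform permutation over the batch. Anchors are run to layer m, their hidden
states mixed token-wise, h_i^m = λ_i g_m(x_i) + (1−λ_i) g_m(x̂_i), then run
through the remaining layers. The virtual label mixes the same way,
v_i^mix = λ_i v_i + (1−λ_i) v̂_i. The contrast set is restricted to the B
positives {f(x_k+)}; the negative-weight normalizer averages over the B−1
indices k ≠ i, α_ii+ = 1, and the per-anchor loss is the cross-entropy of
the weighted softmax against v_i^mix. The label index of the shuffled
partner keeps its computed α weight in the denominator. i-Mix is the same
construction with m fixed at 0, our convention for "immediately after the
token/position embedding", so input-level instance mixup and manifold mixup
share one code path.

**Curriculum (C²LR).** Phase I runs Weighted SimCLR for `phase1_epochs`
(default 1), phase II runs MI-Mix for `phase2_epochs` (default 2): anchors
become progressively harder. The ablation harness trains the single-loss
schedules (simclr_only, mimix_only, imix_only) and the curriculum with i-Mix
in phase II, on identical data, seed, and hyperparameters.

Reference constants kept as defaults: τ = 0.05, Beta concentration α = 1.0
(so λ is uniform on [0,1]), batch size 48, Adam with learning rate 3e-6,
checkpoint every 10000 steps with minimum-validation-loss selection. Those
optimization constants were tuned for a ~100M-parameter pretrained backbone;
`TrainConfig.desk()` substitutes sizes honest for the small randomly
initialized encoder shipped here (batch 8, lr 1e-3 order, validation every
~100 steps). Validation in phase II uses the phase-II objective, with the
mixup randomization drawn from a fixed stream so successive validations are
comparable; which loss should validate phase II was an open choice and this
is the one we made.

## Encoder

A pre-norm transformer over non-overlapping k-mer tokens (default k = 4,
vocabulary 4^k plus PAD and UNK; k-mers containing N map to UNK; the trailing
remainder shorter than k is dropped; truncation at `max_tokens`). Learned
positional embeddings; masked attention and masked mean pooling make
embeddings invariant to padding. The split-forward contract f = f_m ∘ g_m is
exact (bitwise in eval mode) for every m, which is what MI-Mix relies on.
Package defaults are n_layers 4, hidden 128, 4 heads, max_tokens 512; the
tests use smaller instances (2 layers, width 32) that train in minutes on one
CPU core.

The engine underneath is a small reverse-mode autodiff on numpy float64
arrays (`dnaclr.autodiff`), covering exactly the ops the encoder and losses
need; gradient correctness is pinned to finite differences in the test suite.
Computation graphs are freed eagerly (`free_graph`) because backward closures
form reference cycles that the cyclic collector reclaims too slowly for
large array buffers.

**Batch-standardized loss inputs.** With a pretrained backbone, embeddings
start with meaningful, well-spread similarity structure. A small randomly
initialized encoder does not: pooled embeddings share a large common
component (every sequence's token distribution is close to the mean
composition), cosines start near 1, and the temperature-scaled objectives
stall near their indifference value log(2B−1). The desk-scale recipe
therefore standardizes each embedding dimension within the batch (mean 0,
variance 1) before computing the contrastive loss — the role the
batch-normalized projection head plays in the SimCLR lineage. This is a
training/validation-time transform only; evaluation embeddings are the raw
pooled hidden states. Set `embed_norm="none"` to disable.

## Baselines

TNF is the 256-dim frequency vector of overlapping 4-mers on the given
strand (windows containing N are skipped). TNF-K projects the mean-centered
TNF through an orthonormal basis of the null space of a linear constraint
system: strand (reverse-complement) symmetry f(m) = f(rc(m)), 3-mer overlap
consistency (each 3-mer's frequency as a 4-mer prefix equals its frequency
as a suffix), and the unit-sum constraint. The independent-constraint count
is resolved numerically by the rank of the stacked system rather than
hand-enumerated; the construction asserts the expected 103-dimensional
output. Orthonormality makes the projection non-expansive, and the symmetry
constraint makes TNF-K invariant to reverse complementation of the input.

## Evaluation stack

*Clustering.* K-means with k set to the number of species, ARI against
truth, averaged over 5 seeds (scikit-learn provides both primitives; the
test suite checks ARI against an independent contingency-table
implementation).

*Binning.* Iterative density binning on length-normalized embeddings under
cosine distance: learn a global distance threshold from a subsample of the
pairwise-distance distribution; repeatedly take the point with the most
neighbors within threshold (ties to the lowest index), re-center the medoid
within its candidate set at most `max_refine` (3) times, emit the
neighborhood as a bin, remove it; stop when the densest remaining region
holds fewer than `min_bin_size` (5) points. The default threshold rule is an
Otsu (two-class variance-minimizing) split of the distance sample: when the
embedding has cluster structure the split lands in the valley between
within-species and between-species distances. A fixed low quantile was tried
first and rejected — on separable clusters it lands deep inside the tightest
cluster and shatters it; the quantile rule remains available as
`threshold_method="quantile"`. Species recovery matches bins to species
one-to-one, greedily by descending F1 (a bin may identify at most one
species — the conservative reading of non-overlapping clusters), and counts
matched species in F1 bands from 0.5 upward.

*Few-shot probing.* Per run, 80 embeddings per species are held out for
testing; k ∈ {1, 2, 5, 10, 20} training embeddings per species are drawn
from the rest; a multinomial logistic-regression probe (L2, C = 1, fixed
iteration cap — the probe model is named in the protocol but not its
hyperparameters, so we fix them for comparability) is scored by macro F1,
averaged over 5 runs.

*Filters.* Before clustering/classification: species with fewer than 100
sequences are removed and survivors downsampled to exactly 100 (seeded).
Before binning: only sequences strictly longer than 2500 bp are kept, then
species with fewer than 10 sequences are removed.

## Synthetic communities

Each species is an order-3 Markov chain over ACGT, so 4-mer composition is
the species fingerprint — the same signal TNF reads. Species chains
interpolate row-wise between one shared base chain and independent random
chains: row = (1−w)·base + w·noise with w the `divergence` knob; w = 0 makes
species identical and the mean inter-chain distance grows monotonically
with w. Genomes are sampled from the chains; fragments are uniform
substrings with optional log-normal abundance skew and read noise (per-base
errors split 80% substitutions, 10% insertions, 10% deletions, geometric
indel lengths — a qualitative stand-in for long-read noise, not a
platform-specific error profile).

Two shipped presets bracket difficulty, both 10 species × 100 fragments of
1000 bp from 20 kb genomes (seed 2024): `easy` (divergence 0.9) — TNF
features separate species (5-shot macro F1 > 0.9); `hard` (divergence 0.12)
— TNF stays below 0.5 macro F1 at 5 shots, yet enough composition signal
remains for contrastive training to exploit. The divergence values were
calibrated once against those two TNF-separability properties. Fragment
length matters as much as divergence: composition noise scales as
1/√length, so the same divergence is far harder at 500 bp than at 1000 bp;
1000 bp is the shortest length at which the weak-TNF regime still leaves a
learnable pair signal for an encoder reading ~250 tokens.

What passing on these fixtures does and does not show: the generator's
species signal is exactly k-mer composition, which is the assumption TNF
methods make; real communities add shared mobile elements, strain-level
variation, GC covariates, and coverage signals that are absent here. Results
on the fixtures demonstrate that the training machinery optimizes the
intended objectives and that learned metrics can out-cluster raw
composition — not that the desk-scale model matches full-scale systems.

## The desk-scale learning-signal experiment

The acceptance experiment trains the small encoder (k = 4, 2 layers, width
32, 1 head, 250 tokens, no dropout) on 600 pairs of 1000 bp fragments from
the hard community's genomes, one epoch per phase (150 optimizer steps,
batch 8, lr 2e-3), five training seeds per schedule, and scores K-means ARI
(5 K-means seeds) on 50 held-out fragments per species. The trained C²LR
encoder must beat the same encoder untrained on mean ARI and stay within
0.05 of the SimCLR-only schedule. These problem sizes are the package's
chosen desk scale: small enough to run on one CPU core in minutes, large
enough that the trained/untrained gap is consistent across seeds (roughly
0.025 vs 0.009 mean ARI). The absolute ARIs are small — at this fragment
length and divergence the Bayes-achievable clustering is itself modest — so
the claim tested is strictly ordinal.

## Numerical choices and degenerate inputs

- Weighted-softmax losses subtract the per-row maximum logit (detached)
  before exponentiation; both α and the loss are invariant to the shift, so
  stabilization is exact even at τ = 0.05.
- Cosine similarity raises on zero vectors; embeddings are length-normalized
  with an ε floor inside the losses.
- Density binning breaks density ties by the lowest remaining index;
  all-identical embeddings yield one bin; fewer than `min_bin_size` points
  yield none.
- Fragment extraction places two disjoint intervals uniformly via the
  sorted-offset construction; fragments with more than 10% N are re-drawn a
  bounded number of times, then the genome is skipped.
- DNA-Mutate's 5% edit budget is read as a total over round(rate·L)
  positions, split evenly between adjacent swaps and deletions (deletions
  take the floor half); the split is configurable because only the total is
  standard.
- The reverse complement is the standard complement-then-reverse operation
  (AATTC → GAATT).
- Last incomplete training batch is dropped: the loss normalizers assume a
  fixed B.

## Known limitations

- No pretrained backbone: results quantify learning from scratch at small
  scale, not the published large-scale system.
- The autodiff engine is eager, single-threaded float64; it is sized for
  the shipped configurations, not for long-context models.
- The binning threshold is global; real binners use per-cluster and
  coverage-aware criteria.
- The dropout pair strategy degenerates at validation time (dropout off
  makes both views identical); its loss is still defined, but validation
  values for that strategy understate the training loss.
- SupCon is deliberately out of scope in the ablation arms.
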