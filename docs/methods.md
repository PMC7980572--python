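# Methods

This note records the models and procedures the package implements, the
defaults it ships, and the choices made where the design was genuinely open.

## Feature encoding

Each (ncRNA, protein) pair is encoded into two fixed-length vectors.

**Conjoint k-mer blocks.** For a sequence of length L over an alphabet of
size m, the k-mer block is the m^k-vector of sliding-window counts divided
by (L − k + 1), indexed lexicographically in the declared alphabet order
(A,C,G,U for RNA primary; S,H,M,I,B,X,E for RNA structure; groups 1–7 for
reduced protein; H,E,C for protein structure). The normalization makes each
block a probability distribution (sums to 1 whenever L ≥ k), which is the
invariant the tests rely on; no further scaling (e.g. max-normalization) is
applied at the encoder level. A sequence shorter than k yields a zero block
with a logged warning — unreachable for benchmark-filtered data (RNA ≥ 15 nt
with k ≤ 4; protein ≥ 25 aa with k ≤ 3) but possible for synthetic edge
cases. The ncRNA vector is [primary k=1..4 | structure k=1..4 | IP] =
340 + 2800 + 1 = 3141; the protein vector is [reduced primary k=1..3 |
structure k=1..3 | IP, ASA, CN, HSEα-up, HSEα-down] = 399 + 39 + 5 = 443.
The IP scalar is pair-level and is injected into both vectors of its pair;
it is the only pair-dependent element of the ncRNA vector.

**Seven-state RNA loop types.** Given a base-pair set, paired positions are
stems (S). Unpaired positions are labeled by their directly enclosing pair:
no enclosed helix → hairpin (H); exactly one enclosed helix → internal loop
(I) if both strands between the closing pair and the child helix contain
unpaired bases, bulge (B) if only one does; two or more enclosed helices →
multi-loop (M). Unpaired positions outside all pairs are ends (E) in the
5′/3′ terminal runs and external (X) between top-level helices. The B/I and
E/X conventions follow the usual loop-decomposition practice
(bpRNA-style); the state nomenclature alone does not pin them down.
Pseudoknots are removed first by keeping a maximal non-crossing subset of
helices, greedily by helix size with a deterministic 5′-most tie-break —
the seven-state scheme is only defined for nested structures. The
classifier is validated against an independent dot-bracket/tree-parsing
oracle on random nested structures.

**Interface propensity.** IP(pair) is the mean of table[(aa, ss3), (nt,
paired)] over the full residue × nucleotide cross product, where paired
means the seven-state label is S. This is a bilinear form in the two
composition vectors, hence invariant to residue/nucleotide order. The
published 60×8 table is not redistributable input; a neutral all-ones
default (IP ≡ 1) keeps the pipeline runnable and is clearly labeled, with
file-based substitution for the real table.

## Dataset handling

Benchmark filters keep RNAs with 15 ≤ length ≤ 500 (the upper cap mirrors
the input limit of the secondary-structure predictors these pipelines rely
on) and proteins with length ≥ 25; pairs survive iff both members do, then
unpaired records are dropped. Filtering is applied before negative
generation (the order is not fixed by the benchmarks' descriptions; the
filter-first choice is logged per run). Negative pairs are drawn by
uniformly re-pairing the members of the positive set and discarding a
candidate R2–P2 when it duplicates a positive or accepted negative, or when
some positive R1–P1 has identity(P2,P1) ≥ 40% AND identity(R2,R1) ≥ 80%.
Identity is matches / alignment-length under global alignment with match 1,
mismatch 0, gap −1 (the discard rule's source procedure is unspecified;
thresholds and scoring are configurable). The attempt budget is 100·n draws
with an informative failure reporting the acceptance rate.

## Classifier

Architecture per branch (ncRNA input 3141, protein 443, single channel):
three blocks of [conv (filters 45, 64, 86; kernels 6,5,5 for ncRNA and
6,6,6 for protein; stride 1, same padding) → ReLU → max-pool → batch-norm →
dropout 0.2], then a BLSTM (hidden 45, final states of both directions
concatenated) and a fully-connected 64. Head: concat(64+64) → FC 128 →
dropout 0.25 → FC 64 → dropout 0.3 → FC 2 → softmax, cross-entropy loss.
Batch-norm is placed immediately after pooling; the 2-way softmax with
cross-entropy is the binary objective.

All layers and their gradients are implemented in numpy (float32), with
finite-difference checks in the tests. Two numerical details matter on
CPU: gradients vanishing through long backpropagation-through-time chains
produce subnormal floats that are pathologically slow on x86, so BPTT
flushes magnitudes below 1e-30 to zero; and the convolution uses a
channels-last im2col whose copy is cache-contiguous.

Defaults, with provenance:

| parameter | default | origin |
|---|---|---|
| conv filters / kernels / dropout | (45,64,86) / (6,5,5) rna, (6,6,6) protein / 0.2 | published operating point |
| BLSTM hidden, branch FC | 45, 64 | published operating point |
| head widths / dropout | (128,64,2) / (0.25, 0.3) | published operating point |
| Adam lr, SGD lr | 0.001, 0.005 | published operating point |
| pool size | 4 | package choice (below) |
| batch size / max epochs / Adam fraction | 16 / 40 / 0.6 | package choice |
| patience / validation fraction | 10 / 0.15 | package choice |
| L2 weight decay | 1e-4 | package choice |

Training runs Adam first (60% of the epoch budget), then SGD fine-tuning.
Inputs are standardized per feature (z-score) with statistics fitted on the
non-validation training rows — the raw feature scales span four orders of
magnitude (7-mer frequencies ~1e-3 vs ASA averages ~50), and without
standardization optimization stalls at the trivial ln 2 loss. After each
epoch the AUC on a stratified 15% validation split is computed; a phase
stops when it has not improved for `patience` epochs and the
best-validation parameters are restored. Selecting on a validation
discrimination metric rather than validation loss matches how this family
of models is tuned in practice (validation-set MCC/AUC maximization) and
is markedly more stable here: with overconfident small-sample networks the
validation loss deteriorates while ranking quality still improves.

Pooling geometry is the one architectural default deliberately set by the
package: with pool size 2 the ncRNA branch leaves 392 recurrent steps, and
a final-state BLSTM trained on a few hundred samples neither propagates
useful gradient over that horizon nor fits in a sensible CPU budget; pool
size 4 (49 steps) trains reliably. All of these are `ModelConfig` fields
and a YAML config can restore any other operating point.

Determinism: all randomness (init, shuffling, dropout, splits) derives
from the config seed; fixed seed ⇒ bit-identical runs on the same
single-threaded BLAS.

## Evaluation

ACC, TPR, TNR, PPV, F1 and MCC follow the standard confusion-matrix
formulas, with score ≥ 0.5 ⇒ positive (the tie goes to positive, a
documented convention). A metric with a zero denominator is reported as 0
and flagged, keeping fold aggregation stable. AUC is the rank-based
(Mann–Whitney) statistic with ties counting ½. Cross-validation is
stratified five-fold repeated 10 times with repeat-indexed seeds; results
are aggregated as mean ± sd both over all 50 fold measurements and over the
10 repeat means (reports include both, since "±sd" presentations are
ambiguous between the two). The metric implementations are tested against
an exact rational-arithmetic oracle and a brute-force pairwise AUC.

## Synthetic data

The generator emulates the statistical shape of an interaction benchmark:
uniform background sequences with lengths uniform in [15, 500] nt (RNA) and
[25, 300] aa (protein); a pair-level signal implanted with probability 0.9
into positives and 0.1 into negatives; RNA structure strings obtained by
classifying random nested base-pair sets (recursive insertion guarantees
pseudoknot-freedom); protein structure as random H/E/C runs (3–10
residues); tertiary values from positive log-normals (ASA ~ logN(ln 50,
0.5), CN ~ logN(ln 15, 0.4), HSE ~ logN(ln 10, 0.5)).

The signal is carried in the primary sequences — a 14-nt RNA motif and a
12-aa protein motif implanted at a fixed density of one site per 80 nt /
60 aa (at least one site) — because the encoder is k-mer based. Density
implanting, rather than exactly one site, mirrors the multi-site binding of
RNA-binding proteins and keeps the k-mer signal-to-noise ratio independent
of sequence length; a single short site in a 500-nt molecule is
statistically invisible at the k-mer level, which is not how interacting
and non-interacting benchmark sequences actually differ (they differ at
the family/composition level). With implant probabilities 0.9/0.1 the
best achievable held-out AUC is 0.90 (10% of positives are
indistinguishable from clean negatives and vice versa), so the recovery
experiment's AUC ≥ 0.85 demands near-perfect signal detection. Structure
and tertiary channels carry noise by default; `structure_signal=True`
additionally implants fixed structure-state motifs for qualitative
feature-ablation experiments.

What passing the recovery experiment shows — and what it does not: it
demonstrates that encoding, training, selection and evaluation are wired
correctly and can extract a planted, k-mer-visible signal from realistic
sequence lengths at realistic sample sizes, with a shuffled-label control
at chance. It does not establish performance on real benchmark data, whose
discriminative structure (family composition, structure-predictor biases,
curated negatives) the generator does not attempt to reproduce.

## Sizes and runtime

The recovery experiment uses 200+200 pairs (300 train / 100 test), chosen
as the smallest scale at which the classifier's behavior is
representative; default training takes a few minutes on one CPU core.
Unit tests use a scaled-down network (8 filters, hidden 8) over the same
code paths.

## Known limitations

* The CNN is translation-equivariant while k-mer histogram positions are
  semantically fixed, so the architecture is data-hungry relative to a
  linear model on the same features at small n; this is a property of the
  method being implemented, not of the implementation.
* The IP table's published values are external; with the neutral default
  the IP feature is uninformative.
* Pseudoknot removal discards information by construction; structures with
  extensive crossing pairs lose those helices before classification.
* The numpy training loop is single-threaded CPU code; it is meant for
  benchmark-scale datasets (thousands of pairs), not genome-scale scans.
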