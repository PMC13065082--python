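# Methods

## Signature model

A genome S = a₁…a_L over {A,C,G,T} is embedded by the chaos-game midpoint
map CGRᵢ = ½(CGRᵢ₋₁ + α(aᵢ)) from CGR₀ = (0.5, 0.5). The map is an
iterated function system whose attractor is the unit square; the point
after i steps encodes the suffix of the first i bases in its binary
expansion, which is why every point whose last k bases equal w lies in a
unique 2⁻ᵏ sub-square. The per-sequence signature is a 3 × 2ᵏ × 2ᵏ tensor:
k-mer counts (F1) and, per k-mer, the mean x and y of its trajectory
endpoints (F2/F3). The means compress each k-mer's *prefix context*
distribution into a point inside that k-mer's cell; two genomes with equal
k-mer counts but different long-range arrangement separate in F2/F3.

Assumptions worth stating: the signature is strand-specific (no
reverse-complement canonicalization — sequences are used as given), treats
the genome as one linear string, and carries compositional information
only. Host signal enters through the empirical tendency of phages infecting
the same host to share k-mer composition; nothing in the model encodes
biology beyond that.

### Corner assignment

The default maps A=(0,0), C=(0,1), G=(1,1), T=(1,0). Any bijection of
bases onto corners is accepted; a relabeling that realizes a symmetry of
the square permutes grid cells and reflects coordinates without changing
the information content (tested), and classification accuracy is empirically
insensitive to the choice. The default is the convention under which the
package's hand-checkable reference computation (AGTCGTTACA, k = 2) is exact.

### Grid layout

Cells are placed by strict geometry: a word's cell is the sub-square
actually containing its trajectory points, with row 0 at the top (largest
y) and column 0 at the left. The j-th letter of the word contributes its
corner bits at binary weight 2^(j−1), so the *last* letter selects the
half of the square. All per-word lookups go through `kmer_cell_index`;
nothing depends on any printed matrix arrangement.

### Degenerate and messy inputs

* IUPAC ambiguity codes emit no trajectory point and invalidate every
  k-window containing them; counts then sum to the number of clean windows.
  Fabricating coordinates for ambiguous bases would put points in wrong
  cells, so they are skipped instead.
* Sequences shorter than k are a hard error (surfacing data problems beats
  silently emitting a zero tensor).
* Input is uppercased; multi-record FASTA yields one tensor per record.
* Min-max normalization is per channel per sequence; a constant channel
  maps to zeros (division-by-zero guard; arises only for degenerate inputs
  such as single-letter sequences).

All worked-example arithmetic is exact in float64 because every CGR
coordinate of a short sequence is a binary fraction.

## Classifier

Architecture (k = 7 default): conv 5×5/64 + ReLU, pool 2×2 → conv 5×5/128
+ ReLU, pool 2×2 → flatten → FC-512 + ReLU → softmax over host taxa, i.e.
(3,128,128) → (64,128,128) → (64,64,64) → (128,64,64) → (128,32,32) →
131072 → 512 → n_classes. Input side 2ᵏ must be divisible by 2^(conv
blocks). One model is trained per taxonomy level.

Training: categorical cross-entropy, Adam at learning rate 0.001 (its
standard β₁=0.9, β₂=0.999), batch size 32, at most 100 epochs with early
stopping once validation accuracy has not improved for 10 epochs; the
best-validation weights are returned. Batch size, epoch budget and early
stopping are this package's choices (only the learning rate and loss are
fixed by the method); all are overridable in `TrainConfig`. No dropout or
weight decay by default, and no class reweighting — plain cross-entropy.
Arg-max ties break toward the lower class index. Given a seed the whole
fit is deterministic (NumPy RNG for init and shuffling; single-threaded
arithmetic is bit-reproducible).

The network is implemented in NumPy (im2col + GEMM convolutions, float32),
sized for CPU training at desk scale; gradients are verified against finite
differences in the test suite.

## Evaluation

Accuracy, macro precision/recall/F1 and top-k accuracy (k ∈ {1,5,10,15,20}
by default, truncated to n_classes). Per-class ratios with zero
denominators (class never predicted, or absent from the truth) count as 0
in the macro mean — the common convention for sparse test sets; the class
set defaults to the union of true and predicted labels and can be widened
explicitly to include unobserved classes.

## Distances

Signatures flatten to vectors of length 3·4ᵏ (F1 block, then F2, then F3,
each row-major — fixed so vectors are comparable across runs) and are
compared by cosine distance, 1 − cos. Distances use normalized tensors by
default, matching the classifier's input; a flag selects raw tensors.
Matrices are symmetrized exactly, clipped to [0, 2], zeroed on the
diagonal, and exported as relaxed PHYLIP or long TSV. Tree building itself
(Neighbor-Joining) is left to external tools.

## Synthetic data

Each host class is an order-2 Markov chain over {A,C,G,T}. A separation
parameter s ∈ [0,1] interpolates every transition row between a table
shared by all classes (Dirichlet(5) rows, near-uniform) and a class-private
sparse table (Dirichlet(0.15) rows): s = 0 makes classes identical —
classifier accuracy can only reach chance — and s = 1 gives near-disjoint
preferred k-mers (mean total-variation distance between class rows > 0.5).
Order 2 is the smallest order with rich 3-mer-and-above structure whose
stationary distribution is cheaply computable, so tests can compare
empirical dinucleotide frequencies against the analytic stationary law.
Default lengths are drawn from N(5000, 1500²) truncated at 200 bases — a
desk-scale stand-in for phage genomes (real ones run roughly 5–300 kb).

What the generator does *not* emulate: genes, codon structure, GC skew,
prophage mosaicism, shared ancestry between classes, or database label
noise. Passing the recovery tests therefore shows the pipeline extracts
compositional class signal end to end; it does not certify accuracy on real
phage collections, which depends on how strongly true host signal is
expressed in genome composition.

## Problem sizes used in the checks

The learning checks train on 5 classes × 50 sequences × 2 kb at k = 4 with
an 8:1:1 split — sizes at which an order-2 compositional signal at full
separation is reliably recoverable (held-out accuracy ≥ 0.95) while a
single fit stays in the tens of seconds on one CPU. The oracle-equivalence
check uses 100 random sequences of length ≤ 200 at k ≤ 3, where the
brute-force prefix-materializing oracle is affordable. k = 7 (the default
for real genomes) is exercised by the architecture and featurization shape
checks.

## Known limitations

* Float64 CGR coordinates lose trailing bits once a trajectory exceeds
  ~50 steps; means in F2/F3 are then accurate to ~1e-15, which is
  irrelevant at genomic scale but worth knowing for exactness arguments.
* The NumPy CNN targets desk-scale training (hundreds to a few thousand
  sequences); very large collections would want a GPU framework.
* Closed or multi-segment genomes are treated as single linear strings;
  no reverse-complement symmetrization is applied.
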