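# cgrhost

Alignment-free prediction of a bacteriophage's bacterial host
(species/genus/family level) from its genome sequence alone, using
positional chaos-game-representation (CGR) signatures and a small
convolutional neural network. For researchers who need host calls for
assembled phage genomes — or CGR-based distance matrices for
phylogenetics — without alignments or reference databases.

## The method

**Signature.** The chaos game embeds a DNA sequence S = a₁a₂…a_L into the
unit square: starting from CGR₀ = (0.5, 0.5), each nucleotide applies the
midpoint map

    CGRᵢ = ½ (CGRᵢ₋₁ + α(aᵢ)),

where α assigns each base a corner (default A=(0,0), C=(0,1), G=(1,1),
T=(1,0)). All trajectory points whose last k letters spell the same k-mer w
fall inside one 2⁻ᵏ × 2⁻ᵏ sub-square, so a 2ᵏ × 2ᵏ grid indexed by k-mer
tiles the square. Each genome becomes a 3 × 2ᵏ × 2ᵏ tensor:

* **F1** — the count N_w of each k-mer (the classical frequency-CGR),
* **F2** — the mean x̄_w of the N_w trajectory points at which w ends,
* **F3** — the corresponding mean ȳ_w,

with absent k-mers set to (0, 0) in F2/F3 and each channel min-max
normalized to [0, 1]. F2/F3 add positional context that plain k-mer
counting discards.

**Classifier.** A CNN maps the tensor to host-taxon probabilities: two 5×5
same-padding convolutions (64 then 128 channels), each followed by ReLU and
2×2 max pooling, then a 512-unit fully connected ReLU layer and a softmax
output. At the default k = 7 the activations run (3,128,128) →
(64,128,128) → (64,64,64) → (128,64,64) → (128,32,32). Training minimizes
categorical cross-entropy with Adam (learning rate 0.001) on an 8:1:1
train/validation/test split, keeping the best-validation-accuracy epoch.
The network is implemented in NumPy — small enough to train on a laptop CPU.

**Distances.** Each tensor flattens to a 3·4ᵏ vector (F1 cells, then F2,
then F3, row-major) and pairs of genomes are compared by cosine distance
1 − (u·v)/(‖u‖‖v‖), exported as PHYLIP matrices for external
Neighbor-Joining.

A seeded synthetic-data module generates class-conditioned sequences from
per-class order-2 Markov chains with a tunable separation knob, so the
whole pipeline is testable offline.

## Worked example

```python
from cgrhost import (GenomeSequence, cgr_trajectory, kmer_average_positions,
                     build_feature_tensor, kmer_cell_index)

seq = GenomeSequence("example", "AGTCGTTACA")
traj = cgr_trajectory(seq)
print("final point:", traj.points[-1])

pos = kmer_average_positions(seq, 2)
print("GT mean position:", (pos.mean_x["GT"], pos.mean_y["GT"]))

t = build_feature_tensor(seq, 2, normalize=False)
r, c = kmer_cell_index("GT")
print("GT cell (row, col):", (r, c))
print("F1[GT], F2[GT], F3[GT]:", t.f1[r, c], t.f2[r, c], t.f3[r, c])
```

prints

```
final point: (0.11572265625, 0.27587890625)
GT mean position: (0.83203125, 0.36328125)
GT cell (row, col): (2, 3)
F1[GT], F2[GT], F3[GT]: 2.0 0.83203125 0.36328125
```

GT occurs twice in AGTCGTTACA (positions 3 and 6); its trajectory endpoints
are (0.8125, 0.3125) and (0.8515625, 0.4140625), so the mean position is
their average — exact binary fractions, reproduced bit-for-bit. The count 2
and the two means are what lands in GT's grid cell of the three channels.

## Command line

```
cgrhost simulate  --classes 5 --separation 1.0 --n-per-class 50 \
                  --out-fasta phage.fasta --out-labels hosts.tsv
cgrhost featurize phage.fasta --k 7 --out tensors.npz
cgrhost split     hosts.tsv --out splits.tsv
cgrhost train     --tensors tensors.npz --labels hosts.tsv \
                  --splits splits.tsv --out model.npz
cgrhost predict   --model model.npz --tensors tensors.npz --out calls.tsv
cgrhost evaluate  --model model.npz --tensors tensors.npz --labels hosts.tsv \
                  --splits splits.tsv --out metrics.json
cgrhost distmat   phage.fasta --k 7 --out-phylip dist.phylip
```

Real runs take a FASTA of phage genomes plus a two-column TSV mapping
sequence ids to host taxa at one taxonomy level; `evaluate` reports
accuracy, macro precision/recall/F1 and top-k accuracy.

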