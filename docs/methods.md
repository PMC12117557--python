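# Methods

## The model

A screening compound is a labelled molecular graph *m* with binary
activity *y*. The hybrid classifier scores it as

    h  = GNN(m)                # learned representation
    p̂ = f([h ‖ h_dp])          # MLP on the concatenation

where **h_dp** is a fixed-length vector of expert-crafted molecule-level
descriptors, z-scored with statistics fitted on the training side only.
Training minimizes mean binary cross-entropy with scores clipped to
[1e-7, 1 − 1e-7], using Adam (learning rate 1e-3, batch size 128) for a
fixed number of epochs; the final-epoch parameters are kept — no early
stopping or validation-based selection, because with only hundreds of
actives a validation split wastes labels and dropout already limits
overfitting. Ablations use the identical code path: descriptor-only
(the MLP sees h_dp alone) and GNN-only (the descriptor branch is absent,
so scores are provably invariant to descriptor inputs).

### Encoders

**gcn** — per layer, node states are averaged over neighbors including a
self-loop with symmetric degree normalization 1/√(deg_i·deg_j), followed
by a linear map and ReLU; the graph embedding is the mean (default) or
sum of final node states. A dense-matrix oracle D̃^{-1/2}ÃD̃^{-1/2}XW is
used in tests to pin the scatter/gather implementation down to 1e-6.

**schnet** — element embeddings refined by interaction blocks over a
radius graph (default cutoff 10 Å): each interatomic distance is expanded
in 50 Gaussian radial basis functions with centers uniform on [0, cutoff]
and width equal to the spacing; a two-layer filter network maps the basis
to per-channel weights; the continuous-filter convolution sums
neighbor states ⊙ filters, followed by atom-wise layers with
shifted-softplus nonlinearities and a residual update; sum readout.
Because only distances enter, embeddings are invariant under rigid
motions of the coordinates (tested at 1e-5 relative). Bond features are
ignored by this encoder by design; coordinates are required and never
generated downstream.

Defaults (3 layers/blocks, width 128) follow the cited architectures'
common desk-scale settings. Both encoders and the MLP run on a small
reverse-mode autodiff core written on NumPy arrays (`_autograd`), checked
against finite differences; all arithmetic is float64 with deterministic
reduction order, which is what makes seeded runs bit-identical.

### Featurization

Default node features: element one-hot over {H,C,N,O,S,P,F,Cl,Br,I},
degree one-hot (0–5), formal charge one-hot clipped to [−2, 2],
aromaticity flag, ring flag, attached-H one-hot (0–4) — d_node = 28.
Edge features: bond-order one-hot {single, double, triple, aromatic} +
ring flag. Heavy-atom graphs by default (hydrogens enter via the H-count
feature); an explicit-hydrogen mode exists. The scheme is declared in
config so an alternative feature list can be dropped in without touching
the encoders.

### Descriptors

The built-in set (23 features) covers scalar and 2D molecule-level
quantities computable from the graph alone: heavy-atom count, molecular
weight, ring and aromatic-ring counts, aromatic-atom count, H-bond
donors/acceptors, rotatable bonds, topological polar surface area (TPSA),
Crippen logP, formal-charge sum, sp³ carbon fraction, heteroatom count,
and per-element counts. External tables (e.g. a 391-column QSAR
descriptor export) are imported from CSV keyed by molecule id; missing
cells are imputed with the feature mean (never label-aware).
Standardization uses the population sd (ddof = 0); zero-variance features
are flagged and mapped to 0.

## Evaluation

Only a tiny top fraction of a ranked library can be tested, so metrics
focus on early recognition:

- **logAUC[0.001, 0.1]** — area under the ROC with FPR on a log10 axis,
  normalized by the log-width. The ROC is integrated segment by segment
  (vertical segments have zero FPR measure) by trapezoid on a log-uniform
  grid of 10,001 points plus the curve vertices; the curve is extended
  from (0, 0) so FPRs below 1/#inactives are covered. This reproduces the
  analytic values exactly: 1 for a perfect ranking, (0.1 − 0.001)/(2 ln 10)
  ≈ 0.0215 for the diagonal.
- **BEDROC(α = 20)** — (RIE − RIE_min)/(RIE_max − RIE_min) with
  RIE = Σ_actives e^(−α rᵢ/N) normalized by the uniform expectation;
  cross-checked in tests against RDKit's independent implementation.
- **EF₁₀₀** — (n₁₀₀/100)/(n/N), exact rational arithmetic.
- **CG₁₀₀ / DCG₁₀₀** — active counts in the top 100, undiscounted and
  discounted by 1/log2(rank + 1).

Ties are broken deterministically (score descending, then stable input
order), which makes every metric value exact and reproducible; an
optional `tie_policy="shuffle-average"` mode instead averages the
rank-based metrics over 10 seeded shuffles of tie blocks, which is less
flattering to degenerate scorers (an all-tied ranking then scores like a
random one) at the cost of exactness.

## Splits and statistics

Random splits take the first ⌊frac·N⌋ of a seeded permutation. Scaffold
splits group molecules by Bemis–Murcko framework (ring systems plus
linkers, atom types retained; acyclic molecules share one reserved group,
or optionally one group each) and assign whole groups greedily, largest
first, so training holds the common chemotypes and the test side is
enriched for rare ones; equal-size group runs are shuffled under the seed
so repeated scaffold splits differ.

Model comparison pairs metric values on byte-identical splits:
d = b − a per (dataset, replicate), paired t-test with df = k − 1, 95% CI
from the t quantile, effect size d_z = mean(d)/sd(d), and
Benjamini–Hochberg adjustment applied jointly across the whole family of
(model pair × metric × dataset) cells. Identical differences in every
unit yield a flagged degenerate result rather than an error. The default
benchmark uses 5 split replicates.

## Synthetic data

The generator emulates the HTS regime the method targets — large
imbalance (sub-percent to few-percent actives), scaffold-family
structure, and an activity signal that mixes a global molecular property
with a local motif — at sizes a single CPU handles in minutes. Molecules
are assembled by decorating one of 15 ring scaffolds with up to 3 of 15
acyclic substituents at valence-safe positions, deduplicated by canonical
SMILES. The latent activity is

    w_global · z(TPSA) + w_motif · 1[sulfonamide present] + N(0, noise²)

and exactly the top ⌈active_fraction·N⌉ latent scores are labelled
active. TPSA was chosen as the global channel because it sits in the
built-in descriptor set but is a molecule-level aggregate a shallow graph
readout recovers poorly, so descriptor integration has something real to
contribute; the sulfonamide motif is the complementary local signal a GNN
can spot. Defaults (2000 molecules, 1–2% actives, 10 families,
w_global = w_motif = 1, noise 0.5) mirror that regime scaled to desk
size; the benchmark experiments use 4000 molecules with 2% actives and
five seeded 80/20 splits.

What the generator does **not** emulate: assay noise and frequent-hitter
artifacts, activity cliffs, tautomer/protonation effects, realistic
descriptor redundancy, or library-scale chemical diversity. Passing
benchmarks on this data shows the pipeline's correctness and the
direction of the descriptor-integration effect under a planted signal,
not performance on any particular real screen.

## Numerical and design notes

- All training randomness (init, shuffling, dropout) flows from one
  seeded NumPy generator per fit; two fits with identical seed, config
  and data are bit-identical, and the end-to-end benchmark reproduces its
  metric table byte-for-byte.
- The radius-graph builder includes (j, i) with every (i, j) and excludes
  self-pairs; non-finite coordinates are fatal.
- Duplicate structures collapse by canonical SMILES; label conflicts
  default to "keep-active" (a confirmed active outweighs an inactive
  read), with "keep-first" and "drop-conflict" available.
- Degenerate inputs fail loudly: single-class training sets or metric
  inputs, descriptor width mismatches, ranking cutoffs exceeding the test
  set, and scaffold splits with a single group are all errors, not
  silent fallbacks.
- The encoder registry maps names to constructors so further
  architectures (e.g. spherical message passing over distances, angles
  and torsions) can be plugged in without touching the training loop;
  none beyond gcn/schnet ship here.

## Limitations

The NumPy training loop is single-threaded and suits 10³–10⁴-molecule
studies, not the 10⁵-molecule screens the method ultimately targets; the
MLP/encoder hyperparameter space is deliberately small; no hyperparameter
search, ensembling, or uncertainty estimation is provided; tautomer and
protonation standardization are out of scope for the I/O layer.
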