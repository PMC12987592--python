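# Methods

`circdsa` predicts associations between circular RNAs (circRNAs) and drug
sensitivity by bipartite link prediction. Known associations form a binary
matrix **Y** (rows: circRNAs, columns: drugs; `Y[i,j]=1` when the expression
of circRNA *i* is significantly associated with cell-line response to drug
*j*). The pipeline has three stages: multi-source similarity construction,
shared-constraint collaborative feature learning, and confidence-guided graph
structure learning with a GCN prediction head.

## Similarity kernels

Each entity type gets three square, symmetric, [0,1]-valued similarity
matrices.

**Sequence (CSS).** For circRNA host-gene sequences s_i, s_j,
`CSS_ij = 1 − LD(s_i, s_j) / max(|s_i|, |s_j|)` with LD the unit-cost
Levenshtein distance, computed by the classic dynamic-programming recurrence
(rows vectorized; the insertion dependency is resolved with a prefix-minimum
scan, exact for unit costs).

**Structure (DSS).** Tanimoto coefficient over binary topological
fingerprints, `d_i·d_j / (|d_i|² + |d_j|² − d_i·d_j)`. Two all-zero
fingerprints are 0/0; we return 0 with a warning.

**Entropy profile (CES/DES).** Each partner k carries a global probability
`p_k = degree(k)/N` (N = total association count). A profile's Shannon
entropy is `H(S_i) = −Σ_{k∈S_i} p_k log2 p_k` and
`CES_ij = 2·H(S_i∩S_j) / (H(S_i)+H(S_j))`, with the intersection entropy
using the same global probabilities (no renormalization). Conventions:
H(∅)=0, and a zero denominator (isolated entities, or a single partner with
p=1) yields similarity 0 rather than NaN, so degenerate entities are
maximally dissimilar. The diagonal equals 1 exactly when H(S_i)>0.

**Gaussian interaction profile (CGS/DGS).** `K_ij = exp(−θ‖y_i − y_j‖²)`
over binary association profiles, with bandwidth θ = 1 / mean squared
profile norm (= 1 / mean degree for binary profiles). Diagonals are pinned
to 1 against floating-point drift.

During cross-validation the held-out positive edges are zeroed before the
entropy and GIP kernels are computed (and before the adjacency is built), so
no test label leaks into training inputs. A `gip_full_matrix` switch restores
the naive protocol for comparison.

## Collaborative feature learning

Each of the six similarity networks is compressed by its own two-layer
graph-convolutional autoencoder. The propagation matrix is
`D^{−1/2}(S+I)D^{−1/2}`; the input node features are the similarity rows
themselves; the decoder is a mirror two-layer dense map; activations are ELU.
The reconstruction loss is the squared Frobenius error averaged over the
number of *sources* (the index of the sum runs over sources; an alternative
reading normalizes by node count and differs only by a constant factor).

After a reconstruction-only warm-up (default 40 of 100 epochs), "must-link"
pairs are mined once and frozen: per source, the Pearson correlation matrix
of embeddings is thresholded at a quantile of its off-diagonal values
(default 0.90), and the shared constraint is the intersection across the
sources of that entity type. Mining once avoids a non-stationary target.
The constraint loss is the mean squared embedding distance over shared pairs,
applied to each source's live embeddings, weighted by `lambda_mc` (default 1).

The quantile default is 0.90 rather than a more extreme value: at the top 1%
the per-source sets barely overlap and the intersection is empty in practice,
leaving the constraint inert; at 0.90 the shared sets contain tens of pairs
that are 100% within-cluster on planted data.

Final per-source embeddings (default 32-dimensional) are assembled into the
block feature matrix `X = [[Hcs 0 Hce 0 Hcg 0], [0 Hds 0 Hde 0 Hdg]]` whose
zero blocks prevent cross-type feature mixing. Under the `no_cfe` ablation,
X holds the raw similarity rows in the same block layout.

## Graph structure learning

The bipartite adjacency is `A = [[0, Y], [Yᵀ, 0]]`. The structure learner is
a full-graph parameterization: a free matrix Ω with `S = σ(Ω)`, σ = ELU+1
(strictly positive, smooth; `relu` and `sigmoid` selectable). Ω is
initialized affinely from the adjacency, `Ω = 4A − 2`, so observed edges
start at weight σ(2)=3 and non-edges at σ(−2)≈0.14. Initializing at Ω = A
itself would give every *non*-edge weight σ(0)=1 — half an edge's weight — a
nearly uniform graph that over-smooths the downstream GCN (measured ≈ −0.03
CV AUC). S is symmetrized and degree-normalized (`D^{−1/2}·(S+Sᵀ)/2·D^{−1/2}`,
zero-degree rows left zero), which is scale-invariant and bounds the spectral
radius by 1.

Two views are built per epoch: a refined view anchored on A and an inference
view on the normalized learned structure Ŝ. Both share one realized
symmetric edge-dropout mask (default p_e = 0.1); feature masking draws one
Bernoulli mask over feature *dimensions* per view, broadcast across rows
(defaults p_mr = 0.1, p_mi = 0.4, the sensitivity-analysis optimum). Each
view has its own two-layer GCN encoder and two-layer MLP projector
(projection width 64).

**Confidence-guided pseudo-labels.** Projections are row-L2-normalized;
each row's pseudo-label is its argmax (ties to the lowest index, detached
from gradients); the loss is the mean of the two views' cross-entropies
against their own labels, restricted to rows whose max softmax probability
reaches a threshold τ in both views (default 0.8; τ=0 disables gating; no
retained rows gives loss 0). Because a freshly initialized 64-way projection
is near-uniform (max probability ≈ 1/64), a fixed gate at 0.8 would retain
nothing and the mechanism would never bootstrap; the trainer therefore
anneals the gate linearly from 0 to τ over `tau_ramp_epochs` (default 50).

An empirical caveat the tests make visible: once the projections sharpen,
the self-labeling cross-entropy collapses toward zero, and on the synthetic
data the pseudo-label term is AUC-neutral — the `no_cgpl` ablation performs
within noise of the full model. The collaborative-feature ablation `no_cfe`,
by contrast, costs ≈ 0.25 AUC. On the real, noisier association data the
balance may differ; the synthetic benchmark cannot adjudicate that.

## Prediction and training protocol

The head is a two-layer GCN over (X, S′), S′ the normalized learned
structure, followed by an inner-product decoder: score(i,j) =
logistic(z_i · z_{n+j}). The supervised loss is the MSE between scores and
binary labels over sampled pairs (positives and an equal number of uniform
zero-cell negatives, 1:1). The stage-B objective is
`L = L_pre + lambda_cpl · L_cpl`, optimized with Adam (lr 5e-3, 150 epochs,
early stop on a loss plateau with patience 30). Stage A (collaborative
features) is trained first and frozen — the three published losses never
share one joint objective, so staging keeps each intact.

All neural components run on a small in-package reverse-mode autodiff engine
over numpy (`circdsa._autodiff`); gradients of every primitive are verified
against finite differences in the test suite.

**Cross-validation.** Positives are split into k folds (default 5). Per
fold: held-out positives are zeroed in every training input; negatives are
drawn uniformly from never-associated cells, disjointly for train and test
(so test pairs never intersect training pairs); metrics are AUC (rank-based),
AUPR (step interpolation), and accuracy/F1/recall at threshold 0.5 (the
threshold is a convention; nothing in the method calibrates it). Everything
is a deterministic function of the configuration seed.

## Synthetic data

The generator emulates the statistical regime of the curated
circRNA–drug-sensitivity dataset (a few hundred entities, ≈7–8% density) at
desk scale: defaults 120 circRNAs × 90 drugs, rank-4 latent factors, 4
clusters per entity type, target density 0.08. Cluster centers are standard
normal; members add isotropic noise (sd 0.5); association probabilities are
`logistic(2.0·UVᵀ + b)` with b calibrated by bisection to the target density
(tolerance 0.005). The same cluster labels drive per-cluster ancestor
sequences (length 300, per-base substitution rate 0.05) and fingerprint
prototypes (128 bits, density 0.3, bit-flip rate 0.05), so all six kernels
carry signal correlated with the planted structure. The noise and scale
were fixed so the oracle AUC of the true probabilities is ≈ 0.95 — the same
separability regime as the real benchmark — leaving meaningful headroom
between a learned model and chance. Rows or columns left with no partner
after ten redraws receive their single most probable association.

What the generator does *not* model: back-splice junction structure, real
host-gene homology, GDSC dose–response noise, hub-dominated degree
distributions, or batch structure. Passing recovery tests therefore show the
pipeline extracts planted low-rank + cluster signal end-to-end, not that it
matches its reported performance on biological data.

## Problem sizes used in the shipped checks

The acceptance tests run 5-fold CV on the default 120×90 dataset under ten
training seeds (median AUC ≥ 0.85, AUPR ≥ 0.80), a ten-seed label-shuffle
null (mean AUC within [0.4, 0.6]), both ablations at the same size, loss
descent over the first 100 epochs, and exact kernel arithmetic against
brute-force and hand-worked oracles on a 3×3 worked example. Unit tests use
a 40×30 dataset with shortened schedules; they exercise mechanics, not
performance.

## Known limitations

- The self-labeling objective is degenerate at convergence (see above); a
  margin- or entropy-regularized variant would likely be needed for the
  pseudo-labels to carry real signal.
- Dense (n+m)×(n+m) structure parameters scale quadratically in memory;
  beyond ~2,000 entities a sparse or factorized learner would be required.
- The Levenshtein kernel is O(L²) per pair and O(n²) pairs; for thousands of
  sequences an alignment library or banded distance would be the practical
  substitute.
- Accuracy/F1/recall depend on the uncalibrated 0.5 threshold and should be
  read qualitatively; AUC/AUPR are the primary metrics.
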