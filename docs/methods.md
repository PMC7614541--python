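# Methods note

This note documents the models implemented in `hemiplex`, the meaning and
defaults of their parameters, the numerical choices, and what the
synthetic generator does and does not emulate. All quantitative claims
below are either definitions or are computed by the test suite and
`scripts/acceptance.py`; no empirical claims beyond those are made.

## Multiplex connectome model

A connectome is four directed, integer-weighted graphs over one shared,
canonically sorted node set, one per connection type: a-d (axo-dendritic),
a-a, d-d, d-a, named by the presynaptic and postsynaptic compartment.
Weights are synapse counts. Self-loops (autapses) are excluded at build
time and counted in a report; synapse records lacking a compartment label
on either side go to an unclassified bucket rather than being dropped
silently, and records referencing unknown neurons are a hard error.

## Axon/dendrite splitting (synapse flow centrality)

For a rooted skeleton, every edge is scored by the number of
(presynaptic site, postsynaptic site) tree paths crossing it, counted
with site multiplicities. Computed with subtree sums in O(n):
`centrality(e) = pre_below·post_above + pre_above·post_below`. The
*linker* is a contiguous segment of maximal-centrality edges whose
strictly interior nodes carry no synapses; when several qualify, the one
nearest the soma wins (a convention — upstream ties are not otherwise
resolvable from the arbor alone). The split node is the linker's
soma-proximal node; the axon is its set of strict descendants, so the
soma always lies on the dendrite side. Neurons with no synapses are
`immature`; neurons missing either presynapses or postsynapses, or with
no qualifying linker, are `unpolarized`.

## Bilateral reproducibility threshold

The *input fraction* of edge i→j is its weight over the target's total
in-weight on that layer (for a-d, the target's dendritic input). An edge
between paired neurons is kept iff the homolog-swapped edge also exists
and the mean of the two input fractions is ≥ the threshold (default
0.01). The mean rule deliberately rescues asymmetric edges: 0.5 % on one
side and 2 % on the other average to 1.25 % and both copies are kept.
Edges touching unpaired neurons have no mirror and are judged on their
own fraction alone (a design decision; the alternative of discarding them
would silence every unpaired neuron).

## Signal flow

Scores minimize Σ wᵢⱼ (zᵢ − zⱼ − 1)², i.e. every synapse prefers a drop
of one level from source to target. The normal equations are the
Laplacian system (D − (W + Wᵀ)) z = d_out − d_in, solved with the
pseudo-inverse (rank deficiency from translation invariance; scores are
mean-centered). Isolated nodes are excluded and reported. Agreement with
a direct weighted-least-squares oracle is verified to 1e-8.

## Signal cascades

A modified independent-cascade process: starting nodes are active at hop
0; each synapse from an active, non-stop node transmits independently
with probability p (default 0.05), so a weight-w edge fires with
probability 1 − (1−p)^w (computed via `w·log1p(−p)` for numerical
stability); a node activates at most once per run and is active for one
hop; stop nodes absorb. Defaults: max_hops 8, 1000 iterations. Per-run
random substreams are spawned from one seed, making results
bit-reproducible and order-independent. "Receives signal" means visit
probability strictly above 0.5. Derived metrics (multisensory
integration, lateralization, recurrence, cluster flow, efference-copy
reach) all reduce to cascades plus set logic; recurrence seeds one
backward cascade per downstream partner with a deterministic sub-seed.

## Joint embedding and recursive clustering

The paired subgraphs LL, RR (ipsilateral) and LR, RL (contralateral) are
indexed by homolog pair, regularized by pass-to-ranks (nonzero weights →
average ranks scaled into (0, 1]), and embedded by adjacency spectral
embedding at d1 = 24 with diagonal augmentation (degree/n). One
orthogonal Procrustes transform per hemisphere pairing (RR→LL, RL→LR),
fitted on stacked out/in positions, removes the orthogonal
non-identifiability. Out/in, ipsi/contra positions are concatenated
(8·d1 columns), reduced to d2 = 10 by SVD over both hemispheres' rows
stacked, and the two homologs' rows averaged — one position per pair, so
homologs cluster together by construction. Clustering recursively fits
1- and 2-component full-covariance Gaussian mixtures and splits when BIC
prefers two components; groups below 32 members never split and recursion
stops at depth 8. BIC ties within 1e-6 resolve to no split; child labels
are named deterministically. Defaults d1/d2/32/8 are presets sized for
brains of a few thousand neurons; on small synthetic graphs the embedding
dimension is reduced automatically (with a warning) to the matrix rank.

## Seeded graph matching

Homolog prediction maximizes trace(A P Bᵀ Pᵀ) over permutations with
known seed pairs held fixed. The Frank-Wolfe relaxation over doubly
stochastic matrices uses the seeded gradient
A₂₁B₂₁ᵀ + A₁₂ᵀB₁₂ + A₂₂DB₂₂ᵀ + A₂₂ᵀDB₂₂, a linear-assignment step
direction, and exact line search on the quadratic; the final iterate is
projected to a permutation by linear assignment. Unequal sides are padded
with isolated dummies. Many restarts (default 50) from random convex
combinations of the barycenter and a random permutation are combined into
an objective-weighted consensus matrix; a candidate's *neighbor rank* is
the rank of the true partner within its consensus row (average ranks for
ties, so 1 means top match).

## Edge statistics null models

Cross-layer reciprocity is Σ SᵢⱼTⱼᵢ / Σ Sᵢⱼ on binarized loopless
adjacencies. The overlap null model treats layers as independent
Erdős–Rényi graphs with densities p_k = ΣA⁽ᵏ⁾/n²; the expected count of
ordered pairs showing pattern x ∈ {0,1}⁴ is
m(x) = n² ∏ p_k^{x_k}(1−p_k)^{1−x_k}, which sums to n² exactly. The n²
normalization (rather than n(n−1)) is retained as the reference
formulation; at connectome scale the difference is O(1/n).

## Synthetic generator

`generate_connectome` emulates the features the analyses are sensitive
to, with planted ground truth for every structure:

- mirrored hemispheres with homolog pairs plus unpaired neurons (default
  300 pairs + 20 unpaired);
- four layers with default densities 0.028 / 0.016 / 0.004 / 0.002
  (a-d / a-a / d-d / d-a), chosen so per-type synapse fractions land near
  0.67 / 0.25 / 0.05 / 0.025 at the default size;
- truncated-geometric weights with p = 1 − √(1 − weak_edge_fraction)
  (default weak fraction 0.66, truncation 30), so about two thirds of
  edges carry ≤ 2 synapses;
- ordered blocks with a feedforward gradient (bias 0.8) from sensory
  input classes to descending outputs, within-block boost 4;
- per-pair axon laterality (ipsi/bilateral/contra = 0.61/0.24/0.15)
  rerouting only the axonal layers (a-d, a-a);
- mirror noise: a template edge is dropped from one random side with
  probability `mirror_noise` (default 0.05);
- planted, mirrored hubs (degree 25), reciprocal loop dyads, homolog pair
  loops on contralateral neurons, and descending→ascending→descending
  zigzags, all at weight 30.

What it does **not** emulate: neuron morphology and spatial structure,
synapse-level positions, correlated weight noise between homolog edges
(mirror noise is presence/absence only), hemisphere-asymmetric cell
counts, and realistic cell-type cardinalities. Two analytic consequences
worth noting: bilateral axons duplicate their template edges, inflating
realized axonal-layer density by roughly (1 + p_bilateral); and unpaired
neurons' edges are deliberately unmirrored, so perfect mirror symmetry at
`mirror_noise = 0` holds only on the paired subgraph.

`generate_skeleton` builds arbors with a designated synapse-free linker
(all postsynapses proximal, all presynapses distal) so the true split is
known by construction; random synapse-free branches are attached
elsewhere.

## Numerical choices and limitations

- Dense `numpy` arrays throughout: the intended scale (10³–10⁴ neurons)
  fits comfortably in memory and dense SVD/pinv are simpler and exactly
  reproducible. Beyond ~10⁵ nodes sparse factorizations would be needed.
- All stochastic components take explicit seeds and are bit-reproducible;
  cascades use per-run spawned substreams, matching uses one generator
  per batch of restarts.
- The Laplacian pseudo-inverse handles disconnected components by
  least-squares, which centers each component independently; cross-
  component score differences are therefore not meaningful.
- Frank-Wolfe converges to a local optimum of a relaxation; recovery is
  verified empirically on planted models, not guaranteed.
- GMM/BIC splitting inherits `scikit-learn`'s local optima; a fixed
  number of restarts (5) with deterministic seeding trades thoroughness
  for reproducibility.
- The pathway enumerator counts simple paths that stop at the first
  target reached; paths through intermediate targets are intentionally
  not counted.
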