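# Methods

## Overview

`ppienrich` tests whether a query list of genes/proteins is associated
with annotated pathways, using two complementary sources of evidence:
exact gene overlap (what classical over-representation analysis counts)
and protein–protein-interaction (PPI) proximity, captured through learned
protein embeddings.  The pipeline has three layers:

1. **Protein encoding.**  A graph neural encoder is fitted to the PPI
   network by link prediction and each protein receives a fixed-length
   embedding vector `hP`.
2. **Enrichment scoring.**  A query is scored against each pathway on the
   Pearson correlations between their proteins' embeddings, with exact
   gene overlaps up-weighted by a coefficient β.
3. **Significance.**  Scores are referred to an empirical null built from
   random gene lists of the same size, with Benjamini–Hochberg FDR
   control across the pathways of a collection.

## Enrichment score

Let the query contain N encodable proteins and a pathway M.  The raw
N × M matrix C holds the Pearson correlation between every query and
pathway embedding.  Three transformations follow, in this fixed order:

1. **Filtration** — entries not strictly above the threshold (default
   0.9) are set to zero, so only strong embedding agreement counts.
2. **Overlap masking** — if a query gene *is* a pathway gene (identifier
   equality), its matrix entry is set to exactly 1 and the rest of that
   pathway gene's column is zeroed: a shared gene contributes once, as
   overlap, and cannot additionally contribute interaction signal.
   Overlap is decided on identifiers, not on a floating-point r = 1; a
   non-identical pair whose correlation is numerically 1 is classified as
   interaction.
3. **Decomposition and weighting** — C splits into a binary overlap part
   and the residual interaction part, C = C_overlap + C_interaction, and
   the weighted score is

       WES = mean_k  max_l ( C_interaction + β · C_overlap )_{k,l}

   the mean over query proteins of each protein's best weighted match.
   β = 1 gives the plain enrichment score ES.

Useful consequences, all covered by property tests:

* 0 ≤ WES ≤ β, and WES ≤ 1 whenever there is no overlap;
* WES is non-decreasing in β (row maxima are monotone in β);
* as β → ∞, WES → β·(overlap rows)/N + (non-overlap row maxima)/N —
  large β reduces the method to coverage-driven detection, small β lets
  interaction-linked but overlap-free pathways surface;
* WES is invariant to affine rescaling of the embeddings (Pearson
  invariance), so embeddings are used raw, with no post-hoc
  normalization.

Defaults: β = 10 (a trade-off weighting both evidence channels; a scan
over β ∈ [1, 100] is available via `beta-scan`), correlation threshold
0.9 strict.

Conventions for degenerate inputs: a zero-variance embedding vector has
correlation 0 with everything (it cannot pass the filter anyway); query
or pathway genes without an embedding are dropped with a warning, and N
is the number of *retained* query rows (`missing_as_zero=True` instead
keeps dropped query genes as zero rows, dividing by the full query
size); a pathway with no encodable member gets score 0, is flagged
`skipped`, and is excluded from the multiple-testing family.  Reported
`pathway_size` (and hence coverage = overlap / pathway_size) refers to
the encodable members actually scored.

## Statistical significance

Null queries are uniform without-replacement samples from the universe
of proteins that have an embedding, matched to the encoded query size;
the same sampled lists are reused across all pathways of a run.  The
empirical p-value is p = (b + 1)/n with b the number of null scores ≥
the observed score — never zero, with floor 1/n (0.00001 at the
production default of n = 100 000; tests and scans use 500 by default
for tractability).  The ≥ in the exceedance count makes the estimator
conservative under ties.  Null scores depend on β and the threshold, so
a β scan recomputes the null per β.  BH adjustment (via statsmodels) is
applied per collection over all non-skipped pathways.

Calibration is checked by construction: when the observed query is
itself a random universe draw, the p-values are uniform up to the 1/n
discretization (KS-tested in the suite).

## Graph encoder

Architecture (numpy throughout, with hand-derived gradients verified by
finite differences in the test suite):

* **Sequence front end.**  Either (default) a trainable 1-D convolution
  (kernel 9, 32 filters) over the position-resolved 27-channel residue
  encoding (20 one-hot + 7 physicochemical group channels: aliphatic,
  aromatic, positive, negative, polar-uncharged, cysteine, proline),
  globally average-pooled over real positions; or the 20-dim residue
  composition shortcut (`sequence_pool="mean-composition"`).
* **Feature centering.**  Both front ends are centered across proteins
  (compositions additionally variance-scaled): protein feature vectors
  hover around the alphabet frequencies, and without centering the
  shared constant component dominates every embedding and destroys the
  per-protein identity that message passing needs.
* **Graph convolutions.**  Two sum-aggregation layers
  H ← relu((A + (1+ε)I) H W / d̄), where d̄ is the mean degree.  The
  global 1/d̄ rescaling keeps per-node degree contrasts (the GIN
  property) while preventing activations from growing by a factor of d̄
  per layer, which saturates the logistic decoder.
* **Objective.**  An edge (u, v) is scored σ(z_u · z_v); binary
  cross-entropy over training edges and an equal number of uniformly
  resampled non-edges per epoch; Adam, lr 0.03, 200 epochs by default.

Edges are split 80/20 into train/test.  Message passing during training
uses the **train adjacency only**, and training negatives are sampled
excluding only train edges — excluding test edges would leak the test
set (pairs never seen as negatives become identifiable) and inflates the
held-out AUC even on structureless graphs.  Validation AUC is held-out
edges vs an equal number of true non-edges.  For the exported embedding
table, inference runs on the full graph.

The embedding dimension (default 64, minimum 3 for Pearson to be
defined) is selectable by `tune_embedding_dim`, a deterministic grid
search over candidate dimensions by validation AUC with ties broken
toward the smaller dimension.  Training is deterministic under the
config seed; a single run seed fans out to the split / initialization /
negative-sampling / permutation sub-streams by fixed offsets
(`ppienrich.utils`).

Edge types (activation, binding, catalysis, ...) are collapsed to a
single "interacts" relation: downstream scoring consumes only the
embeddings.

## Synthetic data

The generators emulate the pipeline's real inputs at desk scale:

* **Topology** — a stochastic block model (default 120 nodes, 4 equal
  communities, p_in = 0.3, p_out = 0.01), a community-structured
  stand-in for a PPI network, exported in the STRING edge-list dialect.
* **Sequences** — uniform random amino-acid strings (lengths 50–200),
  giving each protein a distinctive but biologically meaningless
  sequence fingerprint.
* **Planted embeddings** — per block b, a shared vector g_b, and each
  member gets √ρ·g_b + √(1−ρ)·noise, so within-block pairwise Pearson
  correlation concentrates near ρ (default 0.95 at d = 128).  This
  surrogate lets the scoring and significance layers be validated
  independently of encoder quality.
* **Pathway scenarios** — with the query always drawn from block 0:
  `overlap_rich` pathways share half the query plus cross-block fillers
  (detectable only through overlap, increasingly so as β grows);
  `overlap_free_linked` pathways are disjoint from the query but drawn
  from its block (detectable only through correlation/interaction, and
  losing rank as β grows); `unrelated` pathways are disjoint and
  cross-block (never detectable).

What the generators deliberately do not reproduce: scale-free degree
distributions and hubs, sequence homology between interactors, biased
pathway sizes, and identifier-mapping noise between databases.  Passing
tests therefore demonstrate the correctness and the qualitative regime
behavior of the method, not performance on real STRING/MSigDB data.
In the planted world every block is internally correlated at the same ρ,
so a pathway mixing members from all blocks is "correlated with
everything"; this makes overlap-rich pathways insignificant at β = 1 by
construction, which is the intended regime contrast, not a calibration
artifact.

## Problem sizes used in the checks

Test and acceptance runs use 120-node graphs, collections of ~15
pathways, 60 training epochs for multi-seed encoder sweeps, 500
permutations for calibration (200 replicate queries), 100 000
permutations only for the p-value-floor check, 100 seeds for the
detection-regime rate and 20 seeds for encoder sweeps and rank
comparisons.

## Known limitations

* Identifier matching is exact and case-sensitive across all inputs; no
  gene-symbol ↔ protein-ID mapping layer is provided.
* The permutation null costs n_permutations × pathways score
  evaluations; the vectorised scorer keeps 100 000 permutations feasible
  for small collections, but large GMT collections call for fewer
  permutations or a pre-filtered pathway set.
* The encoder is a desk-scale dense-matrix implementation; graphs beyond
  a few thousand nodes need a sparse rewrite.
* Hyperparameters (hidden width 64, kernel 9, 32 filters) are sensible
  defaults validated on the synthetic worlds, not tuned to any real
  corpus; all are exposed in `EncoderConfig`.
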