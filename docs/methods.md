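# Methods

## Problem and model

A missense variant can abolish one specific protein–protein interaction
while leaving others intact (an *edgetic* effect). `edgetic` scores a
variant-partner triplet (i, v, p) — interactor protein i, variant v in i,
partner p — with the probability that the i–p interaction is lost.

The input representation is a residue contact graph of the two-chain
complex: one node per residue, an edge between two residues whenever any
heavy-atom pair lies within **4.5 Å** (boundary inclusive; intra- and
inter-chain contacts both count). Nodes carry per-residue protein
language-model embedding rows — the *mutant* interactor sequence for
interactor nodes, the wild-type partner sequence for partner nodes. The
variant itself is additionally encoded as the difference between the mutant
and wild-type residue embedding at the variant site, z-scored across the
training variants (population standard deviation; statistics are fitted on
training folds only and applied frozen to test data, because fitting on all
data would leak test-set statistics).

The classifier is a graph attention network:

* two multi-head GAT layers (4 heads, hidden width 128 in production,
  64 in the reduced test-scale configuration) with self-loops, ELU between
  layers and dropout 0.2;
* a mutation processor: a two-layer ReLU feed-forward network on the
  normalized mutation encoding;
* a prediction head: the post-attention representation of the mutation-site
  node concatenated with the processed mutation encoding, mapped through a
  two-layer feed-forward network to one logit and a logistic output.

Because two attention layers aggregate a 2-hop neighborhood of the mutation
site, the prediction is driven by the local structural context of the
variant rather than global protein features. Predictions for variants in
the partner protein are obtained by flipping the chain roles before model
input; the model contract itself is single-directional and rejects
mutation sites on the partner chain.

Two structural channels are appended to the node features inside the model:
a chain-role bit (interactor = 1) and the contact degree z-scored within
the graph. Softmax attention is blind to raw degree and sequence embeddings
carry no chain identity, so without these channels interface membership and
burial — the structural context the model is built to exploit — would be
invisible to the architecture. Both channels are derived from the graph
alone and can be disabled (`structural_channels=False`).

## Two-stage training

Stage 1 pretrains the model on monomeric stability data: variants with
measured folding free-energy change ΔΔG are labeled stability-preserving
when |ΔΔG| < 0.5 kcal/mol and stability-disrupting when |ΔΔG| ≥ 1.5
kcal/mol (boundary inclusive); intermediate variants are excluded. Monomer
contact graphs use the same 4.5 Å rule and the same mutation-site readout;
the binary head is shared between stages (destabilizing ↔ interaction-lost
polarity aligned). Stage 2 fine-tunes every parameter (no freezing) on
labeled variant-partner triplets.

Both stages minimize class-weighted binary cross-entropy with inverse-
frequency weights normalized to mean one, w_c = n/(2·n_c). Optimization is
Adam with decoupled weight decay (10⁻³), learning rate 10⁻³ for
pretraining and 10⁻⁴ for fine-tuning by default, batch size 32, early
stopping on a 10% validation split of the training fold (patience 10
epochs in production configurations; the synthetic-scale configurations in
the test suite use patience 15 and learning rate 10⁻³ for fine-tuning,
which converges in ~1 minute at 400 triplets). Two further regularizers
matter when embeddings are uninformative noise, as with the synthetic
embedder: train-time Gaussian noise (σ = 1.0) added to the embedding
channels of node features and to the mutation encoding — never to the
structural channels — and the weight decay above. Without them the model
memorizes variant-unique embedding rows instead of the structural rule.
Everything is implemented in numpy with hand-derived gradients (dense
masked attention; verified against finite differences in the test suite),
so training and inference are single-threaded, deterministic and
bit-reproducible under a fixed seed.

## Leakage-aware evaluation

Paired-protein inputs leak across ordinary CV splits through sequence
similarity and shared proteins. Evaluation therefore:

1. clusters variant-partner pairs by the concatenated wild-type sequences
   of both proteins at a 50% identity threshold. The built-in clustering is
   the greedy longest-first incremental scheme (identity = identical
   positions in an ungapped comparison divided by the shorter length); a
   parser for CD-HIT `.clstr` files is provided for users who run the
   external tool instead;
2. runs iterated group k-fold CV (30 iterations × 10 folds by default)
   assigning whole clusters to folds, largest cluster first into the
   lightest fold (pair-count balancing, seed-shuffled ties);
3. bins each test pair by protein sharing against that fold's training
   pairs — both shared (class 1), one (class 2), neither (class 3), the
   Park–Marcotte classes; binning is per fold because the test class is
   defined relative to the training data of the model making the
   prediction;
4. reports rank-based ROC AUC per class, size-weighted over folds and
   iterations; classes with fewer than 30 test pairs are skipped. Mean ROC
   curves are vertically averaged on a fixed 101-point FPR grid with ±SEM
   across folds.

Benchmark (blind-test) evaluation uses an ensemble of the 10 fold models
with arithmetic-mean probabilities; benchmark variants that occur in
training (same interactor and mutation, any partner) are excluded first,
and classes are assigned against the full training protein set.

## Edgotypes and enrichment

Per-variant partner-wise predictions are aggregated into an edgotype at
the 0.5 probability threshold (a probability exactly at the threshold
counts as perturbed — the natural operating point for a class-weighted
training objective): quasi-wild-type when no partner interaction is
perturbed, quasi-null when all are, edgetic otherwise. Variants with fewer
than three tested partners are dropped when the interaction catalogue
lists three or more partners; variants with small catalogues are processed
normally. The product formula Pr(quasi-null) = Π_p Pr(loss|p) is *not*
used: partner-wise probabilities are not independent and the outputs are
not calibrated against population frequencies.

Enrichment of an edgotype in a variant group relative to a baseline is the
bounded trend E = (f_obs − f_base)/(f_obs + f_base) ∈ [−1, 1], undefined
when both rates are zero (reported as not-computable, never coerced to 0).
Significance comes from bootstrap resampling (100,000 iterations by
default): variants (profiles, not variant-partner pairs — the variant is
the unit of edgotype, and partner-wise probabilities within a variant are
dependent) are resampled with replacement independently in group and
baseline; an enrichment is significant when the sign of E agrees with the
full-data point estimate in at least 1 − α/n_tests of iterations
(α = 0.05; n_tests defaults to 2 × number of compared strata; the
published analysis used 64). The 68% CI is the 16th–84th percentile of the
bootstrap distribution; the point estimate is computed on the full data,
not the bootstrap mean. Iterations where both rates are zero are discarded
and counted.

The partner-controlled mode resamples exactly three partners per variant
without replacement in every bootstrap iteration (variants with fewer
tested partners use all of them), applied symmetrically to group and
baseline to avoid asymmetric bias. Implementation note: instead of
materializing partner subsets, each resampled variant's edgotype is drawn
from the exact categorical distribution a uniform without-replacement
draw induces — P(all perturbed) = C(k,3)/C(m,3), P(none) = C(m−k,3)/C(m,3)
with k perturbed among m partners — which is distributionally identical
and much faster; the closed form is checked against exhaustive subset
enumeration in the tests.

## Synthetic data

The generators produce every input the pipeline consumes, with planted
statistical structure, so the whole system is testable offline:

* **Complexes** — two jittered straight-chain lattices (Cα every 3.8 Å plus
  one pseudo side-chain atom), chains 10 Å apart. Interface patch residues
  sit at every other position around the chain midpoint; their side-chain
  atoms reach across to 4.0 Å (inside the 4.5 Å rule) while every
  non-designed inter-chain atom pair stays beyond 6 Å, so the planted
  interface is exactly the patch.
* **PPI triplets** — random sequences, half of each pair's variants on the
  interface patch, half at least 3 positions away; label = disruptive iff
  at-interface, XOR a noise flip with probability ε (default runs use
  ε = 0.05, giving a 0.95 ceiling on achievable AUC). Pairs come in
  families of near-identical clones (≤10% divergence) so clustering and
  group CV are exercised.
* **Stability records** — monomers on a 4×4×4 lattice (spacing 4.0 Å);
  buried sites (all six orthogonal neighbors present) draw |ΔΔG| in
  [1.5, 4.0] kcal/mol, surface sites in [0, 0.5), with the same ε flip.
* **Edgotype scenarios** — per-stratum categorical draws of planted
  quasi-null/edgetic/quasi-wild-type rates, then partner probabilities
  consistent with the drawn edgotype.

The synthetic embedder hashes (seed, local k-mer context) into pseudo-
random rows, so a substitution perturbs only a ±1-residue window and the
only signal that generalizes across variants is structural. What passing
tests show is therefore that the architecture can extract interface and
burial context through the graph and that the statistical machinery is
correct — not that the model reaches its published real-data performance;
real embeddings carry evolutionary information the synthetic ones lack,
and real interfaces are not clean lattice patches.

## Problem sizes and numerical choices

The test suite trains at a reduced scale chosen to keep the planted rule
recoverable while the full suite stays fast: embedding dimension 32,
hidden width 64, 400 triplets (40 pairs × 10 variants), 320 stability
variants (20 monomers × 16), up to 100 epochs. Seed-to-seed spread of
held-out AUC at this scale is about ±0.01, so comparisons between training
arms (e.g. pretrained vs from-scratch) are made as means over three seeds
with a 0.02 allowance. Bootstrap checks use 10,000 iterations; the CV
audit runs 3 iterations × 10 folds with a fast logistic baseline trainer,
which exercises identical fold construction to the GAT trainer.

Other numerical choices: contact detection uses a KD-tree with an exact
`d² ≤ t²` post-filter so the boundary case is included regardless of
floating-point rounding; altloc resolution keeps the highest-occupancy
conformer (ties by altloc identifier); non-standard residues map to `X`
and are embedded like any residue; zero-variance encoding dimensions
normalize to 0; logits are clipped to ±30 before the logistic so outputs
stay strictly inside (0, 1); model checkpoints are a fixed-layout binary
format (JSON header + raw float64 arrays) so that identical models produce
byte-identical files.

## Known limitations

* The model does not predict gain of interaction, only loss.
* Structure quality filtering (pLDDT/ipTM) is out of scope; callers decide
  which complexes to trust.
* The built-in clusterer approximates CD-HIT's convention with ungapped
  identity; for production-scale corpora run CD-HIT itself and feed the
  `.clstr` file through the provided parser.
* Complexes with more than two chains are not supported; select the two
  chains of interest upstream.
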