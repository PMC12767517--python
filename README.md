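# edgetic

**Interaction-specific perturbation prediction for missense variants.**

Most variant effect predictors score overall pathogenicity; they cannot say
*which* protein–protein interaction a variant breaks. Yet many
disease variants are *edgetic* — they disrupt some of a protein's
interactions while leaving others intact, rewiring the interactome rather
than removing a node. `edgetic` is a toolkit for researchers in structural
bioinformatics and network biology who want to score individual
variant–partner pairs, aggregate the scores into per-variant perturbation
patterns (edgotypes), and test whether groups of variants (e.g. a disease
cohort) are enriched for those patterns relative to a population baseline.

## The model

Each data point is a triplet (i, v, p): interactor protein i, missense
variant v in i, interaction partner p. The two-chain complex structure of
i and p (e.g. an AlphaFold3 model) is reduced to a residue contact graph —
nodes are residues, edges connect residue pairs with any heavy-atom
distance ≤ 4.5 Å. Per-residue protein language-model embeddings of the
*mutant* interactor sequence i_v and the wild-type partner p are mapped
onto the nodes, and the variant is additionally encoded as the difference
of mutant and wild-type residue embeddings at the variant site, z-scored
across training variants.

A graph attention network (two multi-head GAT layers) aggregates the
2-hop structural context of the mutation site; the mutation-site
representation, concatenated with a feed-forward encoding of the mutation
vector, yields Pr(interaction loss | i, v, p) through a logistic output.
Training is two-stage: pretraining on monomer stability labels
(stability-preserving |ΔΔG| < 0.5 kcal/mol vs disrupting |ΔΔG| ≥ 1.5
kcal/mol), then fine-tuning on labeled variant-partner triplets, both with
class-weighted cross-entropy. The network is implemented in pure numpy
with hand-derived gradients and is bit-reproducible under a fixed seed.

Evaluation is leakage-aware: variant-partner pairs are clustered by their
concatenated wild-type sequences at 50% identity, whole clusters are
assigned to folds (iterated group k-fold CV), and per-class AUC is
reported for the Park–Marcotte test classes (class 1: both proteins seen
in training; class 2: one; class 3: neither).

Downstream, per-partner predictions thresholded at 0.5 classify each
variant as quasi-wild-type (no interaction perturbed), quasi-null (all
perturbed) or edgetic (mixed), and group-level enrichment is measured by
the bounded trend

```
E = (f_obs − f_baseline) / (f_obs + f_baseline)   ∈ [−1, 1]
```

with bootstrap confidence intervals and Bonferroni-corrected
sign-consistency significance. See `docs/methods.md` for the full model
and statistical detail.

## Worked example

`examples/02_train_and_predict.py` generates 160 labeled triplets on
synthetic complexes where interface variants disrupt the interaction
(5% label noise), trains the model from scratch at reduced scale, and
scores held-out variants:

```
trained 40 epochs (best validation loss at epoch 40)
class weights: {0: 1.0, 1: 1.0}
held-out AUC: 0.956  (n = 32)

example predictions (probability of interaction loss):
  I000c1 G11L   → P000c1  [interface]  p = 0.889  label = 1
  I008c1 M9I    → P008c1  [interface]  p = 0.985  label = 1
  I009c0 C9Q    → P009c0  [interface]  p = 0.784  label = 1
  I004c0 P16I   → P004c0  [far     ]  p = 0.037  label = 0
```

Interface variants receive high loss probabilities, far-from-interface
variants low ones; at 5% label noise an AUC of ~0.95 is the ceiling.
`examples/04_edgotype_enrichment.py` takes simulated per-partner
predictions for three variant strata and prints the enrichment table:

```
enrichment vs population baseline (E, 68% CI, Bonferroni significance):
  benign-like  quasi-null  E = -0.442  [-0.579, -0.308] *
  benign-like  edgetic     E = -0.275  [-0.385, -0.171] *
  disease      quasi-null  E = +0.541  [+0.478, +0.608] *
  disease      edgetic     E = +0.285  [+0.209, +0.363] *
```

A disease-like stratum (planted quasi-null rate 0.45 vs baseline 0.10) is
strongly enriched for quasi-null effects; a benign-like stratum is
depleted. The other examples cover contact-graph construction (`01`) and
leakage-aware cross-validation (`03`).

## Command line

The `edgetic` command exposes the pipeline stages for shell use:
`make-fixtures`, `build-graph`, `embed`, `encode`, `pretrain`, `finetune`,
`predict` (with `--flip-roles` for variants on the partner protein), `cv`,
`blind-test`, `edgotype`, `enrich`. Every command writes a `.meta.json`
sidecar with the resolved configuration, its hash and the seed, and
repeated runs with the same seed produce byte-identical numeric outputs.

```bash
edgetic make-fixtures ws --seed 3
edgetic finetune -w ws --from-scratch -o model.ckpt --epochs 40
edgetic predict -w ws --model model.ckpt -o predictions.tsv
edgetic enrich --predictions ws/scenario_predictions.tsv \
    --strata ws/scenario_strata.tsv --baseline baseline -o enrichment.tsv
```

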