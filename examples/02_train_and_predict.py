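"""Train the perturbation model on planted data and score new variants.

Generates labeled variant-partner triplets where interface variants disrupt
the interaction, fine-tunes the graph-attention model from scratch at a
reduced scale, and prints held-out probabilities of interaction loss next
to the planted ground truth.
"""

import numpy as np

from edgetic import ModelConfig, finetune, roc_auc
from edgetic.features import SyntheticEmbedder
from edgetic.pipeline import featurize_pairs
from edgetic.synthetic import PlantedRule, generate_ppi_dataset

pairs, structures, _ = generate_ppi_dataset(
    n_pairs=20, variants_per_pair=8,
    rule=PlantedRule("interface-disrupts", noise=0.05, seed=7),
)
embedder = SyntheticEmbedder(dimension=32, seed=1)
examples = featurize_pairs(pairs, structures, embedder)

rng = np.random.default_rng(0)
order = rng.permutation(len(examples))
test = [examples[i] for i in order[:32]]
train = [examples[i] for i in order[32:]]

config = ModelConfig(embed_dim=32, hidden_dim=64, heads=4, epochs=40,
                     finetune_lr=1e-3, patience=10, seed=0)
model, report = finetune(None, config, train, from_scratch=True)
print(f"trained {report.final_epoch} epochs "
      f"(best validation loss at epoch {report.best_epoch})")
print(f"class weights: { {k: round(v, 3) for k, v in report.class_weights.items()} }")

probs = model.predict_many(test)
labels = [ex.label for ex in test]
print(f"held-out AUC: {roc_auc(probs, labels):.3f}  (n = {len(test)})")
print("\nexample predictions (probability of interaction loss):")
for ex, p in list(zip(test, probs))[:6]:
    site = "interface" if ex.record.source.endswith("interface") else "far     "
    print(f"  {ex.record.interactor_id} {ex.record.mutation.short():<6s} "
          f"→ {ex.record.partner_id}  [{site}]  p = {p:.3f}  label = {ex.label}")

# Interface variants should receive high loss probabilities and far-from-
# interface variants low ones; at 5% label noise an AUC near 0.95 is the
# best achievable.
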