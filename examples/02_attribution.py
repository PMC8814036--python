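"""Expected-gradient attribution of a trained translation submodel.

Trains one submodel on synthetic data, attributes three target proteins to
their inputs (encoder PCs plus each protein's own transcript features),
checks the local-accuracy decomposition, and ranks the most influential
inputs.
"""

import numpy as np

import proteotrans as pt
from proteotrans.attribution import SubmodelPredictor

cfg = pt.GenerativeConfig(n_samples=150, n_genes=300, n_proteins=100, seed=4)
dataset, _ = pt.simulate_dataset(cfg)
sub = pt.train_submodel(dataset, pt.SubmodelConfig(
    encoder_representation="pc", encoder_size=20, latent_dim=8,
    hidden_dims=(32,), max_epochs=80, patience=10, batch_size=32, seed=0))

targets = sub.protein_ids[:3]
adapter = SubmodelPredictor(sub, dataset, targets)
X = adapter.inputs
attr = pt.expected_gradient_attribution(
    adapter, X[100:], X[:100], n_draws=200, seed=0,
    input_ids=adapter.input_ids, target_ids=targets)

vals, _ = adapter.value_and_grad(X[100:])
total = attr.contributions.sum(axis=1)
delta = vals - attr.baseline_prediction[None, :]
print(f"attributed {len(targets)} proteins over {X.shape[1]} inputs "
      f"for {X.shape[0] - 100} samples")
print(f"local accuracy: max |sum(contributions) - (f - baseline)| = "
      f"{np.abs(total - delta).max():.2e} "
      f"(prediction scale {np.abs(delta).max():.2f})")

print("top 5 inputs by mean |contribution|:")
for name, score in pt.rank_inputs(attr)[:5]:
    print(f"  {name:12s} {score:.4f}")
print("-> encoder PCs carry the shared tissue-state signal; a protein's own "
      "mRNA feature appears when its direct coupling matters.")
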