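"""Train a toy peaks-to-SMILES translator and query it.

A 2+2-layer, width-32 model is overfitted on 10 small molecules (about a
minute on one CPU).  Repeated stochastic decoding of a training spectrum
then shows the certainty behaviour: a confident model emits the same
molecule nearly every time, so the unique-prediction set is tiny.
"""

import ms2mol as m

molecules = m.generate_fixture_molecules(10, seed=7)
samples = m.build_dataset(molecules, m.FragmentationConfig(min_fragment_mass=0))
print(f"{len(samples)} samples from {len(molecules)} molecules")

config = m.toy_model_config(model_width=32, n_heads=4, ff_width=64)
model = m.build_model(config, seed=1)
print(f"model: {m.count_parameters(model) / 1e6:.2f}M parameters "
      f"(full-scale configuration would be "
      f"{m.count_parameters_config(m.ModelConfig()) / 1e6:.1f}M)")

train_config = m.TrainConfig(
    batch_size=10, base_batch_size=10, model_width=32,
    warmup_steps=120, patience=80, max_epochs=80, seed=3,
)
checkpoint = m.train(model, samples, samples, train_config)
print(f"trained {len(checkpoint.history)} epochs; "
      f"final training loss {checkpoint.history[-1][1]:.4f} nats/token")

depth3 = [s for s in samples if s.depth == 3]
decoded = m.greedy_decode(model, [s.input for s in depth3])
exact = sum(d == s.molecule.smiles_canonical for d, s in zip(decoded, depth3))
print(f"greedy reconstruction from depth-3 spectra: {exact}/{len(depth3)} exact")

target = depth3[0]
preds = m.sample_predictions(model, target.input, n_runs=50, seed=11)
preds = m.formula_filter(preds, target_formula=target.molecule.formula)
print(f"\nstochastic decoding of one training spectrum (50 runs):")
print(f"  unique canonical predictions: {len(preds.unique_canonical)} "
      f"(uniqueness ratio {preds.uniqueness_ratio:.2f}; low = confident)")
print(f"  most frequent formula-matching candidate: {preds.most_frequent()}")
print(f"  true molecule:                            "
      f"{target.molecule.smiles_canonical}")
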