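"""Building a training set: fixture molecules, depth-wise augmentation,
binning and SMILES tokenization.

Every molecule contributes up to three (spectrum, SMILES) pairs — one per
fragmentation depth — and each spectrum becomes a sorted sequence of
integer 0.01-Da bin indices, the model's input tokens.
"""

import ms2mol as m

molecules = m.generate_fixture_molecules(20, seed=7)
print(f"generated {len(molecules)} unique fixture molecules, e.g.:")
for record in molecules[:3]:
    print(f"  {record.smiles_canonical:<22} {str(record.formula):<10} "
          f"[M+H]+ {record.protonated_mz:.4f}")

samples = m.build_dataset(molecules, m.FragmentationConfig(min_fragment_mass=0))
print(f"\n{len(samples)} training samples from {len(molecules)} molecules "
      f"({len(samples) / len(molecules):.1f}x augmentation)")

vocab = m.default_vocabulary()
print(f"vocabulary: {vocab.size} tokens ({len(vocab.tokens) - 65} specials + 65 symbols)")

sample = samples[2]
print(f"\nsample at depth {sample.depth} for {sample.molecule.smiles_canonical}:")
print(f"  input bins ({len(sample.input.bins)}): {sample.input.bins[:8]} ...")
tokens = [vocab.tokens[i] for i in sample.target]
print(f"  target tokens: {tokens}")
print(f"  detokenized:   {m.detokenize(sample.target, vocab)}")

train, validation = m.split(samples, n_validation=12, seed=1)
train_mols = {s.molecule.smiles_canonical for s in train}
val_mols = {s.molecule.smiles_canonical for s in validation}
print(f"\nsplit: {len(train)} train / {len(validation)} validation samples; "
      f"molecule overlap: {len(train_mols & val_mols)} (leakage-free)")
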