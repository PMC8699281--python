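"""In silico fragmentation: recursive single-bond breaking turns a
structure into a theoretical protonated fragment spectrum.

Each depth adds one more generation of bond breaks; the protonated
molecular ion is always present.  Per-peak provenance records which
fragment (atoms, formula, broken bonds) produced each m/z.
"""

import ms2mol as m

smiles = "CCCC(=O)NCCO"  # N-(2-hydroxyethyl)butanamide
config = m.FragmentationConfig(min_fragment_mass=0.0)

print(f"molecule: {smiles}")
print(f"eligible (single, non-aromatic) bonds: {len(m.eligible_bonds(smiles, config))}")

for depth, spectrum in enumerate(m.depth_series(smiles, config), start=1):
    print(f"depth {depth}: {len(spectrum.peaks):3d} peaks "
          f"(precursor {spectrum.precursor_mz:.5f})")

spectrum = m.fragment(smiles, config)
print("\nfirst five peaks with provenance:")
for mz in spectrum.peaks[:5]:
    frag = spectrum.provenance[mz][0]
    print(f"  m/z {mz:>9.5f}  {str(frag.formula):<8} depth {frag.depth} "
          f"broken {list(frag.broken_bonds)}")
print("Peak counts grow monotonically with depth: deeper recursion only")
print("adds fragments, mirroring harsher collision energies.")
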