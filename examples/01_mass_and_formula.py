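"""Mass arithmetic: canonical SMILES, monoisotopic masses, and enumerating
the molecular formulas compatible with an exact precursor mass.

At high mass resolution the exact mass of the protonated molecular ion
pins the molecular formula down to very few candidates; this is the first
filter the identification pipeline applies.
"""

import ms2mol as m

compounds = {
    "cortisol": "OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C",
    "cytosine": "Nc1ccnc(=O)[nH]1",
    "glutamine": "NC(=O)CCC(C(=O)O)N",
}

print("compound     formula    monoisotopic    [M+H]+")
for name, smiles in compounds.items():
    record = m.MoleculeRecord.from_smiles(smiles)
    print(f"{name:<12} {str(record.formula):<10} {record.monoisotopic_mass:>12.5f}"
          f"  {record.protonated_mz:>9.4f}")

# How wide is the instrument's uncertainty at 500 Da?
print(f"\n5 ppm window at 500 Da: {m.ppm_window(500, m.PpmTolerance(5)):.4f} Da")

# Which C/H/N/O formulas could produce cortisol's neutral mass?
mass = 362.2093241
formulas = m.enumerate_formulas(mass, m.PpmTolerance(5))
print(f"\nformulas within 5 ppm of {mass}:")
for f in formulas:
    deviation = (m.monoisotopic_mass(f) - mass) / mass * 1e6
    print(f"  {str(f):<12} {deviation:+6.2f} ppm")
print("The true formula (C21H30O5) is among a handful of candidates; the")
print("smallest-deviation entries are the most credible assignments.")
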