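"""Recursive in silico fragmentation producing theoretical protonated
fragment spectra.

The forward problem of mass spectrometry — predicting plausible fragments
from a structure — is far more tractable than the inverse one.  Following
the MetFrag family of methods, the engine breaks every eligible bond of a
molecule serially; each break yields either two fragments or, for a bond
inside a ring, a single ring-opened fragment with the same atoms.  The
process recurses on every fragment up to a configured depth or down to a
minimum fragment mass.  Adding an adduct shift (protonation by default) to
each surviving fragment's neutral monoisotopic mass yields a theoretical
fragmentation spectrum: a sorted, deduplicated list of m/z values with
per-peak provenance.

Hydrogen bookkeeping is deliberately naive: every atom keeps the hydrogen
count it had in the parent molecule, with no ±H transfer on cleavage.  The
approach predicts only peak presence/absence, never intensities, and
necessarily misses fragments produced by rearrangements.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

from rdkit import Chem

from ms2mol.chem import (
    ATOMIC_MASS,
    PROTON_MASS,
    MolecularFormula,
    SmilesParseError,
    _mol_from_smiles,
    monoisotopic_mass,
)

Bond = Tuple[int, int]  # (min atom idx, max atom idx) in the parent molecule

#: default adduct set: protonation only ([M+H]+)
DEFAULT_ADDUCTS: Tuple[Tuple[str, float], ...] = (("[M+H]+", PROTON_MASS),)


def _default_bond_filter(mol: Chem.Mol, bond: Chem.Bond) -> bool:
    """Single, non-aromatic bonds between two heavy atoms are breakable."""
    if bond.GetBondType() != Chem.BondType.SINGLE or bond.GetIsAromatic():
        return False
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    return a.GetAtomicNum() > 1 and b.GetAtomicNum() > 1


@dataclass(frozen=True)
class FragmentationConfig:
    max_depth: int = 3
    min_fragment_mass: float = 50.0
    bond_filter: Callable[[Chem.Mol, Chem.Bond], bool] = _default_bond_filter
    adducts: Tuple[Tuple[str, float], ...] = DEFAULT_ADDUCTS
    dedup_decimals: int = 5

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_fragment_mass < 0:
            raise ValueError("min_fragment_mass must be >= 0")
        if not self.adducts:
            raise ValueError("adduct list must be non-empty")


@dataclass(frozen=True)
class Fragment:
    """A connected piece of the parent molecule.

    ``atom_index_set`` refers to heavy-atom indices of the parent; hydrogen
    counts are frozen at the parent's values.  ``depth`` counts bond-break
    generations (0 = intact molecule); ring-opening breaks also consume a
    unit of depth even though they leave the atom set unchanged.
    """

    atom_index_set: FrozenSet[int]
    formula: MolecularFormula
    neutral_mass: float
    broken_bonds: Tuple[Bond, ...]
    depth: int

    def __post_init__(self) -> None:
        if not self.atom_index_set:
            raise ValueError("fragment atom set must be non-empty")


@dataclass(frozen=True)
class TheoreticalSpectrum:
    """Sorted unique fragment m/z values with per-peak provenance."""

    peaks: Tuple[float, ...]
    provenance: Dict[float, Tuple[Fragment, ...]]
    precursor_mz: float

    def __len__(self) -> int:
        return len(self.peaks)


class _MolGraph:
    """Heavy-atom graph with per-atom element and frozen hydrogen counts."""

    def __init__(self, mol: Chem.Mol):
        self.elements: List[str] = []
        self.h_counts: List[int] = []
        self.masses: List[float] = []
        for atom in mol.GetAtoms():
            el = atom.GetSymbol()
            h = atom.GetTotalNumHs()
            if el not in ATOMIC_MASS:
                raise ValueError(f"no monoisotopic mass for element {el!r}")
            self.elements.append(el)
            self.h_counts.append(h)
            self.masses.append(ATOMIC_MASS[el] + h * ATOMIC_MASS["H"])
        self.bonds: List[Bond] = []
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            self.bonds.append((min(i, j), max(i, j)))
        self.adjacency: Dict[int, List[Tuple[int, Bond]]] = {
            i: [] for i in range(len(self.elements))
        }
        for b in self.bonds:
            i, j = b
            self.adjacency[i].append((j, b))
            self.adjacency[j].append((i, b))

    def formula_of(self, atoms: Iterable[int]) -> MolecularFormula:
        counts: Dict[str, int] = {}
        for i in atoms:
            el = self.elements[i]
            counts[el] = counts.get(el, 0) + 1
            if self.h_counts[i]:
                counts["H"] = counts.get("H", 0) + self.h_counts[i]
        return MolecularFormula(counts)

    def mass_of(self, atoms: Iterable[int]) -> float:
        return sum(self.masses[i] for i in atoms)

    def components(
        self, atoms: FrozenSet[int], removed: FrozenSet[Bond]
    ) -> List[FrozenSet[int]]:
        """Connected components of the induced subgraph minus removed bonds."""
        seen: set = set()
        comps: List[FrozenSet[int]] = []
        for start in sorted(atoms):
            if start in seen:
                continue
            stack = [start]
            comp = set()
            while stack:
                node = stack.pop()
                if node in comp:
                    continue
                comp.add(node)
                for other, b in self.adjacency[node]:
                    if other in atoms and b not in removed and other not in comp:
                        stack.append(other)
            seen |= comp
            comps.append(frozenset(comp))
        return comps


def _as_mol(molecule: Union[str, Chem.Mol]) -> Chem.Mol:
    if isinstance(molecule, Chem.Mol):
        return molecule
    return _mol_from_smiles(molecule)


def eligible_bonds(
    molecule: Union[str, Chem.Mol], config: FragmentationConfig = FragmentationConfig()
) -> List[Bond]:
    """Bonds passing the configured predicate, ascending (min idx, max idx)."""
    mol = _as_mol(molecule)
    out: List[Bond] = []
    for bond in mol.GetBonds():
        if config.bond_filter(mol, bond):
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            out.append((min(i, j), max(i, j)))
    return sorted(out)


def _make_fragment(
    graph: _MolGraph,
    atoms: FrozenSet[int],
    broken: Tuple[Bond, ...],
    depth: int,
) -> Fragment:
    return Fragment(
        atom_index_set=atoms,
        formula=graph.formula_of(atoms),
        neutral_mass=graph.mass_of(atoms),
        broken_bonds=broken,
        depth=depth,
    )


def break_bond(
    molecule: Union[str, Chem.Mol], frag: Fragment, bond: Bond
) -> List[Fragment]:
    """Break one bond of a fragment.

    Returns two fragments partitioning the atom set when the bond is a
    bridge, or one ring-opened fragment with the identical atom set when it
    is not.  Child depth is parent depth + 1; hydrogen counts are inherited
    unchanged.
    """
    graph = molecule if isinstance(molecule, _MolGraph) else _MolGraph(_as_mol(molecule))
    bond = (min(bond), max(bond))
    if bond[0] not in frag.atom_index_set or bond[1] not in frag.atom_index_set:
        raise ValueError(f"bond {bond} is not inside the fragment")
    if bond in frag.broken_bonds:
        raise ValueError(f"bond {bond} was already broken in this fragment")
    removed = frozenset(frag.broken_bonds) | {bond}
    comps = graph.components(frag.atom_index_set, removed)
    broken = frag.broken_bonds + (bond,)
    return [
        _make_fragment(graph, comp, broken, frag.depth + 1) for comp in comps
    ]


def fragment(
    molecule: Union[str, Chem.Mol],
    config: FragmentationConfig = FragmentationConfig(),
) -> TheoreticalSpectrum:
    """Fragment a molecule recursively and return its theoretical spectrum.

    Breadth-first recursion over every eligible bond of every fragment at
    depth < ``max_depth``.  Fragments lighter than ``min_fragment_mass`` are
    discarded and not recursed; the precursor ion is always reported.  Each
    adduct shift is added to each surviving fragment's neutral mass and the
    resulting m/z values are deduplicated at ``dedup_decimals`` and sorted.

    States are revisited-once per unique (atom set, already-broken ring
    bonds) pair, which reproduces exhaustive recursion exactly while
    bounding work.
    """
    mol = _as_mol(molecule)
    graph = _MolGraph(mol)
    if not graph.elements:
        raise SmilesParseError("molecule has no heavy atoms")
    bond_set = frozenset(eligible_bonds(mol, config))

    all_atoms = frozenset(range(len(graph.elements)))
    root = _make_fragment(graph, all_atoms, (), 0)

    surviving: List[Fragment] = [root]
    queue = deque([root])
    # key: (atom set, broken ring bonds still inside the atom set)
    seen = {(root.atom_index_set, frozenset())}
    while queue:
        frag = queue.popleft()
        if frag.depth >= config.max_depth:
            continue
        candidates = sorted(
            b
            for b in bond_set
            if b[0] in frag.atom_index_set
            and b[1] in frag.atom_index_set
            and b not in frag.broken_bonds
        )
        for bond in candidates:
            for child in break_bond(graph, frag, bond):
                if child.neutral_mass < config.min_fragment_mass:
                    continue
                key = (
                    child.atom_index_set,
                    frozenset(
                        b
                        for b in child.broken_bonds
                        if b[0] in child.atom_index_set
                        and b[1] in child.atom_index_set
                    ),
                )
                if key in seen:
                    continue
                seen.add(key)
                surviving.append(child)
                queue.append(child)

    smallest_shift = min(shift for _, shift in config.adducts)
    peaks: Dict[float, List[Fragment]] = {}
    for frag in surviving:
        if frag.depth > 0 and frag.neutral_mass < config.min_fragment_mass:
            continue  # defensive; filtered above
        for _, shift in config.adducts:
            mz = round(frag.neutral_mass + shift, config.dedup_decimals)
            peaks.setdefault(mz, []).append(frag)
    precursor_mz = round(root.neutral_mass + smallest_shift, config.dedup_decimals)
    sorted_mz = tuple(sorted(peaks))
    return TheoreticalSpectrum(
        peaks=sorted_mz,
        provenance={mz: tuple(peaks[mz]) for mz in sorted_mz},
        precursor_mz=precursor_mz,
    )


def depth_series(
    molecule: Union[str, Chem.Mol],
    config: FragmentationConfig = FragmentationConfig(),
) -> List[TheoreticalSpectrum]:
    """Theoretical spectra at depths 1, 2 and 3 for one molecule.

    One (molecule, peaks) pair per bond-breaking generation is the data
    augmentation used to build training sets: early generations emulate the
    high-intensity, low-noise peaks of a real spectrum, later ones the
    noisier tail.  Every element contains the precursor ion.
    """
    if config.max_depth < 3:
        raise ValueError("depth_series requires config.max_depth >= 3")
    mol = _as_mol(molecule)
    out = []
    for depth in (1, 2, 3):
        sub = FragmentationConfig(
            max_depth=depth,
            min_fragment_mass=config.min_fragment_mass,
            bond_filter=config.bond_filter,
            adducts=config.adducts,
            dedup_decimals=config.dedup_decimals,
        )
        out.append(fragment(mol, sub))
    return out


def as_experimental(spec: TheoreticalSpectrum):
    """Wrap a theoretical spectrum as an experimental one with surrogate
    intensities.

    Peaks first produced at shallow recursion depth get the highest
    intensity (precursor highest of all), mirroring the empirical pattern
    that first-generation bond breaks correspond to the strongest, least
    noisy peaks of a measured spectrum.  This makes theoretical spectra
    usable with the top-k intensity prediction protocol.
    """
    from ms2mol.codec import ExperimentalSpectrum

    peaks = []
    for mz in spec.peaks:
        min_depth = min(f.depth for f in spec.provenance[mz])
        peaks.append((mz, float(4 - min_depth)))
    return ExperimentalSpectrum(
        peaks=tuple(peaks), precursor_mz=spec.precursor_mz, ion_mode="positive"
    )


def write_msp(
    spectra: Sequence[Tuple[str, TheoreticalSpectrum]], path: str
) -> None:
    """Write (name, spectrum) pairs as MSP blocks (NAME, PRECURSORMZ, peaks)."""
    with open(path, "w") as handle:
        for name, spec in spectra:
            handle.write(f"NAME: {name}\n")
            handle.write(f"PRECURSORMZ: {spec.precursor_mz}\n")
            handle.write(f"Num Peaks: {len(spec.peaks)}\n")
            for mz in spec.peaks:
                handle.write(f"{mz} 1.0\n")
            handle.write("\n")


def write_fragments_csv(
    spectra: Sequence[Tuple[str, TheoreticalSpectrum]], path: str
) -> None:
    """Long-format CSV: smiles, mz, formula, depth, bonds_broken."""
    import pandas as pd

    rows = []
    for smiles, spec in spectra:
        for mz in spec.peaks:
            for frag in spec.provenance[mz]:
                rows.append(
                    {
                        "smiles": smiles,
                        "mz": mz,
                        "formula": str(frag.formula),
                        "depth": frag.depth,
                        "bonds_broken": ";".join(
                            f"{i}-{j}" for i, j in frag.broken_bonds
                        ),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
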