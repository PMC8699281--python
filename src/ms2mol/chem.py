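"""Canonical SMILES, molecular formulas, monoisotopic masses and formula
enumeration from exact (precursor) mass.

High-resolution positive-mode electrospray instruments routinely deliver
better than 5 ppm mass accuracy, so the exact mass of the protonated
molecular ion [M+H]+ pins the molecular formula down to a small number of
biologically feasible candidates.  This module supplies the mass arithmetic
the rest of the package builds on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # RDKit is chatty about sanitization

#: Mass of the most abundant isotope of each element, in Da.  Full precision
#: matters: a 5 ppm window at 500 Da is only 0.0025 Da wide.
ATOMIC_MASS: Dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "F": 18.9984031627,
    "Cl": 34.968852682,
    "Br": 78.9183376,
    "I": 126.904473,
    "B": 11.0093055,
    "Si": 27.9769265327,
    "Se": 79.9165218,
    "Na": 22.98976928,
    "K": 38.9637064864,
}

#: Mass of a proton (Da); the shift applied for the [M+H]+ adduct.
PROTON_MASS: float = 1.00727646

# standard bonding valences used for the ring-plus-double-bond count
_VALENCE = {
    "H": 1, "C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
    "F": 1, "Cl": 1, "Br": 1, "I": 1, "B": 3, "Si": 4, "Se": 2,
    "Na": 1, "K": 1,
}

_FORMULA_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition: element symbol -> non-negative count.

    Implicit hydrogens are included in the counts and the net charge of the
    parent structure is taken as zero, so zwitterions (e.g. carnitines)
    contribute their full hydrogen complement.
    """

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.element_counts.items() if n}
        if any(n < 0 for n in clean.values()):
            raise ValueError(f"negative element count in {clean!r}")
        object.__setattr__(self, "element_counts", dict(clean))

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-style formula string such as ``"C21H30O5"``."""
        counts: Dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN_RE.finditer(text):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = match.end()
            el, num = match.group(1), match.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            counts[el] = counts.get(el, 0) + n
        return MolecularFormula(counts)

    def is_subformula_of(self, other: "MolecularFormula") -> bool:
        return all(n <= other[el] for el, n in self.element_counts.items())

    def __eq__(self, other: object) -> bool:
        if isinstance(other, MolecularFormula):
            return self.element_counts == other.element_counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self.element_counts.items()))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        counts = dict(self.element_counts)
        parts = []
        for el in ("C", "H"):
            if el in counts:
                n = counts.pop(el)
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(counts):
            n = counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:
        return f"MolecularFormula({str(self)!r})"


@dataclass(frozen=True)
class PpmTolerance:
    """Relative mass-accuracy window in parts per million (default 5)."""

    ppm: float = 5.0

    def __post_init__(self) -> None:
        if self.ppm <= 0:
            raise ValueError("ppm tolerance must be positive")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles:
        raise SmilesParseError(f"not a SMILES string: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES with stereo and isotope labels stripped.

    Two SMILES denoting the same connectivity map to the same output, and
    the operation is idempotent.  Stereochemistry carries no information for
    mass-spectral identification here, so it is removed up front.
    """
    mol = _mol_from_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    return Chem.MolToSmiles(mol)


def formula_of(smiles: str) -> MolecularFormula:
    """Elemental composition of a SMILES, implicit hydrogens included."""
    mol = _mol_from_smiles(smiles)
    counts: Dict[str, int] = {}
    for atom in mol.GetAtoms():
        el = atom.GetSymbol()
        counts[el] = counts.get(el, 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Sum of most-abundant-isotope masses over the formula, in Da."""
    total = 0.0
    for el, n in formula.element_counts.items():
        try:
            total += ATOMIC_MASS[el] * n
        except KeyError:
            raise ValueError(f"unknown element symbol {el!r}") from None
    return total


def ppm_window(mass: float, tol: PpmTolerance = PpmTolerance()) -> float:
    """Half-width in Da of a ppm tolerance window around ``mass``.

    At 500 Da a 5 ppm window is 0.0025 Da, comfortably inside the 0.01-Da
    bins used downstream.
    """
    if mass < 0:
        raise ValueError("mass must be non-negative")
    return mass * tol.ppm * 1e-6


def rdbe(formula: MolecularFormula) -> float:
    """Ring-plus-double-bond equivalents, 1 + Σ n_i (v_i − 2) / 2.

    For C/H/N/O this reduces to C − H/2 + N/2 + 1.  Chemically sensible
    formulas have a non-negative integer or half-integer RDBE.
    """
    total = 1.0
    for el, n in formula.element_counts.items():
        v = _VALENCE.get(el)
        if v is None:
            raise ValueError(f"no valence known for element {el!r}")
        total += n * (v - 2) / 2.0
    return total


def enumerate_formulas(
    neutral_mass: float,
    tol: PpmTolerance = PpmTolerance(),
    elements: Sequence[str] = ("C", "H", "N", "O"),
    max_counts: Optional[Mapping[str, int]] = None,
) -> List[MolecularFormula]:
    """All formulas over ``elements`` within a ppm window of a neutral mass.

    The search is exhaustive within ``max_counts`` bounds (by default each
    element is bounded by the window ceiling divided by its mass).  Formulas
    with negative ring-plus-double-bond equivalents are rejected; no
    nitrogen-rule or other heuristic filtering is applied.  Results are
    sorted by absolute mass deviation, smallest first.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    if not elements:
        raise ValueError("element set must be non-empty")
    window = ppm_window(neutral_mass, tol)
    lo, hi = neutral_mass - window, neutral_mass + window

    # heaviest first, hydrogen last: tightest pruning
    order = sorted(set(elements), key=lambda el: -ATOMIC_MASS[el])
    bounds = {}
    for el in order:
        cap = int((hi) // ATOMIC_MASS[el])
        if max_counts and el in max_counts:
            cap = min(cap, int(max_counts[el]))
        bounds[el] = cap

    out: List[MolecularFormula] = []
    counts: Dict[str, int] = {}

    def descend(idx: int, mass_so_far: float) -> None:
        if idx == len(order):
            if lo <= mass_so_far <= hi:
                f = MolecularFormula(counts)
                if f.element_counts and rdbe(f) >= 0:
                    out.append(f)
            return
        el = order[idx]
        el_mass = ATOMIC_MASS[el]
        remaining_min = 0.0  # all remaining elements may be absent
        for n in range(bounds[el] + 1):
            mass = mass_so_far + n * el_mass
            if mass + remaining_min > hi:
                break
            counts[el] = n
            descend(idx + 1, mass)
        counts.pop(el, None)

    descend(0, 0.0)
    out.sort(key=lambda f: (abs(monoisotopic_mass(f) - neutral_mass), str(f)))
    return out


@dataclass(frozen=True)
class MoleculeRecord:
    """A molecule with its canonical SMILES, formula and monoisotopic mass."""

    smiles_raw: str
    smiles_canonical: str
    formula: MolecularFormula
    monoisotopic_mass: float
    source_tag: str = ""

    @classmethod
    def from_smiles(cls, smiles: str, source_tag: str = "") -> "MoleculeRecord":
        canonical = canonicalize(smiles)
        f = formula_of(canonical)
        return cls(
            smiles_raw=smiles,
            smiles_canonical=canonical,
            formula=f,
            monoisotopic_mass=monoisotopic_mass(f),
            source_tag=source_tag,
        )

    @property
    def protonated_mz(self) -> float:
        """m/z of the [M+H]+ ion."""
        return self.monoisotopic_mass + PROTON_MASS


def read_smiles(path: str, column: str = "smiles", source_tag: str = "") -> List[MoleculeRecord]:
    """Read molecules from plain text (one SMILES per line) or CSV.

    Files ending in ``.csv`` are read with pandas and ``column`` selects the
    SMILES column; anything else is treated as one SMILES per line with
    blank lines and ``#`` comments skipped.
    """
    smiles_list: List[str]
    if str(path).lower().endswith(".csv"):
        import pandas as pd

        frame = pd.read_csv(path)
        if column not in frame.columns:
            raise KeyError(f"column {column!r} not found in {path}")
        smiles_list = [str(s) for s in frame[column].dropna()]
    else:
        with open(path) as handle:
            smiles_list = [
                line.strip() for line in handle
                if line.strip() and not line.lstrip().startswith("#")
            ]
    return [MoleculeRecord.from_smiles(s, source_tag=source_tag) for s in smiles_list]


def write_records_csv(records: Iterable[MoleculeRecord], path: str) -> None:
    """Write records as CSV with smiles_canonical, formula, monoisotopic_mass."""
    import pandas as pd

    recs = list(records)
    frame = pd.DataFrame(
        {
            "smiles_canonical": [r.smiles_canonical for r in recs],
            "formula": [str(r.formula) for r in recs],
            "monoisotopic_mass": [r.monoisotopic_mass for r in recs],
        }
    )
    frame.to_csv(path, index=False)
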