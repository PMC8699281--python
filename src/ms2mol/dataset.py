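"""Molecule filtering, depth-wise augmentation, SMILES tokenization and
train/validation assembly, plus a bundled fixture-molecule generator.

Each molecule contributes up to three training samples, one per
bond-breaking generation of the fragmenter (depths 1-3).  Early generations
emulate the strong, clean peaks of a real spectrum; deeper ones the noisier
tail — so the augmentation teaches the model to prioritise informative
peaks.  Samples whose binned peak list exceeds the maximum input length of
100 are dropped individually.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from rdkit import Chem

from ms2mol.chem import MoleculeRecord, canonicalize
from ms2mol.codec import BinnedSpectrum, BinningConfig, encode_spectrum
from ms2mol.fragment import FragmentationConfig, depth_series, eligible_bonds

# ---------------------------------------------------------------------------
# vocabulary

SOS, EOS, UNK, PAD = "<sos>", "<eos>", "<unk>", "<pad>"
SPECIAL_TOKENS = (SOS, EOS, UNK, PAD)  # fixed ids 0..3

# 65 content tokens.  SMILES is split into atom symbols (two-letter symbols
# such as Cl and Br are single tokens) and structural characters; bracket
# expressions are tokenized character-wise, so charges, explicit hydrogens
# and ring bonds all round-trip by plain concatenation.  The content set is
# frozen as a versioned artifact; its exact membership beyond the organic
# subset is a coverage reserve for library data.
_CONTENT_TOKENS = (
    # two-letter element symbols (single tokens, also inside brackets)
    "Cl", "Br", "Si", "Se", "Na", "Li", "Mg", "Al", "Ca", "Fe",
    "Zn", "Cu", "Mn", "As", "Sn", "Ag", "Te", "Ba", "Sr", "Ni",
    # one-letter element symbols
    "B", "C", "N", "O", "P", "S", "F", "I", "H", "K",
    # aromatic atoms
    "b", "c", "n", "o", "p", "s", "se", "si",
    # ring-closure digits and the %nn two-digit marker
    "0", "1", "2", "3", "4", "5", "6", "7", "8", "9", "%",
    # bonds, branches, charges, brackets and misc structural characters
    "-", "=", "#", ":", "(", ")", "[", "]", "+", "/", "\\", ".",
    "@", "*", "$", "~",
)
assert len(_CONTENT_TOKENS) == 65


@dataclass(frozen=True)
class Vocabulary:
    """Token inventory with the four special tokens pinned at ids 0-3."""

    tokens: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tokens[:4] != SPECIAL_TOKENS:
            raise ValueError("tokens must start with <sos>, <eos>, <unk>, <pad>")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        object.__setattr__(
            self, "_token_to_id", {t: i for i, t in enumerate(self.tokens)}
        )

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def sos_id(self) -> int:
        return 0

    @property
    def eos_id(self) -> int:
        return 1

    @property
    def unk_id(self) -> int:
        return 2

    @property
    def pad_id(self) -> int:
        return 3

    def id_of(self, token: str) -> int:
        return self._token_to_id.get(token, self.unk_id)

    def __contains__(self, token: str) -> bool:
        return token in self._token_to_id


def default_vocabulary() -> Vocabulary:
    """The frozen 69-token vocabulary: 4 specials + 65 content tokens."""
    return Vocabulary(SPECIAL_TOKENS + _CONTENT_TOKENS)


_TWO_LETTER = tuple(t for t in _CONTENT_TOKENS if len(t) == 2 and t[0].isupper())
_TWO_LETTER_ORGANIC = ("Cl", "Br")  # only these occur outside brackets


def split_smiles(smiles: str) -> List[str]:
    """Split a SMILES string into vocabulary tokens.

    Outside brackets only Cl and Br are two-character tokens; inside a
    bracket expression any two-letter element symbol is matched greedily and
    the remaining characters (charges, digits, H counts) tokenize singly.
    Detokenization is plain concatenation.
    """
    tokens: List[str] = []
    i = 0
    in_bracket = False
    while i < len(smiles):
        two = smiles[i : i + 2]
        if in_bracket and two in _TWO_LETTER:
            tokens.append(two)
            i += 2
            continue
        if not in_bracket and two in _TWO_LETTER_ORGANIC:
            tokens.append(two)
            i += 2
            continue
        ch = smiles[i]
        if ch == "[":
            in_bracket = True
        elif ch == "]":
            in_bracket = False
        tokens.append(ch)
        i += 1
    return tokens


def tokenize(smiles: str, vocab: Optional[Vocabulary] = None) -> Tuple[int, ...]:
    """Token-id sequence for a SMILES: <sos>, symbols, <eos>.

    Symbols outside the vocabulary map to <unk>; use :func:`unk_fraction`
    to audit coverage.
    """
    vocab = vocab or default_vocabulary()
    ids = [vocab.sos_id]
    ids.extend(vocab.id_of(t) for t in split_smiles(smiles))
    ids.append(vocab.eos_id)
    return tuple(ids)


def detokenize(ids: Sequence[int], vocab: Optional[Vocabulary] = None) -> str:
    """Inverse of :func:`tokenize`; stops at <eos>, drops special tokens."""
    vocab = vocab or default_vocabulary()
    out: List[str] = []
    for i in ids:
        if i == vocab.eos_id:
            break
        if i in (vocab.sos_id, vocab.pad_id):
            continue
        if i == vocab.unk_id:
            out.append("?")
            continue
        out.append(vocab.tokens[i])
    return "".join(out)


def unk_fraction(ids: Sequence[int], vocab: Optional[Vocabulary] = None) -> float:
    """Fraction of non-special positions mapped to <unk>."""
    vocab = vocab or default_vocabulary()
    content = [i for i in ids if i not in (vocab.sos_id, vocab.eos_id, vocab.pad_id)]
    if not content:
        return 0.0
    return sum(1 for i in content if i == vocab.unk_id) / len(content)


# ---------------------------------------------------------------------------
# filtering and dataset assembly


@dataclass(frozen=True)
class FilterConfig:
    max_precursor_mz: float = 500.0
    max_smiles_len: int = 99
    max_peaks: int = 100

    def __post_init__(self) -> None:
        if min(self.max_precursor_mz, self.max_smiles_len, self.max_peaks) <= 0:
            raise ValueError("filter bounds must be positive")


def filter_molecule(
    record: MoleculeRecord,
    n_peaks: int,
    config: FilterConfig = FilterConfig(),
    seen: Optional[Set[str]] = None,
) -> Tuple[bool, Optional[str]]:
    """Apply the dataset admission rules; returns (passed, first failing rule).

    Rules, in order: protonated-precursor m/z above the cap; canonical
    SMILES longer than the cap (measured in characters); more peaks than
    the cap; duplicate canonical SMILES already in ``seen``.  When the
    record passes and ``seen`` is given, its SMILES is added to ``seen``.
    """
    if record.protonated_mz > config.max_precursor_mz:
        return False, "max_precursor_mz"
    if len(record.smiles_canonical) > config.max_smiles_len:
        return False, "max_smiles_len"
    if n_peaks > config.max_peaks:
        return False, "max_peaks"
    if seen is not None:
        if record.smiles_canonical in seen:
            return False, "duplicate"
        seen.add(record.smiles_canonical)
    return True, None


@dataclass(frozen=True)
class TrainingSample:
    """One (binned spectrum, SMILES token sequence) pair at a given depth."""

    input: BinnedSpectrum
    target: Tuple[int, ...]
    depth: int
    molecule: MoleculeRecord

    def __post_init__(self) -> None:
        if self.depth not in (1, 2, 3):
            raise ValueError("depth must be 1, 2 or 3")


def build_dataset(
    molecules: Sequence[MoleculeRecord],
    frag_config: FragmentationConfig = FragmentationConfig(),
    filter_config: FilterConfig = FilterConfig(),
    vocab: Optional[Vocabulary] = None,
    binning: BinningConfig = BinningConfig(),
) -> List[TrainingSample]:
    """Depth-wise augmented training set: up to 3 samples per molecule.

    Each molecule is fragmented at depths 1, 2 and 3; a depth's sample is
    dropped when its binned peak list exceeds ``filter_config.max_peaks``
    bins.  Molecules failing the admission rules (including global
    duplicate removal) contribute nothing.
    """
    vocab = vocab or default_vocabulary()
    seen: Set[str] = set()
    samples: List[TrainingSample] = []
    for record in molecules:
        passed, _ = filter_molecule(record, 0, filter_config, seen)
        if not passed:
            continue
        target = tokenize(record.smiles_canonical, vocab)
        for depth, spectrum in enumerate(depth_series(record.smiles_canonical, frag_config), start=1):
            in_range = [mz for mz in spectrum.peaks if 0 < mz < binning.mz_max]
            bins = sorted({int(np.floor(mz * binning.scale + 1e-7)) for mz in in_range})
            if len(bins) > filter_config.max_peaks:
                continue
            samples.append(
                TrainingSample(
                    input=BinnedSpectrum(tuple(bins)),
                    target=target,
                    depth=depth,
                    molecule=record,
                )
            )
    return samples


def split(
    dataset: Sequence[TrainingSample], n_validation: int, seed: int
) -> Tuple[List[TrainingSample], List[TrainingSample]]:
    """Reproducible train/validation split with no molecule straddling it.

    Molecules (not samples) are shuffled under ``seed`` and assigned to the
    validation side until it holds at least ``n_validation`` samples; all
    depth-variants of one molecule land on the same side, so validation
    loss measures generalisation to unseen structures rather than unseen
    depths.
    """
    if n_validation >= len(dataset):
        raise ValueError("n_validation must be smaller than the dataset")
    by_molecule: Dict[str, List[TrainingSample]] = {}
    order: List[str] = []
    for sample in dataset:
        key = sample.molecule.smiles_canonical
        if key not in by_molecule:
            by_molecule[key] = []
            order.append(key)
        by_molecule[key].append(sample)
    rng = np.random.default_rng(seed)
    shuffled = list(order)
    rng.shuffle(shuffled)
    validation: List[TrainingSample] = []
    train: List[TrainingSample] = []
    for key in shuffled:
        if len(validation) < n_validation:
            validation.extend(by_molecule[key])
        else:
            train.extend(by_molecule[key])
    return train, validation


# ---------------------------------------------------------------------------
# fixture-molecule generator

_AROMATIC_SCAFFOLDS = (
    "c1ccccc1",      # benzene
    "c1ccncc1",      # pyridine
    "c1ccoc1",       # furan
    "c1cc[nH]c1",    # pyrrole
    "c1cnc[nH]1",    # imidazole
)

_VALENCE_CAP = {"C": 4, "N": 3, "O": 2}


def _random_tree_molecule(rng: np.random.Generator, n_heavy: int) -> Optional[str]:
    """Grow a random acyclic C/N/O skeleton, optionally closing one ring
    and adding one carbonyl, and return its SMILES (None on failure)."""
    mol = Chem.RWMol()
    symbols = ["C"]
    mol.AddAtom(Chem.Atom("C"))
    used = [0]
    for _ in range(n_heavy - 1):
        el = rng.choice(["C", "N", "O"], p=[0.60, 0.18, 0.22])
        free = [i for i in range(len(symbols)) if _VALENCE_CAP[symbols[i]] - used[i] >= 1]
        if not free:
            return None
        parent = int(free[rng.integers(len(free))])
        idx = mol.AddAtom(Chem.Atom(str(el)))
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        symbols.append(str(el))
        used.append(1)
        used[parent] += 1
    # one ring closure between non-adjacent atoms with spare valence
    if rng.random() < 0.35 and len(symbols) >= 4:
        adjacency = {
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
        } | {(b.GetEndAtomIdx(), b.GetBeginAtomIdx()) for b in mol.GetBonds()}
        pairs = [
            (i, j)
            for i in range(len(symbols))
            for j in range(i + 1, len(symbols))
            if (i, j) not in adjacency
            and _VALENCE_CAP[symbols[i]] - used[i] >= 1
            and _VALENCE_CAP[symbols[j]] - used[j] >= 1
        ]
        if pairs:
            i, j = pairs[int(rng.integers(len(pairs)))]
            mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
            used[i] += 1
            used[j] += 1
    # one carbonyl oxygen on a carbon with two spare valences
    if rng.random() < 0.45:
        carbons = [
            i for i in range(len(symbols))
            if symbols[i] == "C" and _VALENCE_CAP["C"] - used[i] >= 2
        ]
        if carbons:
            i = int(carbons[rng.integers(len(carbons))])
            o = mol.AddAtom(Chem.Atom("O"))
            mol.AddBond(i, o, Chem.BondType.DOUBLE)
            used[i] += 2
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def _decorated_aromatic(rng: np.random.Generator, n_extra: int) -> Optional[str]:
    """An aromatic scaffold with a few single-bonded C/N/O substituents."""
    scaffold = _AROMATIC_SCAFFOLDS[int(rng.integers(len(_AROMATIC_SCAFFOLDS)))]
    base = Chem.MolFromSmiles(scaffold)
    mol = Chem.RWMol(base)
    capacity = {a.GetIdx(): a.GetTotalNumHs() for a in base.GetAtoms()}
    symbols: List[str] = []
    used: List[int] = []
    index_map: List[int] = []  # added-atom position -> mol index
    for _ in range(n_extra):
        el = str(rng.choice(["C", "N", "O"], p=[0.65, 0.15, 0.20]))
        ring_sites = [i for i, h in capacity.items() if h >= 1]
        chain_sites = [
            k for k in range(len(symbols)) if _VALENCE_CAP[symbols[k]] - used[k] >= 1
        ]
        total = len(ring_sites) + len(chain_sites)
        if total == 0:
            break
        pick = int(rng.integers(total))
        idx = mol.AddAtom(Chem.Atom(el))
        if pick < len(ring_sites):
            parent = ring_sites[pick]
            capacity[parent] -= 1
        else:
            k = chain_sites[pick - len(ring_sites)]
            parent = index_map[k]
            used[k] += 1
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        symbols.append(el)
        used.append(1)
        index_map.append(idx)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def generate_fixture_molecules(
    n: int,
    seed: int,
    min_heavy: int = 5,
    max_heavy: int = 10,
) -> List[MoleculeRecord]:
    """Generate ``n`` unique, valid, canonical fixture molecules.

    The grammar draws small organic structures over C/H/N/O — random
    branched skeletons with optional single rings and carbonyls, plus
    substituted five- and six-membered aromatic scaffolds — in the size
    range typical of the metabolite-like molecules the method targets.
    Every product parses, has a protonated m/z far below 500, carries at
    least one breakable bond, and the list is reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records: List[MoleculeRecord] = []
    seen: Set[str] = set()
    attempts = 0
    while len(records) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("fixture generation failed to converge")
        n_heavy = int(rng.integers(min_heavy, max_heavy + 1))
        if rng.random() < 0.30:
            smiles = _decorated_aromatic(rng, max(n_heavy - 5, 1))
        else:
            smiles = _random_tree_molecule(rng, n_heavy)
        if smiles is None:
            continue
        try:
            record = MoleculeRecord.from_smiles(smiles, source_tag="fixture")
        except Exception:
            continue
        if record.smiles_canonical in seen:
            continue
        if record.protonated_mz >= 500 or len(record.smiles_canonical) > 99:
            continue
        if not eligible_bonds(record.smiles_canonical):
            continue
        seen.add(record.smiles_canonical)
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# serialization


def write_dataset(samples: Sequence[TrainingSample], path: str,
                  vocab: Optional[Vocabulary] = None) -> None:
    """TSV with bins (comma-joined), target SMILES and depth, plus a JSON
    sidecar (same path + ``.json``) holding the vocabulary."""
    vocab = vocab or default_vocabulary()
    with open(path, "w") as handle:
        handle.write("bins\tsmiles\tdepth\n")
        for s in samples:
            bins = ",".join(str(b) for b in s.input.bins)
            handle.write(f"{bins}\t{s.molecule.smiles_canonical}\t{s.depth}\n")
    with open(path + ".json", "w") as handle:
        json.dump({"vocabulary": list(vocab.tokens)}, handle, indent=1)


def load_dataset(path: str) -> List[TrainingSample]:
    """Inverse of :func:`write_dataset` (vocabulary from the sidecar)."""
    with open(path + ".json") as handle:
        vocab = Vocabulary(tuple(json.load(handle)["vocabulary"]))
    out: List[TrainingSample] = []
    with open(path) as handle:
        next(handle)  # header
        for line in handle:
            bins_text, smiles, depth = line.rstrip("\n").split("\t")
            bins = tuple(int(b) for b in bins_text.split(",")) if bins_text else ()
            record = MoleculeRecord.from_smiles(smiles)
            out.append(
                TrainingSample(
                    input=BinnedSpectrum(bins),
                    target=tokenize(smiles, vocab),
                    depth=int(depth),
                    molecule=record,
                )
            )
    return out
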