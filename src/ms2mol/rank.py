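"""Candidate post-processing: round-trip ranking, TYPICAL multi-fingerprint
similarity, the top-k intensity protocol for experimental spectra, and
CASMI-style filtering and scoring.

Round-tripping closes the loop between the forward and inverse problems:
every candidate structure is re-fragmented in silico and its theoretical
spectrum scored against the query peak list with binned cosine similarity.
The TYPICAL similarity guards against any single fingerprint's blind
spots by taking the maximum Tanimoto over six encodings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from rdkit import Chem
from rdkit import DataStructs
from rdkit.Chem import AllChem, MACCSkeys

from ms2mol.chem import (
    MolecularFormula,
    MoleculeRecord,
    PpmTolerance,
    canonicalize,
    _mol_from_smiles,
)
from ms2mol.codec import (
    BinnedSpectrum,
    BinningConfig,
    ExperimentalSpectrum,
    encode_spectrum,
)
from ms2mol.fragment import FragmentationConfig, fragment
from ms2mol.model import (
    PredictionSet,
    Seq2SeqTransformer,
    formula_filter,
    merge_prediction_sets,
    sample_predictions,
)

# ---------------------------------------------------------------------------
# fingerprints


def _fp_rdkit(mol):
    return Chem.RDKFingerprint(mol)


def _fp_atom_pair(mol):
    return AllChem.GetHashedAtomPairFingerprintAsBitVect(mol, nBits=2048)


def _fp_torsion(mol):
    return AllChem.GetHashedTopologicalTorsionFingerprintAsBitVect(mol, nBits=2048)


def _fp_maccs(mol):
    return MACCSkeys.GenMACCSKeys(mol)


def _fp_morgan(mol):
    return AllChem.GetMorganFingerprintAsBitVect(mol, 2, nBits=2048)


def _fp_pattern(mol):
    return Chem.PatternFingerprint(mol)


FINGERPRINTS = {
    "rdkit": _fp_rdkit,
    "atom_pair": _fp_atom_pair,
    "torsion": _fp_torsion,
    "maccs": _fp_maccs,
    "morgan": _fp_morgan,
    "pattern": _fp_pattern,
}


@dataclass(frozen=True)
class EvalConfig:
    ts_close_cutoff: float = 0.8
    ts_high_cutoff: float = 0.9
    n_runs_per_k: int = 300
    fingerprints: Tuple[str, ...] = (
        "rdkit", "atom_pair", "torsion", "maccs", "morgan", "pattern"
    )

    def __post_init__(self) -> None:
        if not (0 < self.ts_close_cutoff <= 1 and 0 < self.ts_high_cutoff <= 1):
            raise ValueError("similarity cutoffs must lie in (0, 1]")


def tanimoto(a: Union[str, Chem.Mol], b: Union[str, Chem.Mol],
             fingerprint: str = "rdkit") -> float:
    """Tanimoto (Jaccard) coefficient under one named fingerprint."""
    mol_a = a if isinstance(a, Chem.Mol) else _mol_from_smiles(a)
    mol_b = b if isinstance(b, Chem.Mol) else _mol_from_smiles(b)
    fn = FINGERPRINTS[fingerprint]
    return DataStructs.TanimotoSimilarity(fn(mol_a), fn(mol_b))


def typical_similarity(
    a: Union[str, Chem.Mol],
    b: Union[str, Chem.Mol],
    config: EvalConfig = EvalConfig(),
) -> Tuple[float, str]:
    """Maximum Tanimoto over the configured fingerprint encodings.

    Returns (score, encoding that attained it).  A failing encoding is
    skipped with a warning; if every encoding fails an error is raised.
    """
    mol_a = a if isinstance(a, Chem.Mol) else _mol_from_smiles(a)
    mol_b = b if isinstance(b, Chem.Mol) else _mol_from_smiles(b)
    best, best_name = -1.0, ""
    for name in config.fingerprints:
        fn = FINGERPRINTS[name]
        try:
            score = DataStructs.TanimotoSimilarity(fn(mol_a), fn(mol_b))
        except Exception as exc:  # fingerprint failure on exotic structures
            warnings.warn(f"fingerprint {name!r} failed: {exc}", stacklevel=2)
            continue
        if score > best:
            best, best_name = score, name
    if best < 0:
        raise RuntimeError("every fingerprint encoding failed")
    return best, best_name


# ---------------------------------------------------------------------------
# round-trip ranking


@dataclass(frozen=True)
class RankedCandidates:
    """Candidates ordered by round-trip cosine, then frequency, then SMILES."""

    entries: Tuple[Tuple[MoleculeRecord, float, int], ...]

    def __len__(self) -> int:
        return len(self.entries)

    def top(self) -> MoleculeRecord:
        return self.entries[0][0]


def roundtrip_rank(
    candidates: Sequence[Union[str, MoleculeRecord]],
    query: Union[BinnedSpectrum, Sequence[float]],
    frag_config: FragmentationConfig = FragmentationConfig(),
    binning: BinningConfig = BinningConfig(),
    frequencies: Optional[Dict[str, int]] = None,
) -> RankedCandidates:
    """Rank candidates by cosine between their theoretical spectra and a query.

    Each candidate is fragmented, binned (peaks at or above the binning
    ceiling are ignored) and scored against the query.  A candidate that
    fails fragmentation scores 0 with a warning.  Ordering is cosine
    descending, prediction frequency descending, canonical SMILES ascending
    — total and deterministic.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if not isinstance(query, BinnedSpectrum):
        query = encode_spectrum(
            [mz for mz in query if 0 < mz < binning.mz_max], binning
        )
    entries: List[Tuple[MoleculeRecord, float, int]] = []
    for cand in candidates:
        try:
            record = (
                cand
                if isinstance(cand, MoleculeRecord)
                else MoleculeRecord.from_smiles(cand)
            )
        except Exception as exc:
            warnings.warn(
                f"candidate {cand!r} failed round-trip: {exc}", stacklevel=2
            )
            entries.append(
                (
                    MoleculeRecord(
                        smiles_raw=str(cand),
                        smiles_canonical=str(cand),
                        formula=MolecularFormula({}),
                        monoisotopic_mass=0.0,
                    ),
                    0.0,
                    0,
                )
            )
            continue
        freq = (frequencies or {}).get(record.smiles_canonical, 0)
        try:
            spec = fragment(record.smiles_canonical, frag_config)
            bins = encode_spectrum(
                [mz for mz in spec.peaks if 0 < mz < binning.mz_max], binning
            )
            score = (
                len(set(bins.bins) & set(query.bins))
                / (len(bins.bins) * len(query.bins)) ** 0.5
                if bins.bins and query.bins
                else 0.0
            )
        except Exception as exc:
            warnings.warn(
                f"candidate {record.smiles_canonical!r} failed round-trip: {exc}",
                stacklevel=2,
            )
            score = 0.0
        entries.append((record, score, freq))
    entries.sort(key=lambda e: (-e[1], -e[2], e[0].smiles_canonical))
    return RankedCandidates(tuple(entries))


# ---------------------------------------------------------------------------
# top-k intensity protocol


def topk_procedure(
    spectrum: ExperimentalSpectrum,
    model: Seq2SeqTransformer,
    target_formula: Optional[MolecularFormula] = None,
    precursor_mz: Optional[float] = None,
    config: EvalConfig = EvalConfig(),
    binning: BinningConfig = BinningConfig(),
    tol: PpmTolerance = PpmTolerance(),
    seed: int = 0,
) -> Tuple[PredictionSet, Optional[str]]:
    """Iterated prediction over top-k intensity prefixes of a real spectrum.

    High-intensity peaks are empirically the trustworthy ones; noise grows
    as intensity falls.  For k = 1..n_peaks the k most intense peaks are
    taken (intensity ties broken toward lower m/z), sorted ascending in
    m/z, encoded and decoded ``n_runs_per_k`` times; each round's
    predictions are formula-filtered and the rounds are pooled with summed
    frequencies.  The final candidate is the most frequent canonical
    SMILES, or None when nothing with the right formula was ever produced
    (the explicit "no prediction" outcome).
    """
    if not spectrum.has_intensities:
        raise ValueError(
            "top-k iteration needs peak intensities; supply an ordered peak "
            "list or intensities"
        )
    if not (1 <= len(spectrum.peaks) <= 100):
        raise ValueError("spectrum must hold between 1 and 100 peaks")
    if target_formula is None and precursor_mz is None:
        raise ValueError("supply target_formula or precursor_mz")
    by_intensity = sorted(spectrum.peaks, key=lambda p: (-p[1], p[0]))
    rounds: List[PredictionSet] = []
    for k in range(1, len(by_intensity) + 1):
        mzs = sorted(mz for mz, _ in by_intensity[:k])
        usable = [mz for mz in mzs if 0 < mz < binning.mz_max]
        if not usable:
            continue
        bins = encode_spectrum(usable, binning)
        preds = sample_predictions(model, bins, config.n_runs_per_k, seed=seed + k)
        preds = formula_filter(
            preds, precursor_mz=precursor_mz, tol=tol, target_formula=target_formula
        )
        rounds.append(preds)
    merged = merge_prediction_sets(rounds)
    final = None
    if merged.formula_filtered:
        final = min(
            merged.formula_filtered,
            key=lambda s: (-merged.formula_filtered[s], s),
        )
    return merged, final


# ---------------------------------------------------------------------------
# CASMI-style filtering and scoring


def casmi_filter(
    challenges: Sequence[Tuple[Sequence[Tuple[float, Optional[float]]], str, str]],
    mz_max: float = 500.0,
    max_peaks: int = 100,
    max_smiles_len: int = 100,
) -> Tuple[List[int], Dict[str, int]]:
    """Select evaluable challenges; count rejections per rule.

    A challenge is a (peak list, ion mode, truth SMILES) triple.  Rules in
    application order: positive ion mode; every peak m/z strictly below
    ``mz_max``; peak count strictly below ``max_peaks``; SMILES length
    strictly below ``max_smiles_len``.  Returns the indices of retained
    challenges plus the per-rule rejection counts.
    """
    counts = {"malformed": 0, "ion_mode": 0, "mz_range": 0,
              "peak_count": 0, "smiles_length": 0, "retained": 0}
    kept: List[int] = []
    for idx, challenge in enumerate(challenges):
        try:
            peaks, mode, smiles = challenge
            mzs = [float(p[0]) for p in peaks]
        except Exception as exc:
            warnings.warn(f"challenge {idx} malformed: {exc}", stacklevel=2)
            counts["malformed"] += 1
            continue
        if not str(mode).strip().lower().startswith("pos"):
            counts["ion_mode"] += 1
            continue
        if any(mz >= mz_max for mz in mzs):
            counts["mz_range"] += 1
            continue
        if len(mzs) >= max_peaks:
            counts["peak_count"] += 1
            continue
        if len(str(smiles)) >= max_smiles_len:
            counts["smiles_length"] += 1
            continue
        counts["retained"] += 1
        kept.append(idx)
    return kept, counts


@dataclass(frozen=True)
class CasmiOutcome:
    """Challenge verdict: correct, unknown (formula-only), or no_prediction."""

    category: str
    best_ts: float
    best_prediction: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in ("correct", "unknown", "no_prediction"):
            raise ValueError(f"bad category {self.category!r}")


def casmi_score(
    predictions: PredictionSet,
    truth_smiles: str,
    config: EvalConfig = EvalConfig(),
    use_typical: bool = False,
) -> CasmiOutcome:
    """Score a formula-filtered prediction set against the truth.

    ``correct`` when some prediction's canonical SMILES equals the truth's
    (best_ts = 1 by construction); ``no_prediction`` when the
    formula-filtered set is empty; otherwise ``unknown``, with the highest
    Tanimoto similarity reported for diagnosis.  By default the similarity
    uses the path-based fingerprint alone; ``use_typical`` switches to the
    six-encoding maximum.
    """
    truth = canonicalize(truth_smiles)
    pool = (
        predictions.formula_filtered
        if predictions.formula_filtered is not None
        else predictions.unique_canonical
    )
    if not pool:
        return CasmiOutcome(category="no_prediction", best_ts=0.0)
    best_ts, best_pred = -1.0, None
    for smiles in sorted(pool):
        if smiles == truth:
            return CasmiOutcome(category="correct", best_ts=1.0, best_prediction=smiles)
        if use_typical:
            ts, _ = typical_similarity(smiles, truth, config)
        else:
            ts = tanimoto(smiles, truth, "rdkit")
        if ts > best_ts:
            best_ts, best_pred = ts, smiles
    return CasmiOutcome(category="unknown", best_ts=best_ts, best_prediction=best_pred)


def expand_candidates(molecule: Union[str, MoleculeRecord]) -> List[MoleculeRecord]:
    """Plug-in hook for external candidate generators.

    A generative model (for instance a molecular autoencoder searched
    around the top hit) can be attached here to enlarge the candidate pool
    before round-trip ranking.  The default implementation returns the
    input itself.
    """
    record = (
        molecule
        if isinstance(molecule, MoleculeRecord)
        else MoleculeRecord.from_smiles(molecule)
    )
    return [record]
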