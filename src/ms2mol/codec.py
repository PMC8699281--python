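"""Peak-list parsing, m/z binning to model-input tokens, and binned cosine
similarity.

Model inputs are sequences of integer bin indices: the m/z axis from 0 to
500 Da is divided into 50,000 bins of width 0.01 Da (m/z multiplied by 100
and truncated).  A 5 ppm instrument at 500 Da is accurate to 0.0025 Da, so
the bins comfortably absorb measurement error.  Intensities are carried
through parsing but never enter the encoding or the cosine score; they are
used only to order peaks in the top-k prediction protocol.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from ms2mol.chem import MoleculeRecord, SmilesParseError


@dataclass(frozen=True)
class BinningConfig:
    mz_max: float = 500.0
    scale: int = 100
    n_bins: int = 50_000

    def __post_init__(self) -> None:
        if self.n_bins != int(round(self.mz_max * self.scale)):
            raise ValueError("n_bins must equal mz_max * scale exactly")


@dataclass(frozen=True)
class ExperimentalSpectrum:
    """A measured peak list; intensities optional, ion mode recorded."""

    peaks: Tuple[Tuple[float, Optional[float]], ...]
    precursor_mz: Optional[float] = None
    ion_mode: str = "positive"

    def __post_init__(self) -> None:
        if any(mz <= 0 for mz, _ in self.peaks):
            raise ValueError("all m/z values must be positive")

    @property
    def mz_values(self) -> Tuple[float, ...]:
        return tuple(mz for mz, _ in self.peaks)

    @property
    def has_intensities(self) -> bool:
        return bool(self.peaks) and all(i is not None for _, i in self.peaks)


@dataclass(frozen=True)
class BinnedSpectrum:
    """Strictly ascending, duplicate-free bin indices; at most 100 of them."""

    bins: Tuple[int, ...]

    def __post_init__(self) -> None:
        if list(self.bins) != sorted(set(self.bins)):
            raise ValueError("bins must be strictly ascending and unique")
        if len(self.bins) > 100:
            raise ValueError("a binned spectrum holds at most 100 bins")

    def __len__(self) -> int:
        return len(self.bins)


def bin_index(mz: float, config: BinningConfig = BinningConfig()) -> int:
    """Bin index of one peak: floor(mz * scale).

    Truncation (not rounding) is used, so bin b covers [b/scale,
    (b+1)/scale).  A small epsilon absorbs binary floating-point
    representation error (123.055 is stored as 123.05499…, which must still
    land in bin 12305).
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if mz >= config.mz_max:
        raise ValueError(f"m/z {mz} is out of range (max {config.mz_max})")
    idx = int(math.floor(mz * config.scale + 1e-7))
    return min(idx, config.n_bins - 1)


def encode_spectrum(
    peaks: Iterable[float], config: BinningConfig = BinningConfig()
) -> BinnedSpectrum:
    """Bin a peak list: ascending, deduplicated bin indices."""
    bins = sorted({bin_index(mz, config) for mz in peaks})
    if len(bins) > 100:
        raise ValueError(
            f"{len(bins)} distinct bins exceed the maximum input length of 100"
        )
    return BinnedSpectrum(tuple(bins))


def cosine(a: BinnedSpectrum, b: BinnedSpectrum) -> float:
    """Cosine similarity of two binned spectra as binary occurrence vectors.

    |a ∩ b| / (√|a| · √|b|); intensities never enter the score.
    """
    if not a.bins or not b.bins:
        raise ValueError("cosine is undefined for an empty spectrum")
    shared = len(set(a.bins) & set(b.bins))
    return shared / math.sqrt(len(a.bins) * len(b.bins))


class PeakParseError(ValueError):
    """Raised when a peak list cannot be parsed; carries a line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


def _parse_bare(text: str) -> ExperimentalSpectrum:
    rows: List[List[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        cleaned = line.strip().strip("()[]")
        if not cleaned or cleaned.startswith("#"):
            continue
        row: List[float] = []
        for token in cleaned.replace(",", " ").split():
            token = token.strip("()[]")
            if not token:
                continue
            try:
                row.append(float(token))
            except ValueError:
                raise PeakParseError(f"non-numeric token {token!r}", lineno)
        if row:
            rows.append(row)
    if not rows:
        raise PeakParseError("no peaks found in input")
    # two uniform numeric columns over several lines read as (m/z, intensity)
    if len(rows) >= 2 and all(len(r) == 2 for r in rows):
        peaks = tuple((mz, intensity) for mz, intensity in rows)
    else:
        values = [v for r in rows for v in r]
        peaks = tuple((mz, None) for mz in values)
    return ExperimentalSpectrum(
        peaks=peaks, precursor_mz=max(mz for mz, _ in peaks)
    )


def _parse_mgf(text: str) -> ExperimentalSpectrum:
    from pyteomics import mgf

    with io.StringIO(text) as handle:
        entries = list(mgf.read(handle, use_index=False))
    if not entries:
        raise PeakParseError("no BEGIN IONS block with peaks found")
    entry = entries[0]
    mzs = list(entry["m/z array"])
    intens = list(entry["intensity array"])
    if not mzs:
        raise PeakParseError("MGF block contains no peaks")
    peaks = tuple(
        (float(mz), float(i) if i is not None else None)
        for mz, i in zip(mzs, intens)
    )
    params = entry.get("params", {})
    precursor = None
    pepmass = params.get("pepmass")
    if pepmass:
        precursor = float(pepmass[0])
    charge = params.get("charge")
    ion_mode = "positive"
    if charge:
        try:
            ion_mode = "negative" if int(charge[0]) < 0 else "positive"
        except (TypeError, ValueError):
            pass
    return ExperimentalSpectrum(peaks=peaks, precursor_mz=precursor, ion_mode=ion_mode)


def _parse_msp(text: str) -> ExperimentalSpectrum:
    peaks: List[Tuple[float, Optional[float]]] = []
    precursor: Optional[float] = None
    ion_mode = "positive"
    in_peaks = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            if peaks:
                break
            continue
        lower = stripped.lower()
        if ":" in stripped and not in_peaks:
            key, _, value = stripped.partition(":")
            key = key.strip().lower()
            value = value.strip()
            if key in ("precursormz", "precursor_mz"):
                try:
                    precursor = float(value)
                except ValueError:
                    raise PeakParseError(f"bad precursor m/z {value!r}", lineno)
            elif key in ("ion_mode", "ionmode"):
                ion_mode = "negative" if value.lower().startswith("n") else "positive"
            elif key in ("num peaks", "numpeaks", "num_peaks"):
                in_peaks = True
            continue
        fields = stripped.replace(",", " ").split()
        if len(fields) not in (1, 2):
            raise PeakParseError(f"bad peak line {stripped!r}", lineno)
        try:
            mz = float(fields[0])
            intensity = float(fields[1]) if len(fields) == 2 else None
        except ValueError:
            raise PeakParseError(f"non-numeric token in {stripped!r}", lineno)
        peaks.append((mz, intensity))
    if not peaks:
        raise PeakParseError("MSP block contains no peaks")
    return ExperimentalSpectrum(
        peaks=tuple(peaks), precursor_mz=precursor, ion_mode=ion_mode
    )


def parse_peaks(source: str) -> ExperimentalSpectrum:
    """Parse a peak list in MGF, MSP, or bare numeric (whitespace/comma) form.

    The dialect is sniffed: an MGF ``BEGIN IONS`` block, an MSP block with
    ``NAME:``/``Num Peaks:`` headers, or a bare list such as the
    parenthesised m/z tuples mass-spec software exports.  Intensities are
    kept when present.  For bare lists the precursor is taken as the largest
    m/z (the protonated molecular ion is assumed present in positive mode).
    """
    if not source or not source.strip():
        raise PeakParseError("empty input")
    upper = source.upper()
    if "BEGIN IONS" in upper:
        return _parse_mgf(source)
    if any(key in upper for key in ("NAME:", "NUM PEAKS", "PRECURSORMZ")):
        return _parse_msp(source)
    return _parse_bare(source)


#: keys tried, in order, for each field of a GNPS-style JSON record
_GNPS_SMILES_KEYS = ("smiles", "SMILES", "Smiles")
_GNPS_MODE_KEYS = ("ion_mode", "Ion_Mode", "ionmode", "IonMode", "Ion_Source")
_GNPS_PEAK_KEYS = ("peaks", "peaks_json", "Peaks", "spectrum")


def _first_key(record: dict, keys: Sequence[str]):
    for key in keys:
        if key in record:
            return record[key]
    return None


def parse_gnps_records(
    records: Union[str, Sequence[dict]],
    mz_max: float = 500.0,
    max_smiles_len: int = 99,
    max_peaks: int = 100,
) -> Tuple[List[Tuple[MoleculeRecord, ExperimentalSpectrum]], Dict[str, int]]:
    """Parse spectral-library JSON records into (molecule, spectrum) pairs.

    Records are rejected, with per-filter counts, when (in order) a required
    field is missing or ``"N/A"``; the ion mode is not positive; any peak
    m/z reaches ``mz_max``; the SMILES exceeds ``max_smiles_len``
    characters; or the peak count exceeds ``max_peaks``.  Unparseable
    SMILES are counted under ``invalid_smiles``.
    """
    if isinstance(records, str):
        try:
            records = json.loads(records)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed JSON: {exc}") from exc
    counts = {
        "missing_field": 0,
        "ion_mode": 0,
        "mz_range": 0,
        "smiles_length": 0,
        "peak_count": 0,
        "invalid_smiles": 0,
        "retained": 0,
    }
    out: List[Tuple[MoleculeRecord, ExperimentalSpectrum]] = []
    for record in records:
        smiles = _first_key(record, _GNPS_SMILES_KEYS)
        mode = _first_key(record, _GNPS_MODE_KEYS)
        raw_peaks = _first_key(record, _GNPS_PEAK_KEYS)
        if isinstance(raw_peaks, str):
            try:
                raw_peaks = json.loads(raw_peaks)
            except json.JSONDecodeError:
                raw_peaks = None
        missing = (
            smiles is None or str(smiles).strip().upper() in ("", "N/A")
            or mode is None or str(mode).strip().upper() in ("", "N/A")
            or raw_peaks is None
        )
        if missing:
            counts["missing_field"] += 1
            continue
        if not str(mode).strip().lower().startswith("pos"):
            counts["ion_mode"] += 1
            continue
        peaks = [
            (float(p[0]), float(p[1]) if len(p) > 1 and p[1] is not None else None)
            for p in raw_peaks
        ]
        if any(mz >= mz_max for mz, _ in peaks):
            counts["mz_range"] += 1
            continue
        if len(str(smiles)) > max_smiles_len:
            counts["smiles_length"] += 1
            continue
        if len(peaks) > max_peaks:
            counts["peak_count"] += 1
            continue
        try:
            molecule = MoleculeRecord.from_smiles(str(smiles), source_tag="gnps")
        except SmilesParseError:
            counts["invalid_smiles"] += 1
            continue
        spectrum = ExperimentalSpectrum(
            peaks=tuple(peaks),
            precursor_mz=max(mz for mz, _ in peaks) if peaks else None,
            ion_mode="positive",
        )
        out.append((molecule, spectrum))
        counts["retained"] += 1
    return out, counts


def truncate_to_top_intensity(
    spectrum: ExperimentalSpectrum, max_peaks: int = 100
) -> ExperimentalSpectrum:
    """Keep the ``max_peaks`` most intense peaks, warning when truncating.

    Used at prediction time only; dataset building rejects over-long peak
    lists outright.  Ties at the boundary are broken toward lower m/z.
    """
    if len(spectrum.peaks) <= max_peaks:
        return spectrum
    if not spectrum.has_intensities:
        raise ValueError("cannot truncate by intensity: intensities missing")
    warnings.warn(
        f"truncating spectrum from {len(spectrum.peaks)} to {max_peaks} peaks "
        "by intensity",
        stacklevel=2,
    )
    ordered = sorted(spectrum.peaks, key=lambda p: (-p[1], p[0]))[:max_peaks]
    kept = tuple(sorted(ordered, key=lambda p: p[0]))
    return ExperimentalSpectrum(
        peaks=kept, precursor_mz=spectrum.precursor_mz, ion_mode=spectrum.ion_mode
    )
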