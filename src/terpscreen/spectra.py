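"""Unit-mass EI spectra, spectral libraries and n-alkane retention ladders.

The data model is deliberately nominal-mass: quadrupole EI spectra of
sesquiterpenes (m/z ~ 41-220) carry no useful sub-integer mass information,
so every m/z is rounded half-up to an integer at ingest and intensities of
colliding bins are summed.  Intensities are relative abundances; spectra are
base-peak-normalized (base peak = 100) before any similarity scoring.

File formats
------------
* NIST-style MSP text for libraries (``Name:`` / ``Num Peaks:`` headers,
  whitespace- or semicolon-delimited peak pairs).  Library records carry a
  ``Retention_index:`` header because a library entry without a reference RI
  cannot take part in RI-windowed search.
* CSV with header ``carbon_number,retention_time_min`` for alkane ladders.
* A two-column TSV dialect (``mz<TAB>intensity``) for single query spectra.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MassSpectrum",
    "RetentionLadder",
    "LibraryEntry",
    "MSPParseError",
    "normalize_spectrum",
    "bin_nominal",
    "read_msp",
    "write_msp",
    "read_ladder_csv",
    "write_ladder_csv",
    "read_query_tsv",
    "write_query_tsv",
]


class MSPParseError(ValueError):
    """Raised when an MSP record violates the dialect contract."""


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def bin_nominal(mz: Sequence[float], intensities: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Round m/z half-up to integers and sum intensities of colliding bins.

    Total ion intensity is conserved exactly (a pure regrouping of terms).
    Returns (mz, intensity) arrays sorted by m/z.
    """
    mz_int = _round_half_up(mz)
    inten = np.asarray(intensities, dtype=float)
    if mz_int.shape != inten.shape:
        raise ValueError("m/z and intensity arrays differ in length")
    uniq, inverse = np.unique(mz_int, return_inverse=True)
    summed = np.zeros(uniq.size, dtype=float)
    np.add.at(summed, inverse, inten)
    return uniq, summed


@dataclass(frozen=True)
class MassSpectrum:
    """A unit-mass EI spectrum: strictly increasing integer m/z, relative intensities.

    ``retention_time`` is in minutes; ``retention_index`` is the dimensionless
    alkane-referenced elution position.  Both are optional metadata.
    """

    mz: np.ndarray
    intensities: np.ndarray
    name: str = ""
    retention_time: float | None = None
    retention_index: float | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.int64)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensities", inten)
        if mz.ndim != 1 or inten.ndim != 1 or mz.size != inten.size:
            raise ValueError("peaks must be parallel 1-d m/z and intensity arrays")
        if mz.size == 0:
            raise ValueError("a spectrum needs at least one peak")
        if np.any(mz <= 0):
            raise ValueError("m/z values must be positive")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be unique and strictly increasing")
        if np.any(inten < 0) or not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite and non-negative")
        if not np.any(inten > 0):
            raise ValueError("at least one intensity must be positive")

    @property
    def peaks(self) -> list[tuple[int, float]]:
        return list(zip(self.mz.tolist(), self.intensities.tolist()))

    @property
    def base_peak_mz(self) -> int:
        return int(self.mz[int(np.argmax(self.intensities))])

    def is_normalized(self, tol: float = 0.0) -> bool:
        return abs(float(self.intensities.max()) - 100.0) <= tol

    def __eq__(self, other: object) -> bool:  # array fields break dataclass eq
        if not isinstance(other, MassSpectrum):
            return NotImplemented
        return (
            np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensities, other.intensities)
            and self.name == other.name
            and self.retention_time == other.retention_time
            and self.retention_index == other.retention_index
        )


def normalize_spectrum(s: MassSpectrum) -> MassSpectrum:
    """Scale intensities so the base peak is exactly 100.

    Idempotent: a spectrum whose maximum is already 100 is returned unchanged
    (the scale factor is exactly 1.0).
    """
    top = float(s.intensities.max())
    if top <= 0:
        raise ValueError("cannot normalize a spectrum with no positive intensity")
    if top == 100.0:
        return s
    return replace(s, intensities=s.intensities * (100.0 / top))


@dataclass(frozen=True)
class RetentionLadder:
    """n-alkane calibration ladder: carbon numbers with retention times (min)."""

    carbon_numbers: np.ndarray
    retention_times: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.carbon_numbers, dtype=np.int64)
        t = np.asarray(self.retention_times, dtype=float)
        object.__setattr__(self, "carbon_numbers", c)
        object.__setattr__(self, "retention_times", t)
        if c.size != t.size or c.ndim != 1:
            raise ValueError("carbon numbers and times must be parallel 1-d arrays")
        if c.size < 2:
            raise ValueError("a ladder needs at least two rungs")
        if np.any(c < 1):
            raise ValueError("carbon numbers must be >= 1")
        if np.any(np.diff(c) <= 0):
            raise ValueError("carbon numbers must be strictly increasing")
        if np.any(np.diff(t) <= 0) or not np.all(np.isfinite(t)):
            raise ValueError("retention times must be finite and strictly increasing")

    @property
    def rungs(self) -> list[tuple[int, float]]:
        return list(zip(self.carbon_numbers.tolist(), self.retention_times.tolist()))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.retention_times[0]), float(self.retention_times[-1])


@dataclass(frozen=True)
class LibraryEntry:
    """A reference compound: named spectrum plus its reference retention index."""

    compound_name: str
    spectrum: MassSpectrum
    reference_ri: float
    compound_class: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_name:
            raise ValueError("library entry needs a compound name")
        if not (self.reference_ri > 0):
            raise ValueError("reference RI must be positive")


# ---------------------------------------------------------------------------
# MSP (NIST text) reading / writing
# ---------------------------------------------------------------------------

_HEADER_SYNONYMS = {
    "name": "name",
    "retention_index": "retention_index",
    "retentionindex": "retention_index",
    "ri": "retention_index",
    "retention_time": "retention_time",
    "rt": "retention_time",
    "class": "compound_class",
    "compound_class": "compound_class",
    "num peaks": "num_peaks",
    "num_peaks": "num_peaks",
}


def _parse_peak_line(line: str, lineno: int) -> list[tuple[float, float]]:
    pairs = []
    for chunk in line.replace(";", "\n").splitlines():
        chunk = chunk.strip()
        if not chunk:
            continue
        fields = chunk.replace(",", " ").split()
        if len(fields) != 2:
            raise MSPParseError(f"line {lineno}: expected 'm/z intensity' pair, got {chunk!r}")
        try:
            pairs.append((float(fields[0]), float(fields[1])))
        except ValueError as exc:
            raise MSPParseError(f"line {lineno}: non-numeric peak value in {chunk!r}") from exc
    return pairs


def read_msp(path: str | Path) -> list[LibraryEntry]:
    """Parse a NIST-style MSP library into LibraryEntry records, preserving order.

    Fractional m/z are rounded half-up to the nearest integer; intensities of
    colliding bins are summed.  Unknown header lines are ignored (logged at
    DEBUG).  Malformed records raise :class:`MSPParseError` naming the line.
    """
    path = Path(path)
    entries: list[LibraryEntry] = []
    record: dict | None = None
    peaks: list[tuple[float, float]] = []
    record_line = 0

    def flush(lineno: int) -> None:
        nonlocal record, peaks
        if record is None:
            return
        declared = record.get("num_peaks")
        if declared is None:
            raise MSPParseError(
                f"line {record_line}: record {record.get('name', '?')!r} has no 'Num Peaks' header"
            )
        if len(peaks) != declared:
            raise MSPParseError(
                f"line {lineno}: record {record.get('name', '?')!r} declares "
                f"{declared} peaks but lists {len(peaks)}"
            )
        if record.get("retention_index") is None:
            raise MSPParseError(
                f"line {record_line}: record {record.get('name', '?')!r} has no "
                "'Retention_index' header (library entries need a reference RI)"
            )
        mz, inten = bin_nominal([p[0] for p in peaks], [p[1] for p in peaks])
        spectrum = MassSpectrum(
            mz,
            inten,
            name=record["name"],
            retention_time=record.get("retention_time"),
            retention_index=record.get("retention_index"),
        )
        entries.append(
            LibraryEntry(
                compound_name=record["name"],
                spectrum=spectrum,
                reference_ri=record["retention_index"],
                compound_class=record.get("compound_class"),
            )
        )
        record, peaks = None, []

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                canon = _HEADER_SYNONYMS.get(key.strip().lower())
                value = value.strip()
                if canon == "name":
                    flush(lineno)
                    record = {"name": value}
                    record_line = lineno
                    continue
                if record is None:
                    raise MSPParseError(f"line {lineno}: header {key!r} before any 'Name:' record")
                if canon == "num_peaks":
                    try:
                        record["num_peaks"] = int(value)
                    except ValueError as exc:
                        raise MSPParseError(f"line {lineno}: bad 'Num Peaks' value {value!r}") from exc
                elif canon in ("retention_index", "retention_time"):
                    try:
                        record[canon] = float(value)
                    except ValueError as exc:
                        raise MSPParseError(f"line {lineno}: bad {key.strip()} value {value!r}") from exc
                elif canon == "compound_class":
                    record["compound_class"] = value
                else:
                    logger.debug("line %d: ignoring unknown MSP header %r", lineno, key.strip())
                continue
            # peak data line
            if record is None:
                raise MSPParseError(f"line {lineno}: peak data before any 'Name:' record")
            if record.get("num_peaks") is None:
                raise MSPParseError(
                    f"line {lineno}: peak data before 'Num Peaks' in record {record.get('name', '?')!r}"
                )
            peaks.extend(_parse_peak_line(line, lineno))
    flush(lineno + 1)
    return entries


def write_msp(entries: Iterable[LibraryEntry], path: str | Path) -> None:
    """Write library entries as NIST-style MSP text.

    Intensities are written with full float precision so that
    ``read_msp(write_msp(entries))`` reproduces the entries exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for entry in entries:
            s = entry.spectrum
            fh.write(f"Name: {entry.compound_name}\n")
            if entry.compound_class is not None:
                fh.write(f"Class: {entry.compound_class}\n")
            fh.write(f"Retention_index: {entry.reference_ri!r}\n")
            if s.retention_time is not None:
                fh.write(f"Retention_time: {s.retention_time!r}\n")
            fh.write(f"Num Peaks: {s.mz.size}\n")
            for mz, inten in zip(s.mz.tolist(), s.intensities.tolist()):
                fh.write(f"{mz} {inten!r}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Ladder CSV and query TSV
# ---------------------------------------------------------------------------

LADDER_COLUMNS = ("carbon_number", "retention_time_min")


def read_ladder_csv(path: str | Path) -> RetentionLadder:
    """Read an alkane ladder from CSV with header ``carbon_number,retention_time_min``."""
    df = pd.read_csv(path)
    missing = [c for c in LADDER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: ladder CSV missing column(s) {missing}")
    return RetentionLadder(df["carbon_number"].to_numpy(), df["retention_time_min"].to_numpy())


def write_ladder_csv(ladder: RetentionLadder, path: str | Path) -> None:
    pd.DataFrame(
        {"carbon_number": ladder.carbon_numbers, "retention_time_min": ladder.retention_times}
    ).to_csv(path, index=False)


def read_query_tsv(path: str | Path, name: str | None = None) -> MassSpectrum:
    """Read a single query spectrum from the two-column ``mz<TAB>intensity`` dialect.

    Lines starting with ``#`` are comments; the same nominal-mass binning as
    MSP ingest applies.
    """
    path = Path(path)
    mzs: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'mz<TAB>intensity', got {line!r}")
            mzs.append(float(fields[0]))
            intens.append(float(fields[1]))
    if not mzs:
        raise ValueError(f"{path}: no peaks found")
    mz, inten = bin_nominal(mzs, intens)
    return MassSpectrum(mz, inten, name=name or path.stem)


def write_query_tsv(s: MassSpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {s.name}\n")
        for mz, inten in zip(s.mz.tolist(), s.intensities.tolist()):
            fh.write(f"{mz}\t{inten!r}\n")
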