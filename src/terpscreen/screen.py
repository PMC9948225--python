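"""Candidate-gene triage: ORF validation and terpene-synthase motif scanning.

Class-I sesquiterpene synthases carry two Mg2+-binding signature regions that
coordinate the diphosphate of farnesyl pyrophosphate: an aspartate-rich motif
(canonically D(D/E/N)xxD, sometimes the weaker DDxxx variant) on one active-
site helix and the NSE/DTE triad on the opposite helix.  Candidates lacking
both are very likely catalytically dead, and nucleotide candidates without a
start codon are presumed silent pseudogenes — that is the triage logic this
module implements.

Motif placement in these enzymes is positionally constrained: the aspartate-
rich region sits roughly 60-160 residues into the protein and the NSE/DTE
motif lies downstream of it.  Both the search region and the NSE/DTE
consensus are configurable because exact boundaries vary across fungal
lineages.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "OrfStatus",
    "CandidateStatus",
    "MotifReport",
    "read_fasta",
    "write_fasta",
    "validate_orf",
    "scan_aspartate_rich",
    "scan_nse_dte",
    "classify_candidates",
    "DEFAULT_SEARCH_REGION",
    "DEFAULT_NSE_DTE_PATTERN",
    "motif_report_frame",
]

#: 1-based residue span within which the aspartate-rich motif must start.
DEFAULT_SEARCH_REGION = (60, 160)

#: NSE/DTE consensus: (N/D)-D-hydrophobic-x-(S/T)-x-x-x-E.
DEFAULT_NSE_DTE_PATTERN = "[ND]D[LIVMFYT].[ST]...E"

ASPARTATE_CANONICAL = "D[DEN]..D"
ASPARTATE_VARIANT = "DD..."
ASPARTATE_NONCANONICAL = ("E[DEN]..E", "EE")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_NT_ALPHABET = frozenset("ACGTN")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercased sequence) pairs, order preserved.

    Record ids are truncated at the first whitespace.  Duplicate ids and empty
    sequences are rejected.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# ORF validation
# ---------------------------------------------------------------------------

class OrfStatus:
    COMPLETE = "complete_orf"
    NO_START = "no_start_codon"
    INTERNAL_STOP = "internal_stop"


@dataclass(frozen=True)
class CandidateStatus:
    candidate_id: str
    status: str  # one of the OrfStatus values


def validate_orf(sequence: str) -> str:
    """Classify a nucleotide candidate as complete_orf / no_start_codon / internal_stop.

    complete_orf requires an ATG first codon, length divisible by three, and
    no in-frame stop codon before the final codon.  A non-ATG first codon is
    no_start_codon regardless of anything downstream; everything else
    (frame-breaking length, premature stop) is internal_stop.  Codons
    containing N are never counted as stops.
    """
    seq = sequence.upper()
    if len(seq) < 6:
        raise ValueError("nucleotide sequence must be at least 6 nt")
    bad = set(seq) - _NT_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    if seq[:3] != "ATG":
        return OrfStatus.NO_START
    if len(seq) % 3 != 0:
        return OrfStatus.INTERNAL_STOP
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if any(c in STOP_CODONS for c in codons[:-1]):
        return OrfStatus.INTERNAL_STOP
    return OrfStatus.COMPLETE


def validate_candidates(candidates: Iterable[tuple[str, str]]) -> list[CandidateStatus]:
    return [CandidateStatus(cid, validate_orf(seq)) for cid, seq in candidates]


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

class AspartateStatus:
    CANONICAL = "canonical"
    VARIANT = "variant_ddxxx"
    NON_CANONICAL = "non_canonical"
    ABSENT = "absent"


class Classification:
    LIKELY_ACTIVE = "likely_active"
    NON_CANONICAL = "non_canonical"
    LIKELY_INACTIVE = "likely_inactive"


def _check_protein(seq: str, min_len: int) -> str:
    seq = seq.upper()
    if len(seq) < min_len:
        raise ValueError(f"protein sequence shorter than {min_len} residues")
    bad = set(seq) - _AA_ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    return seq


def _leftmost_in_region(pattern: str, seq: str, region: tuple[int, int]) -> int | None:
    """1-based start of the leftmost match whose start lies inside ``region``."""
    lo, hi = region
    for m in re.finditer(f"(?=({pattern}))", seq):
        pos = m.start() + 1
        if pos > hi:
            return None
        if pos >= lo:
            return pos
    return None


def scan_aspartate_rich(
    sequence: str, region: tuple[int, int] = DEFAULT_SEARCH_REGION
) -> tuple[str, int | None]:
    """Scan for the Mg2+-binding aspartate-rich motif within the search region.

    Precedence: canonical D(D/E/N)xxD, then the DDxxx variant, then the
    glutamate-substituted non-canonical form (E(D/E/N)xxE or EE); within a
    tier the leftmost match wins.  Positions are 1-based match starts.  X in
    the sequence matches wildcard positions only, never a stated residue
    class.
    """
    seq = _check_protein(sequence, 5)
    pos = _leftmost_in_region(ASPARTATE_CANONICAL, seq, region)
    if pos is not None:
        return AspartateStatus.CANONICAL, pos
    pos = _leftmost_in_region(ASPARTATE_VARIANT, seq, region)
    if pos is not None:
        return AspartateStatus.VARIANT, pos
    candidates = [
        p for pat in ASPARTATE_NONCANONICAL
        if (p := _leftmost_in_region(pat, seq, region)) is not None
    ]
    if candidates:
        return AspartateStatus.NON_CANONICAL, min(candidates)
    return AspartateStatus.ABSENT, None


def scan_nse_dte(
    sequence: str,
    pattern: str = DEFAULT_NSE_DTE_PATTERN,
    search_from: int = 0,
) -> tuple[str, int | None]:
    """Scan for the NSE/DTE Mg2+-binding triad consensus.

    ``search_from`` is a 0-based index: matches must start at or after it,
    which is how the downstream-of-the-aspartate-rich-region ordering
    constraint is applied by :func:`classify_candidates`.  Returns
    ("present", 1-based position) or ("absent", None).
    """
    seq = _check_protein(sequence, 9)
    m = re.search(f"(?=({pattern}))", seq[search_from:])
    if m is None:
        return "absent", None
    return "present", search_from + m.start() + 1


@dataclass(frozen=True)
class MotifReport:
    """Per-protein motif classification."""

    protein_id: str
    aspartate_rich: str
    aspartate_rich_pos: int | None
    nse_dte: str
    nse_dte_pos: int | None
    classification: str


def classify_candidates(
    proteins: Iterable[tuple[str, str]],
    region: tuple[int, int] = DEFAULT_SEARCH_REGION,
    nse_dte_pattern: str = DEFAULT_NSE_DTE_PATTERN,
    require_order: bool = True,
) -> list[MotifReport]:
    """Run both motif scanners on each protein and classify activity.

    * likely_inactive — both motifs absent (the signature-less pseudo-synthase
      case).
    * non_canonical — glutamate-substituted aspartate-rich region (the EE
      case), whatever the NSE/DTE status.
    * likely_active — at least one motif present with a canonical or DDxxx
      aspartate-rich region.

    With ``require_order`` (default), the NSE/DTE motif must start after the
    aspartate-rich match — or, when that motif is absent, after the start of
    the search region.
    """
    reports: list[MotifReport] = []
    for pid, seq in proteins:
        asp_status, asp_pos = scan_aspartate_rich(seq, region=region)
        if require_order:
            search_from = asp_pos + 4 if asp_pos is not None else region[0] - 1
        else:
            search_from = 0
        nse_status, nse_pos = scan_nse_dte(seq, pattern=nse_dte_pattern, search_from=search_from)
        if asp_status == AspartateStatus.ABSENT and nse_status == "absent":
            cls = Classification.LIKELY_INACTIVE
        elif asp_status == AspartateStatus.NON_CANONICAL:
            cls = Classification.NON_CANONICAL
        else:
            cls = Classification.LIKELY_ACTIVE
        reports.append(MotifReport(pid, asp_status, asp_pos, nse_status, nse_pos, cls))
    counts = Counter(r.classification for r in reports)
    logger.info(
        "motif screen: %d proteins — %s",
        len(reports),
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())) or "none",
    )
    return reports


def motif_report_frame(reports: Sequence[MotifReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.protein_id for r in reports],
            "asp_rich_status": [r.aspartate_rich for r in reports],
            "asp_rich_pos": [r.aspartate_rich_pos for r in reports],
            "nse_dte_status": [r.nse_dte for r in reports],
            "nse_dte_pos": [r.nse_dte_pos for r in reports],
            "classification": [r.classification for r in reports],
        }
    )
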