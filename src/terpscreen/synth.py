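"""Seeded generators emulating the pipeline's study inputs.

Every stage of the screen — spectral library search, retention-index
calibration, ORF triage, motif scanning, clade assignment — is exercised
against data from this module, so no external chromatograms or genomes are
needed.  All generators are bit-reproducible for a fixed seed and parameter
set, and every generator returns its ground-truth labels alongside the data
so tests never re-derive truth from the code under test.

What is emulated (and what is not): EI spectra are sparse unit-mass stick
spectra over the sesquiterpene fragment range m/z 41-220 with an
exponential rank-abundance intensity law — they reproduce the sparsity and
dynamic range of real 70 eV spectra but not fragmentation chemistry.
Alkane ladders are near-linear in carbon number, as on a temperature-
programmed run.  Proteins are uniform-random backbones with signature
motifs planted at class-I-synthase-like positions; nucleotide candidates
are stop-free ORFs with a controllable fraction of start-codon-less
pseudogene mimics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .screen import DEFAULT_NSE_DTE_PATTERN, DEFAULT_SEARCH_REGION
from .spectra import LibraryEntry, MassSpectrum, RetentionLadder, normalize_spectrum

__all__ = [
    "SpectrumModel",
    "NoiseModel",
    "CladeFixture",
    "make_spectrum",
    "make_library",
    "perturb_spectrum",
    "make_ladder",
    "plant_motif_sequences",
    "make_candidate_genes",
    "make_clade_references",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPOUND_CLASSES = (
    "cadinane-type",
    "protoilludane-type",
    "alliacane-type",
    "barbatane-type",
    "acorane-type",
)


@dataclass(frozen=True)
class SpectrumModel:
    """EI stick-spectrum generator parameters.

    Intensities follow an exponential rank-abundance law I_r = 100*exp(-rate*r)
    over randomly placed integer m/z in ``mz_range`` — the simplest model that
    yields EI-like sparse spectra with one dominant base peak.
    """

    n_peaks: int = 25
    mz_range: tuple[int, int] = (41, 220)
    decay_rate: float = 0.15

    def __post_init__(self) -> None:
        lo, hi = self.mz_range
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        if not (0 < lo < hi):
            raise ValueError("mz_range must satisfy 0 < low < high")
        if hi - lo + 1 < self.n_peaks:
            raise ValueError("mz_range too narrow for n_peaks distinct peaks")
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters for replicate query spectra.

    ``intensity_cv`` — coefficient of variation of multiplicative log-normal
    intensity noise; ``dropout_p`` — per-peak Bernoulli loss probability;
    ``contaminant_rate`` — Poisson mean count of spurious peaks at unoccupied
    m/z (relative intensity Uniform(1, 10), i.e. minor background peaks).
    """

    intensity_cv: float = 0.05
    dropout_p: float = 0.02
    contaminant_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.intensity_cv < 0 or self.contaminant_rate < 0:
            raise ValueError("noise parameters must be >= 0")
        if not (0 <= self.dropout_p < 1):
            raise ValueError("dropout_p must lie in [0, 1)")


def make_spectrum(model: SpectrumModel, rng: np.random.Generator, name: str = "") -> MassSpectrum:
    """Draw one synthetic EI spectrum from the model (base peak exactly 100)."""
    lo, hi = model.mz_range
    mz = np.sort(rng.choice(np.arange(lo, hi + 1), size=model.n_peaks, replace=False))
    ranks = rng.permutation(model.n_peaks)
    intensities = 100.0 * np.exp(-model.decay_rate * ranks)
    return MassSpectrum(mz, intensities, name=name)


def make_library(
    n_compounds: int,
    model: SpectrumModel = SpectrumModel(),
    ri_range: tuple[float, float] = (1300.0, 1670.0),
    seed: int = 0,
) -> list[LibraryEntry]:
    """Synthetic spectral library with reference RIs drawn uniformly in ``ri_range``.

    The default RI span covers the sesquiterpene elution window (RI roughly
    1300-1670 on an apolar column).  Reproducible per seed.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    lo, hi = ri_range
    if not (0 < lo < hi):
        raise ValueError("ri_range must satisfy 0 < low < high")
    rng = np.random.default_rng(seed)
    entries = []
    width = len(str(n_compounds))
    for k in range(n_compounds):
        name = f"compound_{k + 1:0{width}d}"
        spectrum = make_spectrum(model, rng, name=name)
        ri = float(rng.uniform(lo, hi))
        entries.append(
            LibraryEntry(
                compound_name=name,
                spectrum=replace(spectrum, retention_index=ri),
                reference_ri=ri,
                compound_class=_COMPOUND_CLASSES[k % len(_COMPOUND_CLASSES)],
            )
        )
    return entries


def perturb_spectrum(
    s: MassSpectrum,
    noise: NoiseModel,
    rng: np.random.Generator | int = 0,
    max_retries: int = 100,
) -> MassSpectrum:
    """Apply measurement noise to a spectrum and renormalize.

    Multiplicative log-normal intensity noise with the stated CV, Bernoulli
    peak dropout, and Poisson-count contaminant peaks at unoccupied m/z.
    A zero-noise model returns the input spectrum exactly.  If dropout wipes
    out every peak the draw is retried (bounded), then an error is raised.
    """
    if noise.intensity_cv == 0 and noise.dropout_p == 0 and noise.contaminant_rate == 0:
        return s
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    lo_mz = int(s.mz.min())
    hi_mz = int(s.mz.max())
    for _ in range(max_retries):
        keep = rng.random(s.mz.size) >= noise.dropout_p
        if not np.any(keep):
            continue
        mz = s.mz[keep]
        inten = s.intensities[keep].astype(float)
        if noise.intensity_cv > 0:
            sigma = float(np.sqrt(np.log1p(noise.intensity_cv**2)))
            inten = inten * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=inten.size)
        if noise.contaminant_rate > 0:
            n_cont = int(rng.poisson(noise.contaminant_rate))
            free = np.setdiff1d(np.arange(lo_mz, hi_mz + 1), mz)
            n_cont = min(n_cont, free.size)
            if n_cont > 0:
                cont_mz = rng.choice(free, size=n_cont, replace=False)
                cont_int = rng.uniform(1.0, 10.0, size=n_cont)
                mz = np.concatenate([mz, cont_mz])
                inten = np.concatenate([inten, cont_int])
                order = np.argsort(mz)
                mz, inten = mz[order], inten[order]
        return normalize_spectrum(
            MassSpectrum(mz, inten, name=s.name, retention_time=s.retention_time)
        )
    raise RuntimeError(
        f"dropout_p={noise.dropout_p} wiped out every peak in {max_retries} consecutive draws"
    )


def make_ladder(
    c_min: int = 8,
    c_max: int = 30,
    t0: float = 8.0,
    spacing: float = 3.2,
    curvature: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> RetentionLadder:
    """n-alkane ladder with near-linear retention times.

    ``t0`` is the C(c_min) elution time in minutes and ``spacing`` the
    per-carbon increment (defaults mimic a 3 degC/min temperature program
    where successive alkanes elute ~3 min apart).  ``curvature`` adds a mild
    quadratic term; ``jitter_sd`` adds seeded Gaussian timing noise.  The
    result must be strictly increasing or a ValueError is raised.
    """
    if c_min >= c_max:
        raise ValueError("c_min must be < c_max")
    if c_min < 1:
        raise ValueError("carbon numbers must be >= 1")
    carbons = np.arange(c_min, c_max + 1)
    x = carbons - c_min
    times = t0 + spacing * x + curvature * x.astype(float) ** 2
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        times = times + rng.normal(0.0, jitter_sd, size=times.size)
    if np.any(np.diff(times) <= 0):
        raise ValueError("ladder parameterization yields non-monotone retention times")
    return RetentionLadder(carbons, times)


# ---------------------------------------------------------------------------
# Protein / nucleotide fixtures
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _sample_from_classes(rng: np.random.Generator, classes: Sequence[str]) -> str:
    return "".join(c if len(c) == 1 else rng.choice(list(c)) for c in classes)


# Pattern alphabets for planting (each element: literal residue or a class string).
# The non-canonical plant carries glutamates with no aspartate anywhere in the
# motif, so it can never be read as a DD... variant.
_AA_NO_D = AMINO_ACIDS.replace("D", "")
_CANONICAL_ASP = ("D", "DEN", AMINO_ACIDS, AMINO_ACIDS, "D")
_NONCANONICAL_ASP = ("E", "EN", _AA_NO_D, _AA_NO_D, "E")
_NSE_DTE = ("ND", "D", "LIVMFYT", AMINO_ACIDS, "ST", AMINO_ACIDS, AMINO_ACIDS, AMINO_ACIDS, "E")

# The generator's own truth regexes (kept independent of the scanner module's
# compiled logic; the pattern strings are shared vocabulary, not shared code).
_D_PATTERNS = ("D[DEN]..D", "DD")
_E_PATTERNS = ("E[DEN]..E", "EE")


def _region_clean(seq: str, region: tuple[int, int], patterns: Sequence[str]) -> bool:
    lo, hi = region
    window = seq[max(lo - 1 - 4, 0) : hi + 4]
    return not any(re.search(p, window) for p in patterns)


def _downstream_clean(seq: str, region: tuple[int, int], nse_pattern: str) -> bool:
    return re.search(nse_pattern, seq[region[0] - 1 :]) is None


def plant_motif_sequences(
    n_pos: int,
    n_neg: int,
    n_noncanonical: int = 0,
    length: int = 350,
    seed: int = 0,
    region: tuple[int, int] = DEFAULT_SEARCH_REGION,
    nse_pattern: str = DEFAULT_NSE_DTE_PATTERN,
    max_rejections: int = 10_000,
) -> list[tuple[str, str, str]]:
    """Proteins with planted signature motifs, plus motif-free negatives.

    Returns (id, sequence, truth_label) triples with labels ``positive``
    (canonical aspartate-rich + NSE/DTE planted), ``non_canonical`` (EE
    variant + NSE/DTE), and ``negative`` (rejection-sampled to contain no
    qualifying match for either scanner).  Identical seeds give identical
    output.
    """
    if min(n_pos, n_neg, n_noncanonical) < 0:
        raise ValueError("counts must be >= 0")
    if length < 200:
        raise ValueError("length must be >= 200 residues")
    lo, hi = region
    if hi + 30 > length:
        raise ValueError("length too short for the motif search region")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str, str]] = []

    def plant(asp_classes: Sequence[str] | None, forbidden: Sequence[str]) -> str:
        for _ in range(max_rejections):
            seq = _random_protein(rng, length)
            if not _region_clean(seq, region, forbidden):
                continue
            if asp_classes is None:
                if not _downstream_clean(seq, region, nse_pattern):
                    continue
                return seq
            asp = _sample_from_classes(rng, asp_classes)
            asp_start = int(rng.integers(lo, hi + 1))  # 1-based
            seq = seq[: asp_start - 1] + asp + seq[asp_start - 1 + len(asp) :]
            if not _region_clean(
                seq[: asp_start - 1] + "." * len(asp) + seq[asp_start - 1 + len(asp) :],
                region,
                forbidden,
            ):
                continue
            nse = _sample_from_classes(rng, _NSE_DTE)
            # plant the NSE/DTE triad past the aspartate-rich search region so
            # its (N/D)D head can never masquerade as an in-region DD variant
            nse_lo = max(asp_start + len(asp) + 5, hi + 5)
            nse_start = int(rng.integers(nse_lo, length - len(nse) + 2))
            seq = seq[: nse_start - 1] + nse + seq[nse_start - 1 + len(nse) :]
            return seq
        raise RuntimeError("rejection sampling exhausted while planting motifs")

    for k in range(n_pos):
        out.append((f"prot_pos_{k + 1:03d}", plant(_CANONICAL_ASP, _E_PATTERNS), "positive"))
    for k in range(n_noncanonical):
        out.append((f"prot_nc_{k + 1:03d}", plant(_NONCANONICAL_ASP, _D_PATTERNS), "non_canonical"))
    for k in range(n_neg):
        out.append((f"prot_neg_{k + 1:03d}", plant(None, _D_PATTERNS + _E_PATTERNS), "negative"))
    return out


def make_candidate_genes(
    n_total: int,
    n_no_start: int,
    seed: int = 0,
    codon_range: tuple[int, int] = (250, 400),
) -> list[tuple[str, str, str]]:
    """Nucleotide candidates of which exactly ``n_no_start`` lack a start codon.

    Complete-ORF candidates are ATG + stop-free codons + a stop codon; the
    start-codon-less ones (pseudogene mimics) differ only in their first
    codon.  Returns (id, sequence, truth_status) triples in a seeded random
    order so status does not correlate with position.
    """
    if not (0 <= n_no_start <= n_total):
        raise ValueError("need 0 <= n_no_start <= n_total")
    rng = np.random.default_rng(seed)
    no_start_idx = set(rng.choice(n_total, size=n_no_start, replace=False).tolist())
    non_atg = [c for c in _NON_STOP_CODONS if c != "ATG"]
    out = []
    width = max(3, len(str(n_total)))
    for k in range(n_total):
        n_codons = int(rng.integers(codon_range[0], codon_range[1] + 1))
        body = "".join(rng.choice(_NON_STOP_CODONS, size=n_codons))
        stop = str(rng.choice(_STOP_CODONS))
        if k in no_start_idx:
            first = str(rng.choice(non_atg))
            status = "no_start_codon"
        else:
            first = "ATG"
            status = "complete_orf"
        out.append((f"cand_{k + 1:0{width}d}", first + body + stop, status))
    return out


# ---------------------------------------------------------------------------
# Clade references
# ---------------------------------------------------------------------------

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


@dataclass(frozen=True)
class CladeFixture:
    """Labelled clade reference set with held-out queries and optional orphans."""

    references: tuple[tuple[str, str, str], ...]  # (id, clade, sequence)
    queries: tuple[tuple[str, str, str], ...]  # (id, true_clade, sequence)
    orphans: tuple[tuple[str, str], ...] = ()  # (id, sequence); truth: not_assigned

    @property
    def reference_labels(self) -> dict[str, str]:
        return {rid: clade for rid, clade, _ in self.references}

    def all_records(self) -> list[tuple[str, str]]:
        return (
            [(rid, seq) for rid, _, seq in self.references]
            + [(qid, seq) for qid, _, seq in self.queries]
            + [(oid, seq) for oid, seq in self.orphans]
        )


def _mutate(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability p by a uniformly drawn different residue."""
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < p)[0]
    for i in hits:
        alternatives = AMINO_ACIDS.replace(chars[i], "")
        chars[i] = str(rng.choice(list(alternatives)))
    return "".join(chars)


def make_clade_references(
    n_clades: int = 5,
    per_clade: int = 4,
    within_divergence: float = 0.05,
    between_divergence: float = 0.4,
    n_queries: int = 0,
    n_orphans: int = 0,
    length: int = 250,
    seed: int = 0,
) -> CladeFixture:
    """Per-clade reference proteins generated by mutating clade ancestors.

    The clade ancestors hang off a two-lobe guide topology: a global root
    sequence spawns two lobe ancestors (each at half the between-clade
    divergence), and the clades are split across the lobes (again at half the
    between-clade divergence), so clades in different lobes sit roughly
    ``between_divergence`` apart and the root lies on the tree's central
    edge.  Each reference or held-out query leaf is its clade ancestor
    mutated at ``within_divergence`` — far below any between-clade distance.
    Queries are spread round-robin over clades.  Orphans are drawn from the
    root at the within-clade divergence: they attach near the central edge,
    with at least two clades on both sides whenever ``n_clades >= 4``, so no
    pure single-clade bipartition contains them (truth: not assignable).
    """
    if n_clades < 2 or per_clade < 2:
        raise ValueError("need n_clades >= 2 and per_clade >= 2")
    for name, p in (("within_divergence", within_divergence), ("between_divergence", between_divergence)):
        if not (0 < p < 1):
            raise ValueError(f"{name} must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    root = _random_protein(rng, length)
    clade_names = [_ROMAN[i] if i < len(_ROMAN) else f"clade{i + 1}" for i in range(n_clades)]
    lobes = (
        _mutate(root, between_divergence / 2.0, rng),
        _mutate(root, between_divergence / 2.0, rng),
    )
    n_left = n_clades // 2
    ancestors = {
        name: _mutate(lobes[0 if i < n_left else 1], between_divergence / 2.0, rng)
        for i, name in enumerate(clade_names)
    }
    references = []
    for clade in clade_names:
        for k in range(per_clade):
            references.append(
                (f"ref_{clade}_{k + 1:02d}", clade, _mutate(ancestors[clade], within_divergence, rng))
            )
    queries = []
    for k in range(n_queries):
        clade = clade_names[k % n_clades]
        queries.append(
            (f"query_{k + 1:02d}", clade, _mutate(ancestors[clade], within_divergence, rng))
        )
    orphans = tuple(
        (f"orphan_{k + 1:02d}", _mutate(root, within_divergence, rng))
        for k in range(n_orphans)
    )
    return CladeFixture(tuple(references), tuple(queries), orphans)
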