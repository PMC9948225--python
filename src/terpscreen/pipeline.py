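"""Orchestration of the full simulate -> screen -> identify -> classify workflow.

``run_simulate`` writes a complete synthetic study (spectral library, query
spectra with retention times, alkane ladder, nucleotide candidates, motif
proteins, clade references) plus sidecar truth TSVs and a manifest with the
seeds and checksums of every file.  ``run_full`` reads those inputs back
through the public readers and emits the three report tables: a candidate
summary (counts per ORF status and motif class), a product identification
table, and a clade assignment table.  All outputs are byte-identical across
reruns with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import identify as _identify
from . import phylo as _phylo
from . import screen as _screen
from . import synth as _synth
from .config import RunConfig
from .spectra import (
    read_ladder_csv,
    read_msp,
    read_query_tsv,
    write_ladder_csv,
    write_msp,
    write_query_tsv,
)

logger = logging.getLogger(__name__)

__all__ = ["run_simulate", "run_full", "SimulatedPaths"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


class SimulatedPaths:
    """Canonical file layout of a simulated fixture directory."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.library = self.root / "library.msp"
        self.ladder = self.root / "ladder.csv"
        self.query_dir = self.root / "queries"
        self.query_index = self.root / "queries.tsv"
        self.candidates = self.root / "candidates.fna"
        self.proteins = self.root / "proteins.faa"
        self.clade_refs = self.root / "clade_references.faa"
        self.clade_labels = self.root / "clade_references.tsv"
        self.clade_queries = self.root / "clade_queries.faa"
        self.truth_products = self.root / "truth_products.tsv"
        self.truth_candidates = self.root / "truth_candidates.tsv"
        self.truth_motifs = self.root / "truth_motifs.tsv"
        self.truth_clades = self.root / "truth_clades.tsv"
        self.manifest = self.root / "manifest.json"


def _rt_for_ri(ri: float, ladder) -> float:
    """Invert the linear RI convention: retention time at which a peak with
    this RI elutes, by interpolation on the ladder."""
    return float(
        np.interp(ri / 100.0, ladder.carbon_numbers.astype(float), ladder.retention_times)
    )


def run_simulate(config: RunConfig, out_dir: str | Path, force: bool = False) -> SimulatedPaths:
    """Generate a full synthetic input set under ``out_dir``.

    Refuses to touch an existing non-empty directory unless ``force`` is set.
    Every sub-generator gets a seed derived deterministically from
    ``config.seed`` via a SeedSequence spawn, so the whole directory is a pure
    function of the config.
    """
    paths = SimulatedPaths(out_dir)
    if paths.root.exists() and any(paths.root.iterdir()) and not force:
        raise FileExistsError(f"{paths.root} exists and is not empty (use force=True / --force)")
    paths.root.mkdir(parents=True, exist_ok=True)
    paths.query_dir.mkdir(exist_ok=True)

    seeds = np.random.SeedSequence(config.seed).spawn(5)
    lib_seed, query_seed, gene_seed, motif_seed, clade_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in seeds
    ]

    # spectral library + ladder
    model = _synth.SpectrumModel(
        n_peaks=config.n_peaks,
        mz_range=(config.mz_low, config.mz_high),
        decay_rate=config.decay_rate,
    )
    library = _synth.make_library(
        config.n_compounds, model, ri_range=(config.ri_low, config.ri_high), seed=lib_seed
    )
    write_msp(library, paths.library)
    ladder = _synth.make_ladder(
        c_min=config.ladder_c_min,
        c_max=config.ladder_c_max,
        t0=config.ladder_t0,
        spacing=config.ladder_spacing,
        curvature=config.ladder_curvature,
    )
    write_ladder_csv(ladder, paths.ladder)

    # enzyme query spectra: each enzyme's product is one library compound,
    # observed through the noise model at the compound's true RI
    noise = _synth.NoiseModel(
        intensity_cv=config.intensity_cv,
        dropout_p=config.dropout_p,
        contaminant_rate=config.contaminant_rate,
    )
    qrng = np.random.default_rng(query_seed)
    product_idx = qrng.integers(0, len(library), size=config.n_enzymes)
    query_rows = []
    truth_rows = []
    for k, idx in enumerate(product_idx):
        enzyme_id = f"STS-{k + 1:02d}"
        entry = library[int(idx)]
        observed = _synth.perturb_spectrum(entry.spectrum, noise, rng=qrng)
        rt = _rt_for_ri(entry.reference_ri, ladder)
        qpath = paths.query_dir / f"{enzyme_id}.tsv"
        write_query_tsv(observed, qpath)
        query_rows.append((enzyme_id, qpath.name, rt))
        truth_rows.append((enzyme_id, entry.compound_name, entry.reference_ri))
    _write_tsv(
        pd.DataFrame(query_rows, columns=["enzyme_id", "spectrum_file", "retention_time_min"]),
        paths.query_index,
    )
    _write_tsv(
        pd.DataFrame(truth_rows, columns=["enzyme_id", "compound", "reference_ri"]),
        paths.truth_products,
    )

    # nucleotide candidates
    genes = _synth.make_candidate_genes(config.n_candidates, config.n_no_start, seed=gene_seed)
    _screen.write_fasta([(gid, seq) for gid, seq, _ in genes], paths.candidates)
    _write_tsv(
        pd.DataFrame([(gid, status) for gid, _, status in genes], columns=["id", "orf_status"]),
        paths.truth_candidates,
    )

    # motif proteins
    prots = _synth.plant_motif_sequences(
        config.n_motif_pos,
        config.n_motif_neg,
        config.n_motif_noncanonical,
        length=config.protein_length,
        seed=motif_seed,
        region=config.search_region,
        nse_pattern=config.nse_dte_pattern,
    )
    _screen.write_fasta([(pid, seq) for pid, seq, _ in prots], paths.proteins)
    _write_tsv(
        pd.DataFrame([(pid, label) for pid, _, label in prots], columns=["id", "truth_label"]),
        paths.truth_motifs,
    )

    # clade references and held-out queries
    fixture = _synth.make_clade_references(
        n_clades=config.n_clades,
        per_clade=config.refs_per_clade,
        within_divergence=config.within_divergence,
        between_divergence=config.between_divergence,
        n_queries=config.n_clade_queries,
        n_orphans=config.n_orphans,
        length=config.clade_seq_length,
        seed=clade_seed,
    )
    _screen.write_fasta([(rid, seq) for rid, _, seq in fixture.references], paths.clade_refs)
    _write_tsv(
        pd.DataFrame(
            [(rid, clade) for rid, clade, _ in fixture.references], columns=["id", "clade"]
        ),
        paths.clade_labels,
    )
    query_records = [(qid, seq) for qid, _, seq in fixture.queries] + list(fixture.orphans)
    _screen.write_fasta(query_records, paths.clade_queries)
    truth_clades = [(qid, clade) for qid, clade, _ in fixture.queries] + [
        (oid, _phylo.NOT_ASSIGNED) for oid, _ in fixture.orphans
    ]
    _write_tsv(pd.DataFrame(truth_clades, columns=["id", "clade"]), paths.truth_clades)

    manifest = {
        "config": config.to_dict(),
        "derived_seeds": {
            "library": lib_seed,
            "queries": query_seed,
            "genes": gene_seed,
            "motifs": motif_seed,
            "clades": clade_seed,
        },
        "files": {
            p.relative_to(paths.root).as_posix(): _sha256(p)
            for p in sorted(paths.root.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    paths.manifest.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("simulated fixture written to %s (%d files)", paths.root, len(manifest["files"]))
    return paths


def run_screen(config: RunConfig, paths: SimulatedPaths, out_dir: Path) -> pd.DataFrame:
    """ORF triage + motif screen; writes motif_report.tsv, returns the frame."""
    candidates = _screen.read_fasta(paths.candidates)
    orf = {c.candidate_id: c.status for c in _screen.validate_candidates(candidates)}
    proteins = _screen.read_fasta(paths.proteins)
    reports = _screen.classify_candidates(
        proteins,
        region=config.search_region,
        nse_dte_pattern=config.nse_dte_pattern,
        require_order=config.require_motif_order,
    )
    frame = _screen.motif_report_frame(reports)
    frame.insert(1, "orf_status", [orf.get(i, "") for i in frame["id"]])
    _write_tsv(frame, out_dir / "motif_report.tsv")

    orf_counts = pd.Series(list(orf.values())).value_counts()
    cls_counts = frame["classification"].value_counts()
    summary = pd.DataFrame(
        {
            "metric": ["gene_candidates", "complete_orf", "no_start_codon", "internal_stop",
                       "proteins_screened", "likely_active", "non_canonical", "likely_inactive"],
            "count": [
                len(candidates),
                int(orf_counts.get("complete_orf", 0)),
                int(orf_counts.get("no_start_codon", 0)),
                int(orf_counts.get("internal_stop", 0)),
                len(reports),
                int(cls_counts.get("likely_active", 0)),
                int(cls_counts.get("non_canonical", 0)),
                int(cls_counts.get("likely_inactive", 0)),
            ],
        }
    )
    _write_tsv(summary, out_dir / "candidate_summary.tsv")
    return summary


def run_identify(config: RunConfig, paths: SimulatedPaths, out_dir: Path):
    """RI-windowed library search of every query spectrum; writes identification.tsv."""
    library = read_msp(paths.library)
    ladder = read_ladder_csv(paths.ladder)
    index = pd.read_csv(paths.query_index, sep="\t")
    queries = [
        (
            row.enzyme_id,
            read_query_tsv(paths.query_dir / row.spectrum_file, name=row.enzyme_id),
            float(row.retention_time_min),
        )
        for row in index.itertuples()
    ]
    table = _identify.identify_products(
        queries, ladder, library, ri_window=config.ri_window, min_si=config.min_si
    )
    table.to_tsv(out_dir / "identification.tsv")
    return table


def run_clades(config: RunConfig, paths: SimulatedPaths, out_dir: Path):
    """NJ tree over references + queries; writes clades.tsv and tree.nwk."""
    refs = _screen.read_fasta(paths.clade_refs)
    queries = _screen.read_fasta(paths.clade_queries)
    labels = dict(
        pd.read_csv(paths.clade_labels, sep="\t").itertuples(index=False, name=None)
    )
    scoring = _phylo.AlignmentScoring(config.align_match, config.align_mismatch, config.align_gap)
    dm = _phylo.distance_matrix(refs + queries, scoring)
    tree = _phylo.neighbor_joining(dm)
    tree.write(str(out_dir / "tree.nwk"))
    assignments = _phylo.assign_clades(tree, labels, [q for q, _ in queries])
    _write_tsv(_phylo.clade_report_frame(assignments), out_dir / "clades.tsv")
    return assignments


def run_full(config: RunConfig, fixture_dir: str | Path, out_dir: str | Path) -> dict:
    """Run screen, identify and clade stages over a fixture directory.

    Returns a dict of the three stage results; writes candidate_summary.tsv,
    motif_report.tsv, identification.tsv, clades.tsv and tree.nwk under
    ``out_dir``.  Logs every threshold used.
    """
    paths = SimulatedPaths(fixture_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "run_full thresholds: ri_window=%s min_si=%s search_region=%s nse_dte_pattern=%r "
        "require_motif_order=%s align=(%d,%d,%d)",
        config.ri_window, config.min_si, config.search_region, config.nse_dte_pattern,
        config.require_motif_order, config.align_match, config.align_mismatch, config.align_gap,
    )
    results = {}
    for stage, fn in (
        ("seq_screen", lambda: run_screen(config, paths, out)),
        ("ms_identify", lambda: run_identify(config, paths, out)),
        ("phylo_clades", lambda: run_clades(config, paths, out)),
    ):
        try:
            results[stage] = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    return results
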