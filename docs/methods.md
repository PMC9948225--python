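# Methods

`terpscreen` implements the desk side of a sesquiterpene-synthase (STS)
discovery workflow: triaging candidate genes from fungal genomes, placing the
surviving candidates on a reference phylogeny, and putatively identifying the
enzymes' volatile products from GC-MS data. This note records the models,
the tunable parameters, the numerical choices, and what the synthetic data
do and do not demonstrate.

## Spectral similarity

Query and reference EI spectra are unit-mass stick spectra. Quadrupole EI
data at 70 eV carry no reliable sub-integer mass information for C15
hydrocarbons, so all m/z are rounded half-up to integers at ingest and
intensities of colliding bins are summed (total ion intensity is conserved
exactly). Matching uses the similarity index

    SI = (1 - Σ|Iu(m/z) - It(m/z)| / Σ(Iu(m/z) + It(m/z))) × 100

summed over the union of the two m/z supports, absent peaks counting as
zero. Iu and It are *relative* intensities; because SI is not invariant to
spectrum scale, both spectra are base-peak-normalized (base peak = 100)
before scoring. That normalization convention is a package decision — "relative
intensity" admits other scalings — and is applied identically everywhere, so
SI(s, s) = 100 exactly, SI is symmetric, bounded in [0, 100], and zero
precisely when the supports are disjoint.

## Retention indices

Retention indices use the van den Dool–Kratz linear convention,

    RI = 100 · (n + (rt − t_n) / (t_{n+1} − t_n)),

appropriate for temperature-programmed GC runs (the emulated method ramps
3 °C/min); the logarithmic Kovats form applies only to isothermal runs. RI
is exact at every alkane rung, strictly monotone in retention time, and
invariant under affine re-timing of ladder and peak together. Retention
times outside the calibrated alkane span raise an error rather than
extrapolate.

## Library search

Only library entries within `ri_window` RI units of the query's RI are
scored; hits at or above `min_si` are ranked by descending SI, ties broken
by ascending |ΔRI| then compound name (a total order; real data essentially
never tie). Defaults: `ri_window = 15`, `min_si = 90` — the smallest SI at
which the emulated study still names a product is 91, so 90 is the most
permissive threshold that preserves that reporting convention. Queries with
no passing hit are reported as "Unknown compound" with SI "ND", the same
shape a GC-MS product table uses for unidentified majors.

## Sequence triage

`validate_orf` partitions nucleotide candidates into `complete_orf` (ATG
start, length ≡ 0 mod 3, no premature in-frame stop), `no_start_codon`
(first codon ≠ ATG, checked first), and `internal_stop` (everything else);
codons containing N never count as stops.

Motif scanning targets the two Mg²⁺-binding signatures of class-I terpene
synthases. The aspartate-rich region is sought as, in order of precedence,
the canonical `D[DEN]..D`, the weaker `DD...` variant, then the
glutamate-substituted non-canonical forms `E[DEN]..E` / `EE`; within a tier
the leftmost match wins. The search region defaults to residue starts
60–160, the typical placement of this motif in fungal STSs; it is
configurable because exact boundaries vary across lineages. The NSE/DTE
triad uses the configurable consensus `[ND]D[LIVMFYT].[ST]...E` and, by
default, must start downstream of the aspartate-rich match (or, when that
motif is absent, downstream of the search-region start — signature-less
proteins must still be scanned). `X` matches wildcard positions only, never
a stated residue class.

Classification: `likely_inactive` iff both motifs are absent;
`non_canonical` iff the aspartate-rich region is glutamate-substituted;
`likely_active` otherwise. The non-canonical class is kept separate rather
than folded into active/inactive because such enzymes can retain activity.

## Phylogeny and clade assignment

Pairwise distances are global-alignment identity distances,
d = 1 − identities / aligned columns, from Needleman–Wunsch with integer
scoring (default match 1, mismatch 0, linear gap −1; identity scoring avoids
shipping a substitution matrix as hidden state). Among co-optimal alignments
the implementation canonically maximizes (score, identities, aligned pairs)
lexicographically — the third key minimizes columns — which makes the
distance a well-defined, symmetric function of the pair. The three
quantities are packed into one int64 per DP cell, which is why scoring
parameters must be integers.

Trees come from classical Saitou–Nei neighbor joining: deterministic
lowest-index tie-break in the Q criterion; negative branch estimates clamped
to zero with the deficit moved to the sibling edge so the joined pair's path
length is preserved. On additive matrices the tip-to-tip distances of the
output reproduce the input to float round-off.

A query leaf is assigned clade C when some tree bipartition puts only
clade-C references (at least one) on the query's side; among such pure
bipartitions the one with the smallest separating side — equivalently the
maximal pure clade context — is used, and support is the fraction of C's
references on the query's side. A query grafted inside an intact clade
scores support 1.0; one that splits a clade scores fractionally; a query
whose every bipartition side mixes clades (an orphan sitting between
lineages) is `not_assigned`.

## Synthetic data: what it emulates, what it does not

* **Spectra** — `n_peaks` (default 25) distinct m/z uniform on 41–220 (the
  sesquiterpene fragment range), intensities from an exponential
  rank-abundance law `100·exp(−0.15·rank)`: sparse, single-base-peak spectra
  with EI-like dynamic range. No fragmentation chemistry: real isomer pairs
  (e.g. cadinadiene isomers) share far more peaks than two random synthetic
  compounds, so the identification-power results bound performance on
  *distinguishable* compounds, not on near-isobaric isomer discrimination.
* **Noise** — log-normal multiplicative intensity noise (CV 0.05), Bernoulli
  peak dropout (p 0.02), Poisson(1) contaminant peaks at unoccupied m/z with
  relative intensity Uniform(1, 10) — minor background/bleed-like peaks.
* **Ladder** — C8–C30, first rung at 8 min, 3.2 min per carbon (the spacing
  a ~3 °C/min ramp produces), optional curvature and timing jitter.
* **Proteins** — uniform-random backbones (length 350) with motifs planted
  at class-I-like positions; the non-canonical plant contains glutamates and
  no aspartate, and the NSE/DTE plant is placed past the aspartate search
  region so its (N/D)D head cannot read as an in-region DD variant.
  Negatives are rejection-sampled against all motif patterns. Because
  planting uses the same pattern vocabulary the scanner searches, perfect
  precision/recall on these fixtures validates the *scanner logic*, not
  motif discovery in real proteomes.
* **Candidate genes** — stop-free ORFs of 250–400 codons; a chosen count
  lack the ATG start, mimicking pseudogene fragments.
* **Clade references** — a two-lobe guide topology: a root sequence spawns
  two lobe ancestors, clades split across the lobes, every divergence step
  at half the between-clade rate (default between 0.4, within 0.05 per
  site). This puts the root on the tree's central edge, so a root-derived
  orphan attaches with at least two clades on each side (for ≥ 4 clades) and
  is provably unassignable, while held-out queries drawn from clade
  ancestors nest inside their clades.

All generators are bit-reproducible for a fixed seed; truth labels are
emitted alongside every fixture so tests never re-derive ground truth from
the code under test.

## Problem sizes

The shipped test suite and acceptance checks run at the sizes the package
treats as standard working scale: 50-compound libraries with one noisy
replicate per compound for identification power; 310 planted proteins for
the motif screen; 86 nucleotide candidates; 50 random additive matrices of
6–12 leaves for neighbor joining; 5 clades × 4 references with 10 held-out
queries and one orphan for clade recovery. The full suite completes in well
under a minute on one core.

## Known limitations

* SI is the only match statistic; dot-product, reverse and probability
  scores are out of scope, as are isotope patterns and quantification.
* No chromatographic peak picking or deconvolution — queries are assumed to
  be single-component spectra.
* Clade labels are defined relative to the user-supplied labelled reference
  set; the package does not ship a curated STS reference panel.
* NJ gives no branch support; bootstrap and ML/Bayesian inference are
  non-goals.
* The alignment DP is O(L²) per pair and all-pairs distance computation is
  O(n²) pairs; fine for reference panels of tens of sequences, not for
  thousands.
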