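# Methods

## Scope and model

The package analyses sort-seq peptidome screens in which a library of
17-residue peptides, tiled across protein coding sequences at a 5-residue
step, is fused to a fluorescent stability reporter, sorted into four FACS
gates ordered by increasing stability, and sequenced gate by gate.  The
statistical core is (i) the Protein Stability Index (PSI), the
frequency-weighted mean gate number of a peptide, and (ii) a ridge
logistic regression on amino-acid composition that converts
PSI-derived binary labels into a degron probability for any 17-mer.

## Library design

Coding sequences are validated (in-frame, no internal stops, standard
20-letter alphabet after translation; terminal stop codons stripped before
tiling, since the peptides are expressed as C-terminal fusions and a stop
inside a tile would truncate the fusion).  Tiles start at 0, 15, 30, … nt
while a 51-nt window fits.  When the tail residues would otherwise be
uncovered, `anchor_final=True` emits one extra tile anchored at the 3′
end, flagged `anchored_final`; the default drops the remainder, reflecting
that C-terminal ends are not the assay's focus.  Coordinates are 0-based
half-open internally; user-facing residue positions are 1-based.
Proteins with non-standard residues (U, X) are rejected rather than
silently skipped.

## Synthetic screens

The simulator generates uniform-random proteins (default 135 proteins of
100–300 residues, ≈ 5,000 tiles — the scale at which the recovery
properties below are measured), with coding sequences drawn uniformly over
synonymous codons.  Ground truth: each peptide's degron probability is
logistic(intercept + Σ per-residue weights).  Default weights are +0.25
for hydrophobics (L, I, V, F, W, Y, M, C) and −0.25 for charged residues
(D, E, K, R), with intercept −0.85 centring the latent score for a random
composition; this mirrors the hydrophobicity preference of quality-control
degrons and gives the hydropathy-trend analysis something real to detect.
The latent stability index is the linear map PSI_true = 4 − 3·p_true; any
monotone map would do, the linear one makes recovery measurable.

Sorting is modelled as each cell scattering around its peptide's PSI_true
with Gaussian jitter (σ = 0.5 PSI units) and being cut at gate boundaries
1.75 / 2.5 / 3.25.  FACS collects a fixed number of cells per gate
(`cells_per_bin`, default 2×10⁵) multinomially over peptides in proportion
to their analytic Gaussian gate occupancy; sequencing then draws
`reads_per_bin` (default 5×10⁵) reads multinomially in proportion to the
sorted cells.  Reads are the configured prefix (sample barcode `N`s filled
randomly, then the 5′ vector flank) + tile DNA + suffix, with i.i.d.
per-base substitutions at `read_error_rate` (default 0.001).  Not
modelled: PCR amplification bias, FACS spillover, doublets, indels,
quality-score structure — so passing tests demonstrate correctness of the
analysis under a clean generative model, not robustness to every artefact
of real sequencing.

All randomness derives from a single seed through named sub-streams, so
every output is bit-reproducible.

## Read quantification

Trimming locates the 51-nt insert either at a fixed offset or after an
exact occurrence of the configured vector anchor; reads without the anchor
or too short are unmatched, not errors.  Matching allows at most one
substitution: an exact hash lookup first, then a pigeonhole search (any
sequence within Hamming distance 1 of a library member agrees exactly
with one of its two halves) verified by direct comparison.  A quadratic
full-scan matcher with the same contract is kept as an independent oracle
and used by the tests.  Reads at distance ≤ 1 from two or more members are
ambiguous and dropped; identical tiles from different proteins are
collapsed for matching and their count duplicated into each member row,
flagged `shared`, preserving per-protein profiles.  Indels are not
handled: substitution errors dominate the targeted platform, and an
indel-bearing read simply falls through as unmatched.  Each gate is
normalised to 10⁶ reads; empty gates stay zero and are flagged, and only
an entirely empty screen is an error.

## PSI and residue profiles

PSI uses the normalised frequencies, so equalised per-bin totals weight
gates equally regardless of raw depth (this differs from computing PSI on
raw counts when depths are unequal — deliberate and tested).  Peptides
with zero reads are omitted rather than scored.  Two residue projections
are available: `central` places each tile's PSI at its ninth residue;
`coverage-mean` (default) averages every tile covering the residue, which
matches how a per-residue stability profile is usually drawn.  Interior
residues are covered by 3–4 tiles at the 5-residue step.  Smoothing is a
five-residue (± 2) running median; windows truncate at protein ends rather
than padding (no invented boundary values), missing residues carry NaN and
are skipped by the median, never imputed as zero.

## Degron model

Features are amino-acid composition — counts (default) or counts/17 —
because a 17-mer's degron propensity in this framework is treated as
order-free; predictions are therefore invariant under peptide shuffling.
Labels: total raw reads ≥ 50; PSI < 2.2 → 1, PSI > 2.8 → 0; mid-range
excluded.  PSI exactly at a threshold is excluded and counted separately
(the verbal rules are contradictory at the endpoints; excluding them is
the conservative reading).  The objective is mean logistic loss +
(λ/2)·‖w‖², λ default 0.001, intercept unpenalised — stated explicitly
because λ's effect depends on the mean-vs-sum convention.  λ's scale also
interacts with the feature mode, so it is a plain config value.  The
solver is damped Newton with backtracking line search to a gradient-norm
tolerance of 10⁻⁸: deterministic, order-independent, no random state;
non-convergence raises an error carrying the final gradient norm.  A
matched-objective scikit-learn logistic regression (C = 1/(nλ)) serves as
an independent cross-check in the tests, never as the implementation.

Scanning assigns residue *i* ∈ [9, L−8] the probability of the 17-mer
centred on it; terminal 8 residues per end are undefined.  An optional
cubic smoothing spline over the defined positions is provided for
plotting, off by default — the discrete track is canonical.  Degron calls
are maximal runs of consecutive defined residues with probability above
the cutoff (default 0.85); NaNs break runs; sub-`min_length` runs drop.
On-disk calls use 0-based half-open coordinates (BED-like), in-memory
calls 1-based inclusive.

## Structural characterisation

Hydropathy is the mean Kyte–Doolittle value over the peptide; the trend
statistic is Spearman's ρ against predicted probability, with a NaN result
(flagged) when either variable is constant.

Secondary structure comes from a documented torsion/curvature classifier,
not DSSP: helix requires φ ∈ (−100°, −30°) and ψ ∈ (−80°, −5°) in runs of
≥ 4; sheet requires φ ∈ (−180°, −40°) and ψ ∈ (90°, 180°] ∪ [−180°, −170°)
in runs of ≥ 3; remaining residues where the CA chain direction turns by
≥ 70° over five residues are turns when CA(i−2)–CA(i+2) spans ≤ 6.5 Å,
bends otherwise; everything else, including chain ends without torsions
and residues with missing backbone atoms, is `other`.  Hydrogen-bond-based
assignment is out of scope; users with DSSP output can supply it as an
external per-residue annotation TSV, accepted everywhere the built-in
classifier's output is.  Torsions follow the IUPAC sign convention
(cis = 0°), verified against planar-point oracles and an ideal-geometry
backbone builder (NeRF with standard bond lengths/angles) that is itself
part of the public API for generating test structures.

ASA is Shrake–Rupley: 960 golden-spiral points per atom on the
probe-expanded sphere (probe 1.4 Å), occlusion by KD-tree neighbour
search, residue ASA as the sum over its heavy atoms.  The point lattice is
fixed in the input frame: results are exactly translation-invariant and
rotation-invariant only to lattice resolution (~1%), the price of
determinism.  Van der Waals radii: C 1.70, N 1.55, O 1.52, S 1.80 Å,
others falling back to carbon, overridable.  Relative exposure divides by
the Tien et al. (2013) theoretical maximum-ASA table, clipped to [0, 1];
the exposed/buried cutoff is user-set, with no claimed default.  The
degron-vs-proteome comparison reports secondary-structure class
proportions for residues above the probability cutoff against all
residues, and a two-sided Mann–Whitney U on ASA (exact for both samples
≤ 20, otherwise normal approximation with tie correction), computed
residue-level.

## Pipeline

`run_pipeline` executes simulate → count → psi → train → predict →
features on a synthetic screen, writing TSV/JSON outputs and a manifest
(version, full config, output SHA-256 checksums).  With `resume=True`, a
stage is skipped while its outputs match the recorded checksums; once any
stage reruns, everything downstream reruns.  Defaults live in one
constants table (51/36/17, 10⁶, 1 mismatch, 50 reads, 2.2/2.8, λ = 0.001,
window 5, cutoff 0.85, probe 1.4 Å) asserted by a dedicated test.

## Numerical choices and limitations

- PSI of an all-zero frequency vector is an error (undefined), never 0.
- The matcher is Hamming-only; libraries with members within distance 2 of
  each other will show elevated ambiguity.
- Gate-occupancy bias: with σ = 0.5 the expected estimated PSI compresses
  toward the centre at extreme PSI_true (up to ≈ 0.2 PSI units near the
  boundaries), so PSI recovery RMSE plateaus at that bias rather than at 0
  as depth grows; weight recovery is unaffected because labels depend only
  monotonically on the latent score.
- Test and validation problem sizes (≈ 1,500-tile screens for most tests,
  ≈ 5,000 tiles at 5×10⁵ reads/bin for recovery measurements) were chosen
  as the smallest scales at which the measured properties are stable.
- The simulator's uniform-random proteomes lack real composition bias,
  domain structure and homology; recovery results certify the estimator
  chain, not performance on any particular organism's proteome.
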