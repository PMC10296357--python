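"""Synthetic sort-seq screens with known ground truth.

The simulator emulates the peptidome screen end to end: random proteins
are tiled into the 17-mer library; each peptide's true degron probability
follows a logistic model on amino-acid composition with a known weight
vector; the latent stability index maps linearly onto the 1-4 gate scale
(PSI_true = 4 - 3*p_true); sorted cells scatter around PSI_true with
Gaussian jitter and are cut into four gates; and sequencing draws reads
multinomially from the sorted cells of each gate.  Optionally raw reads
carrying the vector flanks and substitution errors are emitted, so the
trimming/matching stage is exercised too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .library import (
    DEFAULT_FLANK3,
    DEFAULT_FLANK5,
    STANDARD_AA,
    ProteinRecord,
    Tile,
    tile_cds,
)

__all__ = [
    "DEFAULT_TRUE_WEIGHTS",
    "SimConfig",
    "GroundTruth",
    "generate_proteome",
    "simulate_bins",
    "emit_reads",
    "simulate_screen",
    "write_fastq",
]

# Ground-truth degron weights: hydrophobic residues promote degradation,
# charged residues oppose it, mirroring the hydrophobicity preference of
# quality-control degrons.
DEFAULT_TRUE_WEIGHTS: dict[str, float] = {
    aa: (0.25 if aa in "LIVFWYMC" else -0.25 if aa in "DEKR" else 0.0)
    for aa in STANDARD_AA
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic screen.

    ``cells_per_bin`` is the number of cells FACS collects in each gate;
    ``reads_per_bin`` the sequencing depth per gate.  ``gate_sigma`` is the
    cell-to-cell Gaussian jitter (PSI units) around a peptide's latent
    PSI_true, and ``bin_boundaries`` the three thresholds cutting the
    jittered score into gates 1-4.
    """

    n_proteins: int = 135
    protein_length_range: tuple[int, int] = (100, 300)
    true_aa_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_WEIGHTS)
    )
    true_intercept: float = -0.85
    cells_per_bin: int = 200_000
    reads_per_bin: int = 500_000
    read_error_rate: float = 0.001
    gate_sigma: float = 0.5
    bin_boundaries: tuple[float, float, float] = (1.75, 2.5, 3.25)
    read_prefix: str = "NNN" + DEFAULT_FLANK5
    read_suffix: str = DEFAULT_FLANK3
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.protein_length_range
        if not (17 <= lo <= hi):
            raise ValueError("protein_length_range must satisfy 17 <= min <= max")
        b = self.bin_boundaries
        if not (b[0] < b[1] < b[2]):
            raise ValueError("bin_boundaries must be strictly increasing")
        if not (0 <= self.read_error_rate < 1):
            raise ValueError("read_error_rate must be in [0, 1)")
        if self.cells_per_bin <= 0 or self.reads_per_bin <= 0:
            raise ValueError("cells_per_bin and reads_per_bin must be positive")
        if self.gate_sigma <= 0:
            raise ValueError("gate_sigma must be positive")
        missing = set(STANDARD_AA) - set(self.true_aa_weights)
        if missing:
            raise ValueError(f"true_aa_weights missing residues {sorted(missing)}")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass
class GroundTruth:
    """Per-peptide latent truth: degron probability and latent PSI."""

    table: pd.DataFrame  # peptide_id, peptide, p_true, psi_true

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _codon_choices() -> dict[str, list[str]]:
    table = unambiguous_dna_by_id[1]
    choices: dict[str, list[str]] = {aa: [] for aa in STANDARD_AA}
    for codon, aa in table.forward_table.items():
        if aa in choices:
            choices[aa].append(codon)
    return {aa: sorted(c) for aa, c in choices.items()}


def generate_proteome(cfg: SimConfig) -> list[ProteinRecord]:
    """Random proteins: uniform residues, uniform synonymous codons."""
    lo, hi = cfg.protein_length_range
    rng = cfg.rng(stream=1)
    codons = _codon_choices()
    records = []
    for i in range(cfg.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        aa_idx = rng.integers(0, 20, size=length)
        aa_seq = "".join(STANDARD_AA[j] for j in aa_idx)
        cds = "".join(
            codons[aa][rng.integers(0, len(codons[aa]))] for aa in aa_seq
        )
        records.append(ProteinRecord(id=f"sim{i:04d}", aa_seq=aa_seq, cds_seq=cds))
    return records


def true_degron_probability(peptide: str, weights: Mapping[str, float], intercept: float) -> float:
    """logistic(intercept + sum of per-residue weights) for one peptide."""
    return float(expit(intercept + sum(weights[aa] for aa in peptide)))


def _gate_occupancy(psi_true: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """P(cell falls in gate g) for each peptide: Gaussian mass between boundaries."""
    edges = np.concatenate(([-np.inf], cfg.bin_boundaries, [np.inf]))
    z = (edges[None, :] - psi_true[:, None]) / cfg.gate_sigma
    cdf = norm.cdf(z)
    return np.diff(cdf, axis=1)  # (n_peptides, 4)


def simulate_bins(tiles: Sequence[Tile], cfg: SimConfig):
    """Sort the library and sequence each gate.

    Returns a :class:`~ygpsp.counting.BinCountTable` of raw per-gate read
    counts (total exactly ``reads_per_bin`` per gate) and the
    :class:`GroundTruth`.
    """
    from .counting import GATES, BinCountTable

    if not tiles:
        raise ValueError("no tiles to simulate")
    rng = cfg.rng(stream=2)
    peptides = [t.peptide for t in tiles]
    ids = [t.peptide_id for t in tiles]
    p_true = np.array(
        [true_degron_probability(p, cfg.true_aa_weights, cfg.true_intercept)
         for p in peptides]
    )
    psi_true = 4.0 - 3.0 * p_true
    occupancy = _gate_occupancy(psi_true, cfg)  # library members equally abundant

    counts = np.zeros((len(tiles), 4), dtype=np.int64)
    for g in range(4):
        mass = occupancy[:, g]
        if mass.sum() <= 0:
            continue
        cells = rng.multinomial(cfg.cells_per_bin, mass / mass.sum())
        if cells.sum() == 0:
            continue
        counts[:, g] = rng.multinomial(cfg.reads_per_bin, cells / cells.sum())

    raw = pd.DataFrame(
        counts, index=pd.Index(ids, name="peptide_id"),
        columns=[f"gate{g}" for g in GATES],
    )
    truth = GroundTruth(
        pd.DataFrame(
            {"peptide_id": ids, "peptide": peptides,
             "p_true": p_true, "psi_true": psi_true}
        )
    )
    return BinCountTable(raw=raw), truth


def _mutate_reads(reads: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """In-place per-base substitutions on a (n, L) uint8 base matrix."""
    if rate <= 0 or reads.size == 0:
        return
    n, L = reads.shape
    n_err = rng.binomial(L, rate, size=n)
    hit = np.nonzero(n_err)[0]
    for i in hit:
        pos = rng.choice(L, size=n_err[i], replace=False)
        for p in pos:
            old = reads[i, p]
            new = _BASES[rng.integers(0, 3)]
            if new == old:  # shift to a different base
                new = _BASES[3] if old != _BASES[3] else _BASES[2]
            reads[i, p] = new


def emit_reads(
    counts, tiles: Sequence[Tile], cfg: SimConfig
) -> dict[int, list[str]]:
    """Render per-gate reads: prefix + tile DNA + suffix, with errors.

    The multiset size per gate equals the gate's raw count total; 'N'
    placeholders in the prefix (sample barcodes) are filled with random
    bases per read before error injection.
    """
    rng = cfg.rng(stream=3)
    by_id = {t.peptide_id: t for t in tiles}
    template = cfg.read_prefix + "A" * 51 + cfg.read_suffix
    L = len(template)
    insert_at = len(cfg.read_prefix)
    reads_by_gate: dict[int, list[str]] = {}
    raw = counts.raw
    for g in (1, 2, 3, 4):
        col = raw[f"gate{g}"]
        total = int(col.sum())
        mat = np.empty((total, L), dtype=np.uint8)
        row = 0
        for pid, c in col.items():
            if c == 0:
                continue
            tile = by_id[pid]
            line = np.frombuffer(
                (cfg.read_prefix + tile.dna + cfg.read_suffix).encode(), dtype=np.uint8
            )
            mat[row : row + c] = line
            row += c
        # fill barcode Ns with random bases
        n_pos = np.nonzero(np.frombuffer(template.encode(), dtype=np.uint8) == ord("N"))[0]
        n_pos = n_pos[n_pos < insert_at]
        if len(n_pos) and total:
            mat[:, n_pos] = _BASES[rng.integers(0, 4, size=(total, len(n_pos)))]
        _mutate_reads(mat, cfg.read_error_rate, rng)
        order = rng.permutation(total)
        reads_by_gate[g] = [mat[i].tobytes().decode() for i in order]
    return reads_by_gate


def write_fastq(reads: Sequence[str], path: str | Path, gate: int) -> None:
    """Plain FASTQ with a constant quality string (qualities are not modelled)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@g{gate}_read{i}\n{r}\n+\n{'I' * len(r)}\n")


def simulate_screen(cfg: SimConfig, with_reads: bool = False):
    """Convenience: proteome -> tiles -> sorted counts (-> reads)."""
    proteins = generate_proteome(cfg)
    tiles = [t for p in proteins for t in tile_cds(p)]
    counts, truth = simulate_bins(tiles, cfg)
    reads = emit_reads(counts, tiles, cfg) if with_reads else None
    return proteins, tiles, counts, truth, reads
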