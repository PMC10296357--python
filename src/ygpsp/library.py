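"""Tiled peptide library design.

A protein coding sequence is divided into 51-nt fragments advancing in
15-nt steps, so that neighbouring fragments share a 36-nt overlap and each
fragment translates to a 17-residue peptide shifted by 5 residues from its
predecessor.  Fragments receive vector-complementary flanks for synthesis
and Gibson assembly into the expression vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "STANDARD_AA",
    "STOP_CODONS",
    "DEFAULT_FLANK5",
    "DEFAULT_FLANK3",
    "ProteinRecord",
    "Tile",
    "Oligo",
    "translate_cds",
    "strip_terminal_stop",
    "tile_cds",
    "add_flanks",
    "read_cds_fasta",
    "tiles_to_manifest",
    "manifest_to_tiles",
    "write_oligo_fasta",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Vector-side primer-binding anchors of the expression vector: the forward
# primer sequence and the reverse complement of the reverse primer.
DEFAULT_FLANK5 = "GATCAGCTGGCTCACCCG"
DEFAULT_FLANK3 = "GCTAGCTGACTGATCATGTAATTAG"


class LibraryDesignError(ValueError):
    """Raised for invalid coding sequences or tiling requests."""


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (no terminal stop) to amino acids."""
    if len(cds) % 3:
        raise LibraryDesignError(f"CDS length {len(cds)} is not a multiple of 3")
    return str(Seq(cds).translate())


def strip_terminal_stop(cds: str) -> str:
    """Drop a terminal stop codon if present; error if length is not a codon multiple."""
    cds = cds.upper()
    if len(cds) % 3:
        raise LibraryDesignError(f"CDS length {len(cds)} is not a multiple of 3")
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with its coding sequence, validated for tiling.

    The stored ``cds_seq`` is stop-stripped and translates exactly to
    ``aa_seq``; internal stops and non-standard residues are rejected.
    """

    id: str
    aa_seq: str
    cds_seq: str

    @classmethod
    def from_cds(cls, id: str, cds: str) -> "ProteinRecord":
        cds = strip_terminal_stop(cds)
        bad = set(cds) - set("ACGT")
        if bad:
            raise LibraryDesignError(f"{id}: non-ACGT characters in CDS: {sorted(bad)}")
        aa = translate_cds(cds)
        if "*" in aa:
            raise LibraryDesignError(f"{id}: internal stop codon in CDS")
        nonstd = set(aa) - set(STANDARD_AA)
        if nonstd:
            raise LibraryDesignError(
                f"{id}: non-standard residues {sorted(nonstd)} are not supported"
            )
        return cls(id=id, aa_seq=aa, cds_seq=cds)

    def __post_init__(self) -> None:
        if len(self.cds_seq) % 3:
            raise LibraryDesignError(f"{self.id}: CDS length not a multiple of 3")
        if translate_cds(self.cds_seq) != self.aa_seq:
            raise LibraryDesignError(f"{self.id}: CDS does not translate to aa_seq")
        if "*" in self.aa_seq:
            raise LibraryDesignError(f"{self.id}: stop symbol in aa_seq")


@dataclass(frozen=True)
class Tile:
    """One 51-nt library fragment and its 17-residue peptide.

    Coordinates are 0-based half-open into the stop-stripped CDS;
    ``aa_start = nt_start // 3``.  ``anchored_final`` marks the optional
    extra 3'-anchored tile covering a remainder that the regular step
    would miss.
    """

    protein_id: str
    tile_index: int
    nt_start: int
    dna: str
    peptide: str
    anchored_final: bool = False

    @property
    def aa_start(self) -> int:
        return self.nt_start // 3

    @property
    def peptide_id(self) -> str:
        return f"{self.protein_id}|t{self.tile_index:04d}"

    def __post_init__(self) -> None:
        if self.nt_start % 3:
            raise LibraryDesignError("tile nt_start must be codon-aligned")
        if len(self.dna) != 3 * len(self.peptide):
            raise LibraryDesignError("tile dna/peptide length mismatch")
        if translate_cds(self.dna) != self.peptide:
            raise LibraryDesignError("tile dna does not translate to peptide")


@dataclass(frozen=True)
class Oligo:
    """A synthesis oligo: 5' flank + tile DNA + 3' flank."""

    tile: Tile
    flank5: str
    flank3: str

    @property
    def sequence(self) -> str:
        return self.flank5 + self.tile.dna + self.flank3


def tile_cds(
    protein: ProteinRecord,
    tile_nt: int = 51,
    step_nt: int = 15,
    anchor_final: bool = False,
) -> list[Tile]:
    """Tile a CDS into ``tile_nt``-long fragments every ``step_nt`` nt.

    Starts are 0, step, 2*step, ... while the window fits.  When
    ``anchor_final`` is set and the last regular window does not reach the
    CDS end, one extra tile anchored at ``len(cds) - tile_nt`` is emitted
    and flagged, so the C-terminal residues are covered.
    """
    if tile_nt % 3 or step_nt % 3:
        raise LibraryDesignError("tile_nt and step_nt must be codon multiples")
    cds = protein.cds_seq
    if len(cds) < tile_nt:
        raise LibraryDesignError(
            f"{protein.id}: protein too short to tile "
            f"({len(cds)} nt < {tile_nt} nt)"
        )
    starts = list(range(0, len(cds) - tile_nt + 1, step_nt))
    anchored: list[int] = []
    last_anchor = len(cds) - tile_nt
    if anchor_final and last_anchor not in starts:
        anchored.append(last_anchor)

    tiles = []
    for idx, s in enumerate(starts + anchored):
        dna = cds[s : s + tile_nt]
        tiles.append(
            Tile(
                protein_id=protein.id,
                tile_index=idx,
                nt_start=s,
                dna=dna,
                peptide=protein.aa_seq[s // 3 : s // 3 + tile_nt // 3],
                anchored_final=s in anchored,
            )
        )
    return tiles


def add_flanks(tile: Tile, flank5: str = DEFAULT_FLANK5, flank3: str = DEFAULT_FLANK3) -> Oligo:
    """Attach vector-complementary primer-binding flanks to a tile."""
    for name, f in (("flank5", flank5), ("flank3", flank3)):
        if not f or set(f) - set("ACGT"):
            raise LibraryDesignError(f"{name} must be a non-empty ACGT string")
    if not tile.dna:
        raise LibraryDesignError("empty tile")
    return Oligo(tile=tile, flank5=flank5, flank3=flank3)


# ---------------------------------------------------------------------------
# I/O

def read_cds_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord.from_cds(rec.id, str(rec.seq).upper()))
    if not records:
        raise LibraryDesignError(f"no sequences found in {path}")
    return records


MANIFEST_COLUMNS = [
    "peptide_id", "protein_id", "tile_index", "nt_start", "aa_start",
    "dna", "peptide", "anchored_final",
]


def tiles_to_manifest(tiles: Iterable[Tile]) -> pd.DataFrame:
    rows = [
        {
            "peptide_id": t.peptide_id,
            "protein_id": t.protein_id,
            "tile_index": t.tile_index,
            "nt_start": t.nt_start,
            "aa_start": t.aa_start,
            "dna": t.dna,
            "peptide": t.peptide,
            "anchored_final": t.anchored_final,
        }
        for t in tiles
    ]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def manifest_to_tiles(manifest: pd.DataFrame) -> list[Tile]:
    return [
        Tile(
            protein_id=r.protein_id,
            tile_index=int(r.tile_index),
            nt_start=int(r.nt_start),
            dna=r.dna,
            peptide=r.peptide,
            anchored_final=bool(r.anchored_final),
        )
        for r in manifest.itertuples(index=False)
    ]


def write_oligo_fasta(oligos: Sequence[Oligo], path: str | Path) -> None:
    with open(path, "w") as fh:
        for o in oligos:
            fh.write(f">{o.tile.peptide_id}\n{o.sequence}\n")
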