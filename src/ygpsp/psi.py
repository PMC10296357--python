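"""Protein Stability Index: per-peptide scores and per-residue profiles.

The PSI of a peptide is its frequency-weighted mean gate number,

    PSI_i = sum_g g * f_{i,g} / sum_g f_{i,g},   g in {1,2,3,4},

computed from the normalised per-gate frequencies, so a value near 1 means
the peptide drives the reporter into the lowest-fluorescence gates
(a strong degron) and a value near 4 means it leaves the reporter stable.

Peptide scores are projected onto protein residues in one of two ways:
placing each tile's PSI at its central residue (position nine of the
17-mer), or averaging over every tile that covers the residue.  The
per-residue track is then smoothed with a five-residue running median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import GATES, BinCountTable

__all__ = [
    "PsiRecord",
    "ResidueProfile",
    "compute_psi",
    "psi_table",
    "residues_from_tiles",
    "running_median",
]

CENTRAL_OFFSET = 8  # 0-based offset of "position nine" in a 17-mer


class PsiError(ValueError):
    pass


def compute_psi(frequencies: Sequence[float]) -> float:
    """Frequency-weighted mean gate number; requires some mass somewhere."""
    f = np.asarray(frequencies, dtype=float)
    if f.shape != (4,):
        raise PsiError("expected exactly four per-gate frequencies")
    if (f < 0).any():
        raise PsiError("negative frequency")
    total = f.sum()
    if total == 0:
        raise PsiError("PSI undefined: all four frequencies are zero")
    return float(np.dot(np.arange(1, 5), f) / total)


@dataclass(frozen=True)
class PsiRecord:
    peptide_id: str
    psi: float
    total_reads: int
    f: tuple[float, float, float, float]


def psi_table(counts: BinCountTable) -> pd.DataFrame:
    """One PSI record per peptide with any reads.

    Columns: psi, total_reads (raw, all gates combined) and the four
    normalised frequencies f1..f4.  Peptides with zero reads are omitted.
    Uses normalised counts as the frequencies; call
    :func:`ygpsp.counting.normalize_bins` first.
    """
    if counts.normalized is None:
        raise PsiError("counts are not normalised; run normalize_bins first")
    norm = counts.normalized.to_numpy(dtype=float)
    total_reads = counts.raw.sum(axis=1).to_numpy()
    mass = norm.sum(axis=1)
    keep = mass > 0
    gates = np.arange(1, 5)
    psi = np.full(len(norm), np.nan)
    psi[keep] = (norm[keep] @ gates) / mass[keep]
    df = pd.DataFrame(
        {
            "peptide_id": counts.raw.index,
            "psi": psi,
            "total_reads": total_reads,
            "f1": norm[:, 0], "f2": norm[:, 1], "f3": norm[:, 2], "f4": norm[:, 3],
        }
    )
    return df[keep].reset_index(drop=True)


@dataclass
class ResidueProfile:
    """Per-residue track along one protein (1-based positions).

    ``raw`` and ``smoothed`` are float arrays of the protein length with
    NaN at residues no scored tile covers; ``coverage`` counts scoring
    tiles per residue.
    """

    protein_id: str
    raw: np.ndarray
    smoothed: np.ndarray
    coverage: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, len(self.raw) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_id,
                "position": self.positions,
                "raw": self.raw,
                "smoothed": self.smoothed,
                "coverage": self.coverage,
            }
        )


def running_median(track: Sequence[float], window: int = 5) -> np.ndarray:
    """NaN-aware centred running median, truncated at the ends.

    Missing (NaN) inputs stay missing; defined outputs take the median of
    the defined values inside the window.
    """
    if window % 2 == 0 or window < 1:
        raise PsiError("window must be odd and >= 1")
    x = np.asarray(track, dtype=float)
    half = window // 2
    out = np.full_like(x, np.nan)
    for i in range(len(x)):
        if math.isnan(x[i]):
            continue
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        win = x[lo:hi]
        win = win[~np.isnan(win)]
        out[i] = np.median(win)
    return out


def residues_from_tiles(
    psis: pd.DataFrame,
    manifest: pd.DataFrame,
    track: str = "coverage-mean",
    window: int = 5,
    protein_lengths: Mapping[str, int] | None = None,
) -> dict[str, ResidueProfile]:
    """Project per-peptide PSI onto residues, per protein.

    ``track='central'`` places each tile's value at residue aa_start+9
    (1-based); ``track='coverage-mean'`` averages every tile covering the
    residue.  Protein lengths default to the tiling coverage end.
    """
    if track not in ("central", "coverage-mean"):
        raise PsiError(f"unknown track {track!r}")
    merged = psis.merge(
        manifest[["peptide_id", "protein_id", "aa_start", "peptide"]],
        on="peptide_id", how="left",
    )
    if merged["protein_id"].isna().any():
        missing = merged.loc[merged["protein_id"].isna(), "peptide_id"].tolist()[:5]
        raise PsiError(f"peptides without tile coordinates, e.g. {missing}")

    profiles: dict[str, ResidueProfile] = {}
    for pid, grp in merged.groupby("protein_id", sort=True):
        end = int((grp["aa_start"] + grp["peptide"].str.len()).max())
        length = int(protein_lengths[pid]) if protein_lengths else end
        acc = np.zeros(length)
        cov = np.zeros(length, dtype=int)
        for r in grp.itertuples(index=False):
            start = int(r.aa_start)
            if track == "central":
                pos = start + CENTRAL_OFFSET
                acc[pos] += r.psi
                cov[pos] += 1
            else:
                span = slice(start, start + len(r.peptide))
                acc[span] += r.psi
                cov[span] += 1
        raw = np.full(length, np.nan)
        defined = cov > 0
        raw[defined] = acc[defined] / cov[defined]
        profiles[pid] = ResidueProfile(
            protein_id=pid,
            raw=raw,
            smoothed=running_median(raw, window=window),
            coverage=cov,
        )
    return profiles


def write_profiles_tsv(profiles: Mapping[str, ResidueProfile], path: str | Path) -> None:
    pd.concat([p.to_frame() for p in profiles.values()]).to_csv(
        path, sep="\t", index=False
    )
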