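"""Read trimming, 1-mismatch library matching and per-bin quantification.

Reads from each of the four FACS gates are trimmed to the 51-nt insert,
matched against the library allowing at most one substitution (Hamming
distance; indels fall through as unmatched), and tallied into a
peptide-by-gate count table.  Per-gate totals are then normalised to
1e6 reads/bin so that peptide frequencies are comparable across gates.

The 1-mismatch lookup uses the pigeonhole principle: split the 51-mer into
two halves — any sequence within Hamming distance 1 matches at least one
half exactly — and verify candidates by direct comparison.  A quadratic
full-scan matcher is kept alongside as an independent oracle.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .library import Tile

__all__ = [
    "GATES",
    "NORM_TOTAL",
    "TrimSpec",
    "MatchResult",
    "MatchIndex",
    "BinCountTable",
    "trim_prefix",
    "hamming1",
    "match_bruteforce",
    "build_index",
    "count_bins",
    "normalize_bins",
]

log = logging.getLogger(__name__)

GATES = (1, 2, 3, 4)
NORM_TOTAL = 1_000_000  # reads/bin after normalisation


@dataclass(frozen=True)
class TrimSpec:
    """How to locate the 51-nt insert inside a read.

    ``mode='fixed'`` slices ``insert_length`` nt starting at
    ``fixed_length``; ``mode='anchor'`` finds the first exact occurrence of
    the vector anchor and takes the insert immediately after it.
    """

    mode: str = "anchor"
    anchor: str | None = None
    fixed_length: int | None = None
    insert_length: int = 51

    def __post_init__(self):
        if self.mode not in ("fixed", "anchor"):
            raise ValueError(f"unknown trim mode {self.mode!r}")
        if self.mode == "anchor" and not self.anchor:
            raise ValueError("anchor mode requires an anchor sequence")
        if self.mode == "fixed" and self.fixed_length is None:
            raise ValueError("fixed mode requires fixed_length")


def trim_prefix(read: str, spec: TrimSpec) -> str | None:
    """Return the candidate insert, or None if the read cannot be trimmed."""
    if spec.mode == "fixed":
        start = spec.fixed_length
    else:
        pos = read.find(spec.anchor)
        if pos < 0:
            return None
        start = pos + len(spec.anchor)
    insert = read[start : start + spec.insert_length]
    if len(insert) < spec.insert_length:
        return None
    return insert


@dataclass(frozen=True)
class MatchResult:
    status: str                    # unique | ambiguous | unmatched
    entry: int | None = None       # collapsed-entry index when unique
    mismatches: int | None = None


def hamming1(a: str, b: str) -> int:
    """Hamming distance capped at 2 (early exit; 2 means '>1')."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > 1:
                return 2
    return d


def match_bruteforce(query: str, library: Sequence[str]) -> MatchResult:
    """Full-scan reference matcher: best (min-distance ≤ 1) entries."""
    best_d = 2
    hits: list[int] = []
    for i, seq in enumerate(library):
        d = hamming1(query, seq)
        if d < best_d:
            best_d, hits = d, [i]
        elif d == best_d and d < 2:
            hits.append(i)
    if best_d > 1 or not hits:
        return MatchResult("unmatched")
    if len(hits) > 1:
        return MatchResult("ambiguous", mismatches=best_d)
    return MatchResult("unique", entry=hits[0], mismatches=best_d)


class MatchIndex:
    """Exact + 1-mismatch lookup over a 51-mer library.

    Identical DNA sequences from different tiles collapse to a single
    entry holding every member peptide_id; matching reports the entry.
    """

    def __init__(self, tiles: Sequence[Tile]):
        if not tiles:
            raise ValueError("empty library")
        length = len(tiles[0].dna)
        seq_to_entry: dict[str, int] = {}
        self.sequences: list[str] = []
        self.entry_peptide_ids: list[list[str]] = []
        for t in tiles:
            if len(t.dna) != length:
                raise ValueError("library sequences must share one length")
            if set(t.dna) - set("ACGT"):
                raise ValueError(f"non-ACGT characters in library member {t.peptide_id}")
            e = seq_to_entry.get(t.dna)
            if e is None:
                e = seq_to_entry[t.dna] = len(self.sequences)
                self.sequences.append(t.dna)
                self.entry_peptide_ids.append([])
            self.entry_peptide_ids[e].append(t.peptide_id)
        self.length = length
        self.half = length // 2
        self._exact = seq_to_entry
        self._left: dict[str, list[int]] = defaultdict(list)
        self._right: dict[str, list[int]] = defaultdict(list)
        for e, seq in enumerate(self.sequences):
            self._left[seq[: self.half]].append(e)
            self._right[seq[self.half :]].append(e)

    def match(self, query: str) -> MatchResult:
        if len(query) != self.length:
            return MatchResult("unmatched")
        exact = self._exact.get(query)
        if exact is not None:
            return MatchResult("unique", entry=exact, mismatches=0)
        cands = set(self._left.get(query[: self.half], ()))
        cands.update(self._right.get(query[self.half :], ()))
        hits = [e for e in cands if hamming1(query, self.sequences[e]) <= 1]
        if not hits:
            return MatchResult("unmatched")
        if len(hits) > 1:
            return MatchResult("ambiguous", mismatches=1)
        return MatchResult("unique", entry=hits[0], mismatches=1)


def build_index(tiles: Sequence[Tile]) -> MatchIndex:
    return MatchIndex(tiles)


@dataclass
class BinCountTable:
    """Peptide-by-gate raw (and optionally normalised) read counts.

    ``raw`` is indexed by peptide_id with columns gate1..gate4; ``shared``
    flags rows whose DNA is identical to another tile's, in which case the
    collapsed count is duplicated into every member row.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame | None = None
    shared: pd.Series | None = None

    RAW_COLS = [f"gate{g}" for g in GATES]
    NORM_COLS = [f"gate{g}_norm" for g in GATES]

    def __post_init__(self):
        if list(self.raw.columns) != self.RAW_COLS:
            raise ValueError(f"raw columns must be {self.RAW_COLS}")
        if (self.raw.to_numpy() < 0).any():
            raise ValueError("negative raw counts")

    @property
    def gate_totals(self) -> pd.Series:
        return self.raw.sum(axis=0)

    @property
    def peptide_totals(self) -> pd.Series:
        return self.raw.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = self.raw.copy()
        if self.normalized is not None:
            for g, col in zip(GATES, self.NORM_COLS):
                df[col] = self.normalized[f"gate{g}"]
        if self.shared is not None:
            df["shared"] = self.shared
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="peptide_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BinCountTable":
        df = pd.read_csv(path, sep="\t", index_col="peptide_id")
        raw = df[cls.RAW_COLS]
        norm = None
        if set(cls.NORM_COLS) <= set(df.columns):
            norm = df[cls.NORM_COLS].rename(
                columns=dict(zip(cls.NORM_COLS, cls.RAW_COLS))
            )
        shared = df["shared"] if "shared" in df.columns else None
        return cls(raw=raw, normalized=norm, shared=shared)


def _empty_raw(index: MatchIndex) -> tuple[pd.DataFrame, pd.Series]:
    ids, shared = [], []
    for members in index.entry_peptide_ids:
        for pid in members:
            ids.append(pid)
            shared.append(len(members) > 1)
    raw = pd.DataFrame(
        0, index=pd.Index(ids, name="peptide_id"), columns=BinCountTable.RAW_COLS
    )
    return raw, pd.Series(shared, index=raw.index, name="shared")


def count_bins(
    reads_by_gate: Mapping[int, Iterable[str]],
    index: MatchIndex,
    trim_spec: TrimSpec,
    ambiguous: str = "drop",
) -> tuple[BinCountTable, dict]:
    """Trim and match each gate's reads; tally unique hits per peptide.

    Ambiguous reads (two or more library members at the best distance) are
    dropped by default.  Statistics per gate report total, unique,
    ambiguous and unmatched read numbers.
    """
    if ambiguous not in ("drop",):
        raise ValueError("only the 'drop' ambiguous policy is implemented")
    missing = [g for g in GATES if g not in reads_by_gate]
    if missing:
        raise ValueError(f"gates missing from input: {missing}")

    raw, shared = _empty_raw(index)
    entry_counts = np.zeros((len(index.sequences), len(GATES)), dtype=np.int64)
    stats: dict[str, dict] = {}
    for gi, g in enumerate(GATES):
        n = unique = ambig = unmatched = 0
        col = entry_counts[:, gi]
        for read in reads_by_gate[g]:
            n += 1
            insert = trim_prefix(read, trim_spec)
            if insert is None:
                unmatched += 1
                continue
            res = index.match(insert)
            if res.status == "unique":
                col[res.entry] += 1
                unique += 1
            elif res.status == "ambiguous":
                ambig += 1
            else:
                unmatched += 1
        if n == 0:
            log.warning("gate %d is empty", g)
        stats[f"gate{g}"] = {
            "total": n, "unique": unique, "ambiguous": ambig, "unmatched": unmatched,
        }

    # expand collapsed entries to member rows (duplicated counts, flagged shared)
    values = raw.to_numpy()
    row = 0
    for e, members in enumerate(index.entry_peptide_ids):
        for _ in members:
            values[row] = entry_counts[e]
            row += 1
    table = BinCountTable(raw=pd.DataFrame(values, index=raw.index, columns=raw.columns),
                          shared=shared)
    return table, stats


def normalize_bins(table: BinCountTable, total: int = NORM_TOTAL) -> BinCountTable:
    """Scale each gate so its total equals ``total`` reads (reads-per-million style).

    Gates with zero raw total stay all-zero and are flagged in the log;
    all four gates empty is an error.
    """
    totals = table.gate_totals
    if (totals == 0).all():
        raise ValueError("all four gates are empty; nothing to normalise")
    norm = table.raw.astype(float).copy()
    for col in table.RAW_COLS:
        t = totals[col]
        if t > 0:
            norm[col] = norm[col] * (total / t)
        else:
            log.warning("gate %s has zero total; left unnormalised (all zero)", col)
    return BinCountTable(raw=table.raw, normalized=norm, shared=table.shared)


def write_match_stats(stats: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(stats, fh, indent=2)
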