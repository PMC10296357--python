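"""Structural characterisation of predicted degrons.

Three analyses relate degron probability to physical properties:

* hydrophobicity — the mean Kyte–Doolittle hydropathy of each peptide
  against its predicted degron probability (Spearman correlation);
* secondary structure — per-residue helix/sheet/turn/bend/other classes
  from backbone torsion angles and chain curvature, compared between
  degron residues and the whole protein set;
* solvent accessibility — per-residue accessible surface area from a
  Shrake–Rupley calculation (golden-spiral test points on expanded atomic
  spheres), with a Mann–Whitney U comparison of degron residues against
  all residues.

Structures are read from mmCIF/PDB files (e.g. predicted models); an
external per-residue annotation TSV can substitute for the built-in
torsion classifier and ASA when users prefer DSSP-style output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu, spearmanr

from .model import DegronClassifier

__all__ = [
    "KYTE_DOOLITTLE",
    "MAX_ASA",
    "VDW_RADII",
    "AtomSet",
    "StructureAnnotation",
    "kd_score",
    "hydropathy_vs_probability",
    "dihedral",
    "ideal_backbone",
    "assign_secondary_structure",
    "asa_shrake_rupley",
    "relative_asa",
    "degron_structure_report",
]

log = logging.getLogger(__name__)

# Kyte & Doolittle hydropathy scale (Ile +4.5 ... Arg -4.5).
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# Theoretical per-residue maximum ASA (A^2), Tien et al. 2013, for
# relative-exposure normalisation; overridable per call.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Van der Waals radii (A) for heavy atoms; elements outside the table
# fall back to carbon.
VDW_RADII: dict[str, float] = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2}

SS_CLASSES = ("helix", "sheet", "turn", "bend", "other")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(ValueError):
    pass


def kd_score(peptide: str) -> float:
    """Mean Kyte–Doolittle hydropathy over the peptide."""
    try:
        return float(np.mean([KYTE_DOOLITTLE[aa] for aa in peptide]))
    except KeyError as e:
        raise StructureError(f"non-standard residue {e.args[0]!r}") from None


def hydropathy_vs_probability(
    peptides: Sequence[str], model: DegronClassifier
) -> tuple[pd.DataFrame, float, float]:
    """Per-peptide (hydropathy, degron probability) pairs + Spearman rho.

    Returns (table, rho, p-value); rho is NaN (flagged in the log) when
    the probabilities are constant.
    """
    if len(peptides) < 3:
        raise StructureError("need at least 3 peptides for a correlation")
    kd = np.array([kd_score(p) for p in peptides])
    prob = model.predict_proba(list(peptides))[:, 1]
    table = pd.DataFrame({"peptide": list(peptides), "kd_score": kd, "probability": prob})
    if np.ptp(prob) == 0 or np.ptp(kd) == 0:
        log.warning("degenerate input: constant probabilities or hydropathy")
        return table, float("nan"), float("nan")
    rho, p = spearmanr(kd, prob)
    return table, float(rho), float(p)


# ---------------------------------------------------------------------------
# geometry

@dataclass
class AtomSet:
    """Heavy atoms of one chain: coordinates, radii, residue bookkeeping."""

    elements: list[str]
    coords: np.ndarray            # (n_atoms, 3)
    radii: np.ndarray             # (n_atoms,)
    residue_index: np.ndarray     # (n_atoms,) 0-based residue ordinal
    atom_names: list[str]
    residue_names: list[str]      # per residue (3-letter)
    chain: str = "A"

    def __post_init__(self):
        if not np.isfinite(self.coords).all():
            raise StructureError("non-finite coordinates")
        if (self.radii <= 0).any():
            raise StructureError("non-positive van der Waals radius")

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max()) + 1 if len(self.residue_index) else 0

    def residue_letters(self) -> str:
        return "".join(THREE_TO_ONE.get(r, "X") for r in self.residue_names)

    def backbone(self) -> np.ndarray:
        """(n_residues, 3, 3) N/CA/C coordinates; NaN where atoms are absent."""
        bb = np.full((self.n_residues, 3, 3), np.nan)
        slot = {"N": 0, "CA": 1, "C": 2}
        for name, ri, xyz in zip(self.atom_names, self.residue_index, self.coords):
            s = slot.get(name)
            if s is not None:
                bb[ri, s] = xyz
        return bb

    @classmethod
    def from_structure_file(cls, path: str | Path, chain: str | None = None,
                            radii: Mapping[str, float] | None = None) -> "AtomSet":
        """Read the first (or named) polymer chain from a PDB/mmCIF file."""
        import gemmi

        st = gemmi.read_structure(str(path))
        st.setup_entities()
        model = st[0]
        chains = [c for c in model if chain is None or c.name == chain]
        if not chains:
            raise StructureError(f"chain {chain!r} not found in {path}")
        ch = chains[0]
        rtab = dict(VDW_RADII)
        if radii:
            rtab.update(radii)
        elements, xyz, ridx, names, resnames = [], [], [], [], []
        res_ord = -1
        for res in ch:
            if res.name not in THREE_TO_ONE:
                continue
            res_ord += 1
            resnames.append(res.name)
            for atom in res:
                el = atom.element.name.upper()
                if el == "H":
                    continue
                elements.append(el)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                ridx.append(res_ord)
                names.append(atom.name)
        if not xyz:
            raise StructureError(f"no protein atoms in {path}")
        rad = np.array([rtab.get(e, VDW_RADII["C"]) for e in elements])
        return cls(
            elements=elements, coords=np.array(xyz), radii=rad,
            residue_index=np.array(ridx), atom_names=names,
            residue_names=resnames, chain=ch.name,
        )


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees (IUPAC: cis = 0)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return float(np.degrees(np.arctan2(np.cross(b1, v) @ w, v @ w)))


# idealised backbone geometry (A / degrees)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of the next atom."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * np.cos(ang),
         bond * np.sin(ang) * np.cos(tor),
         bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def ideal_backbone(phi_psi: Sequence[tuple[float, float]], omega: float = 180.0) -> np.ndarray:
    """Build N/CA/C coordinates for a chain with the given (phi, psi) per residue.

    Returns an (n_residues, 3, 3) array.  phi of the first residue and psi
    of the last are irrelevant to the geometry but accepted for symmetry.
    """
    n_res = len(phi_psi)
    bb = np.zeros((n_res, 3, 3))
    bb[0, 0] = [0.0, 0.0, 0.0]
    bb[0, 1] = [_BOND["N-CA"], 0.0, 0.0]
    ang = np.radians(_ANGLE["N-CA-C"])
    bb[0, 2] = bb[0, 1] + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        phi_i = phi_psi[i][0]
        psi_prev = phi_psi[i - 1][1]
        bb[i, 0] = _place_atom(bb[i - 1, 0], bb[i - 1, 1], bb[i - 1, 2],
                               _BOND["C-N"], _ANGLE["CA-C-N"], psi_prev)
        bb[i, 1] = _place_atom(bb[i - 1, 1], bb[i - 1, 2], bb[i, 0],
                               _BOND["N-CA"], _ANGLE["C-N-CA"], omega)
        bb[i, 2] = _place_atom(bb[i - 1, 2], bb[i, 0], bb[i, 1],
                               _BOND["CA-C"], _ANGLE["N-CA-C"], phi_i)
    return bb


@dataclass
class StructureAnnotation:
    """Per-residue secondary-structure class and solvent accessibility."""

    protein_id: str
    classes: list[str]
    asa: np.ndarray
    relative_asa: np.ndarray | None = None
    source: str = "computed"

    def __post_init__(self):
        bad = set(self.classes) - set(SS_CLASSES)
        if bad:
            raise StructureError(f"unknown secondary-structure classes {bad}")
        if (np.asarray(self.asa) < 0).any():
            raise StructureError("negative ASA")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "protein_id": self.protein_id,
                "position": np.arange(1, len(self.classes) + 1),
                "ss_class": self.classes,
                "asa": self.asa,
            }
        )
        if self.relative_asa is not None:
            df["relative_asa"] = self.relative_asa
        return df


def _runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Keep only True runs of at least min_len."""
    out = np.zeros_like(mask)
    start = None
    for i, flag in enumerate(np.append(mask, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                out[start:i] = True
            start = None
    return out


def assign_secondary_structure(
    backbone: np.ndarray, turn_span_max: float = 6.5, curvature_deg: float = 70.0
) -> list[str]:
    """Classify residues as helix/sheet/turn/bend/other from backbone geometry.

    Torsion windows: helix needs phi in (-100, -30) and psi in (-80, -5) in
    runs of >= 4 residues; sheet needs phi in (-180, -40) and psi in
    (90, 180] or [-180, -170) in runs of >= 3.  Remaining residues where the
    chain direction (CA(i-2)->CA(i) vs CA(i)->CA(i+2)) bends by at least
    ``curvature_deg`` are turns when CA(i-2)..CA(i+2) come within
    ``turn_span_max`` A, bends otherwise.  Chain ends without torsions are
    'other'.
    """
    bb = np.asarray(backbone, dtype=float)
    n = len(bb)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    for i in range(n):
        try:
            if i > 0 and not np.isnan(bb[i - 1, 2]).any() and not np.isnan(bb[i]).any():
                phi[i] = dihedral(bb[i - 1, 2], bb[i, 0], bb[i, 1], bb[i, 2])
            if i < n - 1 and not np.isnan(bb[i]).any() and not np.isnan(bb[i + 1, 0]).any():
                psi[i] = dihedral(bb[i, 0], bb[i, 1], bb[i, 2], bb[i + 1, 0])
        except (ZeroDivisionError, FloatingPointError):
            continue
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        helix_ok = (phi > -100) & (phi < -30) & (psi > -80) & (psi < -5)
        sheet_ok = (phi > -180) & (phi < -40) & (((psi > 90) & (psi <= 180)) | (psi < -170))
    helix = _runs(np.nan_to_num(helix_ok), 4)
    sheet = _runs(np.nan_to_num(sheet_ok) & ~helix, 3)

    classes = ["other"] * n
    ca = bb[:, 1]
    for i in range(n):
        if helix[i]:
            classes[i] = "helix"
        elif sheet[i]:
            classes[i] = "sheet"
        elif 2 <= i < n - 2 and not np.isnan(ca[i - 2 : i + 3]).any():
            v1 = ca[i] - ca[i - 2]
            v2 = ca[i + 2] - ca[i]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang >= curvature_deg:
                span = np.linalg.norm(ca[i + 2] - ca[i - 2])
                classes[i] = "turn" if span <= turn_span_max else "bend"
    return classes


# ---------------------------------------------------------------------------
# accessible surface area

def _golden_spiral(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (fixed orientation for determinism)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def asa_shrake_rupley(
    atoms: AtomSet, probe_radius: float = 1.4, n_sphere_points: int = 960
) -> np.ndarray:
    """Per-residue accessible surface area (A^2).

    Each atom's expanded sphere (r + probe) carries ``n_sphere_points``
    golden-spiral test points; the accessible fraction (points inside no
    neighbour's expanded sphere) times the sphere area is the atom's ASA,
    and residue ASA sums its atoms.
    """
    pts = _golden_spiral(n_sphere_points)
    coords = atoms.coords
    radii = atoms.radii + probe_radius
    tree = cKDTree(coords)
    if len(coords) != len(np.unique(coords, axis=0)):
        log.warning("identical atom coordinates present; computing as-is")
    max_r = radii.max()
    asa_atom = np.zeros(len(coords))
    for i in range(len(coords)):
        r = radii[i]
        neigh = tree.query_ball_point(coords[i], r + max_r)
        neigh = [j for j in neigh if j != i]
        test = coords[i] + r * pts
        free = np.ones(n_sphere_points, dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", test - coords[j], test - coords[j])
            free &= d2 > radii[j] ** 2
            if not free.any():
                break
        asa_atom[i] = free.mean() * 4.0 * np.pi * r * r
    res_asa = np.zeros(atoms.n_residues)
    np.add.at(res_asa, atoms.residue_index, asa_atom)
    return res_asa


def relative_asa(
    annotation: StructureAnnotation,
    residues: str,
    max_asa: Mapping[str, float] | None = None,
) -> np.ndarray:
    """ASA / per-residue maximum reference, clipped to [0, 1]."""
    table = dict(MAX_ASA)
    if max_asa:
        table.update(max_asa)
    if len(residues) != len(annotation.asa):
        raise StructureError("residue string and ASA track length mismatch")
    try:
        ref = np.array([table[aa] for aa in residues])
    except KeyError as e:
        raise StructureError(f"unknown residue {e.args[0]!r}") from None
    rel = np.clip(annotation.asa / ref, 0.0, 1.0)
    annotation.relative_asa = rel
    return rel


# ---------------------------------------------------------------------------
# degron vs proteome report

def degron_structure_report(
    probabilities: Mapping[str, np.ndarray],
    annotations: Mapping[str, StructureAnnotation],
    cutoff: float = 0.85,
) -> dict:
    """Secondary-structure proportions and ASA comparison: degrons vs all.

    ``probabilities`` maps protein_id to a per-residue degron-probability
    track (NaN where undefined); residues with probability > cutoff form
    the degron population.  Returns class proportions for both
    populations, the Mann–Whitney U statistic and two-sided p-value on ASA
    (exact when both samples are <= 20, normal approximation with tie
    correction otherwise).
    """
    deg_classes: list[str] = []
    all_classes: list[str] = []
    deg_asa: list[float] = []
    all_asa: list[float] = []
    for pid, track in probabilities.items():
        ann = annotations.get(pid)
        if ann is None:
            raise StructureError(f"no structure annotation for protein {pid}")
        if len(ann.classes) != len(track):
            raise StructureError(
                f"annotation/scan length mismatch for protein {pid} "
                f"({len(ann.classes)} vs {len(track)})"
            )
        track = np.asarray(track, dtype=float)
        is_deg = np.where(np.isnan(track), False, track > cutoff)
        all_classes.extend(ann.classes)
        all_asa.extend(ann.asa)
        deg_classes.extend(c for c, d in zip(ann.classes, is_deg) if d)
        deg_asa.extend(a for a, d in zip(ann.asa, is_deg) if d)

    def proportions(classes: Sequence[str]) -> dict[str, float]:
        n = len(classes)
        return {c: (classes.count(c) / n if n else 0.0) for c in SS_CLASSES}

    report = {
        "n_degron_residues": len(deg_classes),
        "n_total_residues": len(all_classes),
        "cutoff": cutoff,
        "proportions_degron": proportions(deg_classes),
        "proportions_all": proportions(all_classes),
    }
    if deg_asa and all_asa:
        method = "exact" if (len(deg_asa) <= 20 and len(all_asa) <= 20) else "asymptotic"
        res = mannwhitneyu(deg_asa, all_asa, alternative="two-sided", method=method)
        report["mannwhitney_u"] = float(res.statistic)
        report["mannwhitney_p"] = float(res.pvalue)
    else:
        report["mannwhitney_u"] = float("nan")
        report["mannwhitney_p"] = float("nan")
    return report


def read_annotation_tsv(path: str | Path) -> dict[str, StructureAnnotation]:
    """External per-residue annotation: protein_id, position, ss_class, asa."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for pid, grp in df.groupby("protein_id"):
        grp = grp.sort_values("position")
        out[pid] = StructureAnnotation(
            protein_id=str(pid),
            classes=list(grp["ss_class"]),
            asa=grp["asa"].to_numpy(dtype=float),
            source="external_annotation",
        )
    return out
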