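"""Hydropathy, secondary structure, solvent accessibility and the degron report."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from ygpsp.structure import (
    AtomSet,
    KYTE_DOOLITTLE,
    StructureAnnotation,
    StructureError,
    asa_shrake_rupley,
    assign_secondary_structure,
    degron_structure_report,
    dihedral,
    hydropathy_vs_probability,
    ideal_backbone,
    kd_score,
    read_annotation_tsv,
    relative_asa,
)


class TestKdScore:
    @pytest.mark.parametrize("aa, value", [("I", 4.5), ("R", -4.5), ("G", -0.4)])
    def test_homopolymer_equals_scale_value(self, aa, value):
        for n in (1, 17, 40):
            assert kd_score(aa * n) == pytest.approx(value)

    def test_mixed_peptide_mean(self):
        assert kd_score("IR") == pytest.approx(0.0)

    def test_nonstandard_rejected(self):
        with pytest.raises(StructureError):
            kd_score("IXR")

    def test_scale_is_complete_and_bounded(self):
        assert len(KYTE_DOOLITTLE) == 20
        assert all(-4.5 <= v <= 4.5 for v in KYTE_DOOLITTLE.values())


class TestHydropathyVsProbability:
    def test_trained_on_hydrophobic_weights_gives_positive_rho(
        self, medium_screen, trained_model
    ):
        """End-to-end: true weights favour hydrophobics, so hydropathy and
        predicted degron probability correlate positively."""
        peptides = [t.peptide for t in medium_screen["tiles"]]
        table, rho, p = hydropathy_vs_probability(peptides, trained_model)
        assert len(table) == len(peptides)
        assert rho > 0.5
        assert p < 1e-6

    def test_degenerate_constant_model_flagged(self, trained_model):
        zero = type(trained_model)()
        zero.classes_ = np.array([0, 1])
        zero.coef_ = np.zeros((1, 20))
        zero.intercept_ = np.zeros(1)
        zero.weights_ = {aa: 0.0 for aa in trained_model.weights_}
        _, rho, p = hydropathy_vs_probability(["A" * 17, "L" * 17, "E" * 17], zero)
        assert np.isnan(rho)

    def test_too_few_peptides_rejected(self, trained_model):
        with pytest.raises(StructureError):
            hydropathy_vs_probability(["A" * 17], trained_model)


def backbone_atoms(bb, resname="ALA"):
    """Wrap an (n,3,3) N/CA/C backbone as an AtomSet."""
    n = len(bb)
    coords = bb.reshape(-1, 3)
    return AtomSet(
        elements=["N", "C", "C"] * n,
        coords=coords,
        radii=np.array([1.55, 1.7, 1.7] * n),
        residue_index=np.repeat(np.arange(n), 3),
        atom_names=["N", "CA", "C"] * n,
        residue_names=[resname] * n,
    )


class TestSecondaryStructure:
    def test_dihedral_of_planar_points(self):
        p = [np.array(x, float) for x in
             [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]]
        assert dihedral(*p) == pytest.approx(0.0)
        p[3] = np.array((1, -1, 0), float)
        assert abs(dihedral(*p)) == pytest.approx(180.0)

    def test_ideal_backbone_reproduces_requested_torsions(self):
        bb = ideal_backbone([(-57.0, -47.0)] * 10)
        for i in range(1, 9):
            assert dihedral(bb[i - 1, 2], bb[i, 0], bb[i, 1], bb[i, 2]) == pytest.approx(-57.0, abs=1e-6)
            assert dihedral(bb[i, 0], bb[i, 1], bb[i, 2], bb[i + 1, 0]) == pytest.approx(-47.0, abs=1e-6)

    def test_ideal_helix_interior_is_helix(self):
        bb = ideal_backbone([(-57.0, -47.0)] * 20)
        classes = assign_secondary_structure(bb)
        assert set(classes[2:18]) == {"helix"}

    def test_ideal_strand_interior_is_sheet(self):
        bb = ideal_backbone([(-120.0, 130.0)] * 12)
        classes = assign_secondary_structure(bb)
        assert set(classes[2:10]) == {"sheet"}

    def test_two_residues_all_other(self):
        bb = ideal_backbone([(-57.0, -47.0)] * 2)
        assert assign_secondary_structure(bb) == ["other", "other"]

    def test_rigid_motion_invariance(self, rng):
        bb = ideal_backbone([(-57.0, -47.0)] * 10 + [(-120.0, 130.0)] * 8)
        classes = assign_secondary_structure(bb)
        # random rotation + translation
        q = rng.normal(size=(3, 3))
        u, _, vt = np.linalg.svd(q)
        rot = u @ vt
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        moved = bb @ rot.T + np.array([5.0, -3.0, 12.0])
        assert assign_secondary_structure(moved) == classes


class TestShrakeRupley:
    def single_atom(self, r=1.7):
        return AtomSet(
            elements=["C"], coords=np.zeros((1, 3)), radii=np.array([r]),
            residue_index=np.array([0]), atom_names=["CA"], residue_names=["ALA"],
        )

    def test_single_atom_within_one_percent_of_sphere(self):
        asa = asa_shrake_rupley(self.single_atom(), n_sphere_points=960)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert abs(asa[0] - exact) / exact < 0.01

    def test_error_nonincreasing_with_point_count(self):
        """Isolated-atom error never grows with lattice density, and the
        occluded two-sphere case converges on the closed form."""
        for n in (96, 240, 960):
            asa = asa_shrake_rupley(self.single_atom(), n_sphere_points=n)[0]
            assert asa == pytest.approx(4 * np.pi * 3.1**2, abs=1e-9)
        # mean over several overlaps averages out lattice luck
        R = 1.7 + 1.4
        errs = []
        for n in (96, 240, 960):
            rel = []
            for d in (1.6, 2.0, 2.4, 2.8):
                atoms = AtomSet(
                    elements=["C", "C"], coords=np.array([[0.0, 0, 0], [d, 0, 0]]),
                    radii=np.array([1.7, 1.7]), residue_index=np.array([0, 1]),
                    atom_names=["CA", "CA"], residue_names=["ALA", "ALA"],
                )
                exact = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * (R - d / 2))
                rel.append(abs(asa_shrake_rupley(atoms, n_sphere_points=n).sum()
                               - exact) / exact)
            errs.append(np.mean(rel))
        assert errs[2] <= errs[0]
        assert errs[2] < 0.005

    def test_far_atoms_additive(self):
        atoms = AtomSet(
            elements=["C", "C"], coords=np.array([[0.0, 0, 0], [50.0, 0, 0]]),
            radii=np.array([1.7, 1.7]), residue_index=np.array([0, 1]),
            atom_names=["CA", "CA"], residue_names=["ALA", "ALA"],
        )
        asa = asa_shrake_rupley(atoms)
        single = asa_shrake_rupley(self.single_atom())[0]
        assert asa == pytest.approx([single, single])

    def test_buried_atom_has_zero_asa(self, rng):
        """An atom enclosed by a dense shell of neighbours is inaccessible."""
        shell_dirs = rng.normal(size=(200, 3))
        shell_dirs /= np.linalg.norm(shell_dirs, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0, 0], shell_dirs * 2.2])
        n = len(coords)
        atoms = AtomSet(
            elements=["C"] * n, coords=coords, radii=np.full(n, 1.7),
            residue_index=np.arange(n), atom_names=["CA"] * n,
            residue_names=["ALA"] * n,
        )
        asa = asa_shrake_rupley(atoms)
        assert asa[0] == pytest.approx(0.0, abs=1e-9)

    def test_residue_sums_atoms(self):
        atoms = AtomSet(
            elements=["C", "C"], coords=np.array([[0.0, 0, 0], [50.0, 0, 0]]),
            radii=np.array([1.7, 1.7]), residue_index=np.array([0, 0]),
            atom_names=["CA", "CB"], residue_names=["ALA"],
        )
        asa = asa_shrake_rupley(atoms)
        assert len(asa) == 1
        assert asa[0] == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=0.01)


class TestRelativeAsa:
    def test_exposed_glycine_near_one(self):
        # an isolated extended tripeptide: central Gly almost fully exposed
        bb = ideal_backbone([(-120.0, 130.0)] * 3)
        atoms = backbone_atoms(bb, resname="GLY")
        ann = StructureAnnotation(
            protein_id="p", classes=["other"] * 3, asa=asa_shrake_rupley(atoms)
        )
        rel = relative_asa(ann, "GGG")
        # terminal backbone is fully exposed (clips at 1); the central
        # residue loses some area to its neighbours but stays mostly exposed
        assert rel[0] == 1.0
        assert rel[1] > 0.5

    def test_clipping_to_unit_interval(self):
        ann = StructureAnnotation(
            protein_id="p", classes=["other"], asa=np.array([500.0])
        )
        assert relative_asa(ann, "G")[0] == 1.0

    def test_unknown_residue_rejected(self):
        ann = StructureAnnotation(protein_id="p", classes=["other"], asa=np.array([10.0]))
        with pytest.raises(StructureError):
            relative_asa(ann, "X")


def brute_force_u(x, y):
    """Pairwise-comparison count: U of sample x vs y with tie halving."""
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else 0.5 if a == b else 0.0
    return u


class TestDegronReport:
    def annotation(self, classes, asa):
        return StructureAnnotation(protein_id="p", classes=classes,
                                   asa=np.asarray(asa, float))

    def test_self_vs_self_degenerate(self):
        n = 30
        ann = self.annotation(["helix"] * n, np.linspace(10, 100, n))
        probs = {"p": np.full(n, 0.99)}  # every residue is a degron
        rep = degron_structure_report(probs, {"p": ann}, cutoff=0.85)
        assert rep["proportions_degron"] == rep["proportions_all"]
        assert rep["mannwhitney_p"] > 0.9

    def test_degrons_in_generated_helices_only(self):
        classes = (["other"] * 10 + ["helix"] * 10 + ["other"] * 10)
        probs = np.zeros(30)
        probs[10:20] = 0.95
        ann = self.annotation(classes, np.arange(30, dtype=float))
        rep = degron_structure_report({"p": probs}, {"p": ann})
        assert rep["proportions_degron"]["helix"] == 1.0

    def test_proportions_sum_to_one(self, medium_screen, rng):
        classes = list(rng.choice(["helix", "sheet", "turn", "bend", "other"], size=50))
        probs = rng.random(50)
        ann = self.annotation(classes, rng.random(50) * 100)
        rep = degron_structure_report({"p": probs}, {"p": ann}, cutoff=0.5)
        assert sum(rep["proportions_all"].values()) == pytest.approx(1.0)
        assert sum(rep["proportions_degron"].values()) == pytest.approx(1.0)

    def test_u_statistic_matches_pair_counting(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 50))
            asa = np.round(rng.random(n) * 20)  # ties likely
            probs = rng.random(n)
            ann = self.annotation(["other"] * n, asa)
            rep = degron_structure_report({"p": probs}, {"p": ann}, cutoff=0.5)
            deg = asa[probs > 0.5]
            if len(deg) == 0:
                assert np.isnan(rep["mannwhitney_u"])
            else:
                assert rep["mannwhitney_u"] == pytest.approx(brute_force_u(deg, asa))

    def test_length_mismatch_names_protein(self):
        ann = self.annotation(["other"] * 5, np.ones(5))
        with pytest.raises(StructureError, match="prot1"):
            degron_structure_report({"prot1": np.zeros(6)}, {"prot1": ann})

    def test_external_annotation_round_trip(self, tmp_path):
        ann = self.annotation(["helix", "other"], [12.0, 30.0])
        ann.to_frame().to_csv(tmp_path / "ann.tsv", sep="\t", index=False)
        back = read_annotation_tsv(tmp_path / "ann.tsv")
        assert back["p"].classes == ann.classes
        assert np.allclose(back["p"].asa, ann.asa)
        assert back["p"].source == "external_annotation"


class TestStructureFileParsing:
    def test_pdb_round_trip_through_gemmi(self, tmp_path):
        """Write a small synthetic helix PDB, parse it, recover classes."""
        bb = ideal_backbone([(-57.0, -47.0)] * 12)
        lines = []
        serial = 0
        for i in range(12):
            for name, el, xyz in zip(("N", "CA", "C"), ("N", "C", "C"), bb[i]):
                serial += 1
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} ALA A{i + 1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"          {el:>2s}"
                )
        path = tmp_path / "synthetic_helix.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        atoms = AtomSet.from_structure_file(path)
        assert atoms.n_residues == 12
        assert atoms.residue_letters() == "A" * 12
        classes = assign_secondary_structure(atoms.backbone())
        assert set(classes[2:10]) == {"helix"}
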