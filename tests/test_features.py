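"""Feature detectors: disulfides, H-bonds, interfaces, SASA, sequons, cores."""

import math

import numpy as np
import pytest

from lamnode.features import (
    FeatureExtractor,
    detect_disulfides,
    detect_hbonds,
    detect_sequons,
    hydrophobic_core_membership,
    interface_residues,
    sasa,
    sequon_proximity,
    sphere_points,
)
from lamnode.model_io import Atom, Chain, Residue, StructureModel
from lamnode.synthetic import make_fragment
from oracles import monte_carlo_sasa


def single_residue_model(atoms, name="UNK", chain="A", number=1):
    return StructureModel(
        "fixture", [Chain(chain, [Residue(number, name, atoms=atoms)])], "synthetic"
    )


class TestDisulfides:
    def test_no_cysteines_empty(self, toy_model):
        frag = make_fragment("helix", 6)
        m = StructureModel("x", [frag], "synthetic")
        assert detect_disulfides(m) == []

    def test_pair_at_2_05_with_distant_third(self):
        """Two SG at 2.05 Å bond; a third SG 6 Å away stays unpaired."""
        def cys(number, sg_xyz):
            return Residue(number, "CYS", atoms=[
                Atom("CA", "C", [sg_xyz[0], sg_xyz[1] + 2.0, sg_xyz[2]]),
                Atom("SG", "S", sg_xyz),
            ])

        chain = Chain("A", [cys(1, [0, 0, 0]), cys(2, [2.05, 0, 0]), cys(3, [8.05, 0, 0])])
        bonds = detect_disulfides(StructureModel("x", [chain], "synthetic"))
        assert len(bonds) == 1
        assert {bonds[0].cys_a[1][0], bonds[0].cys_b[1][0]} == {1, 2}
        assert bonds[0].sg_distance == pytest.approx(2.05)

    def test_each_cysteine_in_at_most_one_bond(self):
        """Three clustered SG atoms: greedy nearest pairing yields one bond."""
        def cys(number, sg_xyz):
            return Residue(number, "CYS", atoms=[Atom("SG", "S", sg_xyz)])

        chain = Chain("A", [cys(1, [0, 0, 0]), cys(2, [2.0, 0, 0]), cys(3, [2.1, 2.0, 0])])
        bonds = detect_disulfides(StructureModel("x", [chain], "synthetic"), sg_cutoff=2.5)
        assert len(bonds) == 1
        assert {bonds[0].cys_a[1][0], bonds[0].cys_b[1][0]} == {1, 2}

    def test_symmetry_and_planted_truth(self, toy_model, toy_truth):
        bonds = detect_disulfides(toy_model)
        got = {tuple(sorted([(b.cys_a[0], b.cys_a[1][0]), (b.cys_b[0], b.cys_b[1][0])]))
               for b in bonds}
        want = {tuple(sorted([(c1, n1), (c2, n2)]))
                for (c1, n1), (c2, n2) in toy_truth["disulfides"]}
        assert got == want


class TestHBonds:
    def test_distant_residues_no_bond(self):
        a = Residue(1, "ALA", atoms=[Atom("N", "N", [0, 0, 0]), Atom("O", "O", [1, 0, 0])])
        b = Residue(2, "ALA", atoms=[Atom("N", "N", [20, 0, 0]), Atom("O", "O", [21, 0, 0])])
        m = StructureModel("x", [Chain("A", [a]), Chain("B", [b])], "synthetic")
        assert detect_hbonds(m) == []

    @pytest.mark.parametrize("distance, expected", [(3.4, True), (3.7, False)])
    def test_cutoff_straddle_with_planted_hydrogen(self, distance, expected):
        """Donor–acceptor at 3.4 Å with a 175° hydrogen detected; 3.7 Å not."""
        h_pos = [1.0, 0.0, 0.02]  # D-H···A ≈ 175°
        donor = Residue(1, "SER", atoms=[
            Atom("OG", "O", [0, 0, 0]),
            Atom("HG", "H", h_pos),
        ])
        acceptor = Residue(2, "ALA", atoms=[Atom("O", "O", [distance, 0, 0])])
        m = StructureModel("x", [Chain("A", [donor]), Chain("B", [acceptor])], "synthetic")
        bonds = detect_hbonds(m)
        assert bool(bonds) is expected
        if bonds:
            assert bonds[0].angle > 170

    def test_bad_hydrogen_angle_rejected(self):
        donor = Residue(1, "SER", atoms=[
            Atom("OG", "O", [0, 0, 0]),
            Atom("HG", "H", [-0.7, 0.7, 0]),  # points away: angle ≈ 45°
        ])
        acceptor = Residue(2, "ALA", atoms=[Atom("O", "O", [3.0, 0, 0])])
        m = StructureModel("x", [Chain("A", [donor]), Chain("B", [acceptor])], "synthetic")
        assert detect_hbonds(m) == []

    def test_base_angle_fallback_without_hydrogens(self):
        """No H: antecedent–donor–acceptor angle must be >= 90°."""
        def build(base_xyz):
            donor = Residue(1, "SER", atoms=[
                Atom("OG", "O", [0, 0, 0]), Atom("CB", "C", base_xyz),
            ])
            acceptor = Residue(2, "ALA", atoms=[Atom("O", "O", [3.0, 0, 0])])
            return StructureModel("x", [Chain("A", [donor]), Chain("B", [acceptor])],
                                  "synthetic")

        assert detect_hbonds(build([-1.4, 0, 0]))  # base opposite acceptor: 180°
        assert detect_hbonds(build([1.4, 0.3, 0])) == []  # base toward acceptor

    def test_symmetric_in_its_residues(self, toy_model):
        """Every detected bond names both partners consistently."""
        for b in detect_hbonds(toy_model):
            assert b.donor != b.acceptor
            assert b.distance <= 3.5
        inter = [b for b in detect_hbonds(toy_model) if b.is_inter_chain]
        keys = {frozenset([b.donor_residue, b.acceptor_residue]) for b in inter}
        assert len(keys) >= 1

    def test_planted_interchain_bond_found(self, toy_model, toy_truth):
        inter = {
            tuple(sorted([(b.donor[0], b.donor[1][0]), (b.acceptor[0], b.acceptor[1][0])]))
            for b in detect_hbonds(toy_model)
            if b.is_inter_chain
        }
        want = {tuple(sorted([(c1, n1), (c2, n2)]))
                for (c1, n1), (c2, n2) in toy_truth["inter_chain_hbonds"]}
        assert inter == want


class TestInterfaces:
    def test_far_chains_empty_sets(self):
        a = make_fragment("strand", 5, chain_id="A")
        b = make_fragment("strand", 5, chain_id="B")
        for r in b.residues:
            for atom in r.atoms:
                atom.position = atom.position + np.array([0, 12.0, 0])
        m = StructureModel("x", [a, b], "synthetic")
        sets = interface_residues(m, "A", "B", contact_cutoff=5.0)
        assert sets["A"] == set() and sets["B"] == set()

    def test_planted_window_recovered_exactly(self, toy_model, toy_truth):
        sets = interface_residues(toy_model, "A", "B", contact_cutoff=5.0)
        assert sorted(n for n, _ in sets["A"]) == toy_truth["interface"]["A"]
        assert sorted(n for n, _ in sets["B"]) == toy_truth["interface"]["B"]

    def test_reciprocity(self, toy_model):
        """r in A is interface iff some B residue lies within cutoff of r."""
        sets = interface_residues(toy_model, "A", "B", contact_cutoff=5.0)
        chain_a, chain_b = toy_model.chain("A"), toy_model.chain("B")
        pts_b = np.array([a.position for r in chain_b.residues for a in r.heavy_atoms()])
        for res in chain_a.residues:
            pts = np.array([a.position for a in res.heavy_atoms()])
            dmin = np.linalg.norm(pts[:, None] - pts_b[None], axis=2).min()
            assert (res.ref in sets["A"]) == (dmin <= 5.0)

    def test_missing_chain_raises(self, toy_model):
        with pytest.raises(KeyError):
            interface_residues(toy_model, "A", "Z")


class TestSasa:
    def test_isolated_carbon_closed_form(self):
        m = single_residue_model([Atom("C1", "C", [0, 0, 0])])
        result = sasa(m)
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert result.total == pytest.approx(exact, rel=1e-3)

    @pytest.mark.parametrize("d", [1.5, 2.5, 3.5, 4.5])
    def test_two_sphere_analytic_overlap(self, d):
        """Equal fused spheres: exposed area 2(4πR² − 2πRh), h = R − d/2."""
        m = single_residue_model([Atom("C1", "C", [0, 0, 0]), Atom("C2", "C", [d, 0, 0])])
        got = sasa(m).total
        R = 1.70 + 1.4
        h = R - d / 2
        exact = 2 * (4 * math.pi * R**2 - 2 * math.pi * R * h)
        assert got == pytest.approx(exact, rel=0.02)

    def test_monte_carlo_oracle_agreement(self):
        """Per-atom areas within 3% of a 1e5-point random-sampling oracle."""
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(12, 3)) * 2.2
        elements = ["C", "N", "O", "S"] * 3
        atoms = [Atom(f"X{i}", e, p) for i, (e, p) in enumerate(zip(elements, pos))]
        m = single_residue_model(atoms)
        got = sasa(m).atom_areas
        from lamnode.features import VDW_RADII

        radii = np.array([VDW_RADII[e] for e in elements])
        ref = monte_carlo_sasa(pos, radii, probe=1.4, n_samples=100_000, seed=1)
        scale = 4 * math.pi * (radii + 1.4) ** 2
        assert np.all(np.abs(got - ref) / scale < 0.03)

    def test_translation_invariance_exact(self, toy_model):
        """Translating the model leaves every atom area bitwise-stable."""
        moved = toy_model.copy()
        t = np.array([123.0, -45.0, 67.0])
        for chain in moved.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.position = atom.position + t
        a1 = sasa(toy_model).atom_areas
        a2 = sasa(moved).atom_areas
        assert np.abs(a1 - a2).max() < 1e-9

    def test_rotation_invariance_to_quadrature(self, toy_model):
        """Rotation changes only which sphere points are occluded; the total
        area is stable to the quadrature resolution of the point set."""
        from lamnode.synthetic import random_rotation

        rng = np.random.default_rng(0)
        R = random_rotation(rng)
        moved = toy_model.copy()
        for chain in moved.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.position = R @ atom.position
        r1, r2 = sasa(toy_model), sasa(moved)
        assert r2.total == pytest.approx(r1.total, rel=0.01)

    def test_sphere_points_unit_and_deterministic(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.array_equal(pts, sphere_points(960))


class TestCore:
    def test_extended_tripeptide_nothing_buried(self):
        frag = make_fragment("strand", 3, residue_names=["LEU", "LEU", "LEU"])
        m = StructureModel("x", [frag], "synthetic")
        assert hydrophobic_core_membership(m) == set()

    def test_planted_leucine_cluster_recovered(self, toy_model, toy_truth):
        core = hydrophobic_core_membership(toy_model)
        assert sorted((c, n) for c, (n, _) in core) == sorted(
            (c, n) for c, n in toy_truth["core"]
        )

    def test_exposed_cysteines_not_core(self, toy_model, toy_truth):
        core = hydrophobic_core_membership(toy_model)
        ss_cys = {(c, n) for pair in toy_truth["disulfides"] for c, n in pair}
        assert not {(c, n) for c, (n, _) in core} & ss_cys


class TestSequons:
    def _chain_of(self, seq):
        three = {"N": "ASN", "P": "PRO", "T": "THR", "S": "SER", "A": "ALA",
                 "G": "GLY", "L": "LEU"}
        return Chain("A", [
            Residue(i + 1, three[c], atoms=[Atom("CA", "C", [3.8 * i, 0, 0])])
            for i, c in enumerate(seq)
        ])

    def test_proline_exclusion(self):
        assert detect_sequons(self._chain_of("NPT")) == []

    def test_simple_match(self):
        sequons = detect_sequons(self._chain_of("ANLTG"))
        assert len(sequons) == 1
        assert sequons[0].asn_position == 2
        assert sequons[0].triplet == "NLT"

    def test_nxs_also_matches(self):
        assert len(detect_sequons(self._chain_of("NGS"))) == 1

    def test_numbering_gap_blocks_window(self):
        chain = self._chain_of("NLT")
        chain.residues[2].number = 7  # chain break between X and T
        assert detect_sequons(chain) == []

    def test_proximity_self_is_zero(self, toy_model, toy_truth):
        chain_id, asn = toy_truth["sequons"][0]
        assert sequon_proximity(toy_model, (chain_id, (asn, ""))) == 0.0

    def test_proximity_no_sequons_infinite(self):
        frag = make_fragment("strand", 5, chain_id="A")
        m = StructureModel("x", [frag], "synthetic")
        assert sequon_proximity(m, ("A", (1, ""))) == math.inf

    def test_planted_exact_distance(self):
        """A standalone Asn placed 7.00 Å from the probe reads back 7.00."""
        probe = Residue(1, "GLY", atoms=[Atom("CA", "C", [0, 0, 0])])
        triplet = [
            Residue(10, "ASN", atoms=[Atom("CA", "C", [7.0, 0, 0])]),
            Residue(11, "GLY", atoms=[Atom("CA", "C", [10.8, 0, 0])]),
            Residue(12, "THR", atoms=[Atom("CA", "C", [14.6, 0, 0])]),
        ]
        chain = Chain("A", [probe] + triplet)
        m = StructureModel("x", [chain], "synthetic")
        d = sequon_proximity(m, ("A", (1, "")))
        assert d == pytest.approx(7.00, abs=0.01)


class TestProfiles:
    def test_planted_interface_residue_profile(self, toy_model, toy_truth):
        ex = FeatureExtractor(toy_model)
        number = toy_truth["interface"]["A"][0]
        p = ex.profile(("A", (number, "")))
        assert p.is_interface
        assert "B" in p.interface_partners
        assert p.in_disulfide is None

    def test_disulfide_cysteine_profile(self, toy_model, toy_truth):
        ex = FeatureExtractor(toy_model)
        (c1, n1), (c2, n2) = toy_truth["disulfides"][0]
        p = ex.profile((c1, (n1, "")))
        assert p.in_disulfide is not None
        assert {p.in_disulfide.cys_a[1][0], p.in_disulfide.cys_b[1][0]} == {n1, n2}

    def test_isolated_surface_residue_all_negative(self, toy_model):
        """A plain strand glycine far from every plant: no features, exposed."""
        ex = FeatureExtractor(toy_model)
        p = ex.profile(("C", (5, "")))
        assert not p.is_interface
        assert not p.inter_chain_hbonds
        assert p.in_disulfide is None
        assert not p.is_hydrophobic_core
        assert p.sequon_distance == math.inf
        assert p.rsa is not None and p.rsa > 0.5

    def test_missing_residue_raises(self, toy_model):
        with pytest.raises(KeyError, match="999"):
            FeatureExtractor(toy_model).profile(("A", (999, "")))
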