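"""Coordinate parsing, mutation notation, manifest arithmetic, pLDDT."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lamnode.model_io import (
    MutationSpec,
    ParseError,
    build_manifest,
    format_mutation,
    load_catalog,
    map_residues,
    parse_mutation_notation,
    parse_structure,
    plddt_profile,
    write_mmcif,
    write_pdb,
)
from lamnode.synthetic import make_fragment
from lamnode.model_io import Chain, StructureModel

MINIMAL_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00 98.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00 98.00           C
END
"""


class TestParseStructure:
    def test_minimal_two_atom_pdb(self):
        m = parse_structure(MINIMAL_PDB)
        assert len(m.chains) == 1
        assert len(m.chains[0].residues) == 1
        assert m.n_atoms() == 2
        assert m.chains[0].residues[0].atom("CA") is not None

    def test_empty_coordinate_section_raises(self):
        with pytest.raises(ParseError, match="no atoms"):
            parse_structure("HEADER    EMPTY\nEND\n")

    def test_unreadable_file_raises(self):
        with pytest.raises(ParseError, match="no such"):
            parse_structure("/nonexistent/file.pdb")

    def test_waters_dropped_other_het_flagged(self, tmp_path):
        pdb = MINIMAL_PDB.replace("END\n", "") + (
            "HETATM    3  O   HOH A 101      9.000   9.000   9.000  1.00  0.00           O\n"
            "HETATM    4 ZN    ZN A 102      5.000   5.000   5.000  1.00  0.00          ZN\n"
            "END\n"
        )
        m = parse_structure(pdb)
        names = [r.name for c in m.chains for r in c.residues]
        assert "HOH" not in names
        assert "ZN" in names
        zn = next(r for c in m.chains for r in c.residues if r.name == "ZN")
        assert zn.is_hetero

    def test_round_trip_pdb_mmcif_identical(self, tmp_path, toy_model):
        """The same model written as PDB and mmCIF re-parses identically."""
        p_pdb, p_cif = tmp_path / "m.pdb", tmp_path / "m.cif"
        write_pdb(toy_model, p_pdb)
        write_mmcif(toy_model, p_cif)
        mp = parse_structure(p_pdb)
        mc = parse_structure(p_cif)
        assert mp.n_atoms() == mc.n_atoms() == toy_model.n_atoms()

        def coords(m):
            return np.array(
                [a.position for c in m.chains for r in c.residues for a in r.atoms]
            )

        def names(m):
            return [a.name for c in m.chains for r in c.residues for a in r.atoms]

        assert names(mp) == names(mc)
        assert np.abs(coords(mp) - coords(mc)).max() < 1e-3
        assert np.abs(coords(mp) - coords(toy_model)).max() < 1e-3

    def test_altloc_keeps_highest_occupancy(self):
        pdb = (
            "ATOM      1  N  AGLY A   1       0.000   0.000   0.000  0.40 10.00           N\n"
            "ATOM      2  N  BGLY A   1       5.000   0.000   0.000  0.60 10.00           N\n"
            "ATOM      3  CA  GLY A   1       1.458   0.000   0.000  1.00 10.00           C\n"
            "END\n"
        )
        m = parse_structure(pdb)
        n = m.chains[0].residues[0].atom("N")
        assert n.position[0] == pytest.approx(5.0)


class TestMutationNotation:
    @pytest.mark.parametrize(
        "text, composition, sub, pos, wt, mut",
        [
            ("α2(C83R)β1γ1", ("alpha2", "beta1", "gamma1"), "alpha2", 83, "C", "R"),
            ("a5b2(Y48S)g1", ("alpha5", "beta2", "gamma1"), "beta2", 48, "Y", "S"),
            ("α5(R286L)β2γ1", ("alpha5", "beta2", "gamma1"), "alpha5", 286, "R", "L"),
            ("a2b1(G269R)g1", ("alpha2", "beta1", "gamma1"), "beta1", 269, "G", "R"),
            ("b2(S179/F)a5g1", ("beta2", "alpha5", "gamma1"), "beta2", 179, "S", "F"),
        ],
    )
    def test_parse_constructs(self, text, composition, sub, pos, wt, mut):
        comp, spec = parse_mutation_notation(text)
        assert comp == composition
        assert (spec.subunit_label, spec.position, spec.wt_aa, spec.mut_aa) == (
            sub, pos, wt, mut,
        )

    def test_wild_type_node(self):
        comp, spec = parse_mutation_notation("α1β1γ1")
        assert comp == ("alpha1", "beta1", "gamma1")
        assert spec is None

    @pytest.mark.parametrize("bad", ["α2(C83R", "x2(C83R)b1g1", "α2β1", "α9β1γ1"])
    def test_malformed_tokens(self, bad):
        with pytest.raises(ParseError):
            parse_mutation_notation(bad)

    def test_two_mutations_unsupported(self):
        with pytest.raises(ParseError, match="unsupported"):
            parse_mutation_notation("α2(C83R)β1(G269R)γ1")

    @given(
        slot=st.integers(0, 2),
        alpha=st.sampled_from(["alpha1", "alpha2", "alpha5"]),
        beta=st.sampled_from(["beta1", "beta2", "beta3"]),
        pos=st.integers(1, 999),
        wt=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
        mut=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
        greek=st.booleans(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_format_parse_round_trip(self, slot, alpha, beta, pos, wt, mut, greek):
        """parse(format(spec)) is the identity over valid random specs."""
        if wt == mut:
            return
        composition = (alpha, beta, "gamma1")
        spec = MutationSpec(composition[slot], pos, wt, mut, composition)
        comp, back = parse_mutation_notation(format_mutation(spec, greek=greek))
        assert comp == composition
        assert back == spec


class TestManifest:
    def test_paper_catalog_counts(self, catalog_path):
        """23 mutations + 6 WT subunits + 3 WT trimers -> 29/26/55 models."""
        catalog = load_catalog(catalog_path)
        assert len(catalog) == 23
        manifest = build_manifest(
            catalog,
            wt_subunits=["alpha1", "alpha2", "alpha5", "beta1", "beta2", "gamma1"],
            wt_trimers=["a1b1g1", "a2b1g1", "a5b2g1"],
        )
        assert manifest.n_monomers == 29
        assert manifest.n_trimers == 26
        assert manifest.total == 55

    def test_empty_catalog(self):
        m = build_manifest([], ["alpha1"], [])
        assert (m.n_monomers, m.n_trimers, m.total) == (1, 0, 1)

    @given(k=st.integers(0, 30), w=st.integers(0, 7), t=st.integers(0, 3))
    @settings(max_examples=50, derandomize=True)
    def test_total_is_w_plus_t_plus_2k(self, k, w, t):
        """Closed form: total = w + t + 2k for k distinct mutations."""
        catalog = [
            MutationSpec("alpha1", i + 1, "A", "V", ("alpha1", "beta1", "gamma1"))
            for i in range(k)
        ]
        manifest = build_manifest(
            catalog, [f"s{i}" for i in range(w)], [("alpha1", "beta1", "gamma1")] * t
        )
        assert manifest.total == w + t + 2 * k
        assert manifest.total == (
            len(manifest.wt_monomers) + len(manifest.mutant_monomers)
            + len(manifest.wt_trimers) + len(manifest.mutant_trimers)
        )

    def test_duplicate_mutation_rejected(self):
        spec = MutationSpec("alpha2", 83, "C", "R", ("alpha2", "beta1", "gamma1"))
        with pytest.raises(ValueError, match="duplicate"):
            build_manifest([spec, spec], [], [])


class TestMapResidues:
    def test_identity_by_number(self, toy_model):
        pairs, un_a, un_b = map_residues(toy_model, toy_model, pairing="by_number")
        n_res = sum(len(c.residues) for c in toy_model.chains)
        assert len(pairs) == n_res
        assert not un_a and not un_b
        assert all(ra is rb for (_, ra), (_, rb) in pairs)

    def test_alignment_recovers_numbering_offset(self):
        """Identical sequences numbered 1..10 vs 5..14 pair fully at offset 4."""
        names = ["ALA", "CYS", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS", "LEU"]
        a = make_fragment("strand", 10, chain_id="A", residue_names=names)
        b = make_fragment("strand", 10, chain_id="A", residue_names=names, start_number=5)
        ma = StructureModel("a", [a], "synthetic")
        mb = StructureModel("b", [b], "synthetic")
        by_number = map_residues(ma, mb, pairing="by_number")[0]
        assert len(by_number) == 6  # overlap of the number ranges only
        pairs, un_a, un_b = map_residues(ma, mb, pairing="by_alignment")
        assert len(pairs) == 10
        assert not un_a and not un_b
        assert all(rb.number - ra.number == 4 for (_, ra), (_, rb) in pairs)

    def test_no_shared_chain_raises(self, toy_model):
        other = StructureModel("x", [Chain(id="Z", residues=[])], "synthetic")
        with pytest.raises(Exception, match="no chain"):
            map_residues(toy_model, other)


class TestPlddt:
    def _computed_model(self, confidences):
        frag = make_fragment("strand", len(confidences), chain_id="A")
        for res, v in zip(frag.residues, confidences):
            for atom in res.atoms:
                atom.confidence = v
        return StructureModel("pred", [frag], source_kind="computed")

    def test_constant_baseline(self):
        profiles = plddt_profile(self._computed_model([98.0] * 8))
        assert profiles[0].baseline == pytest.approx(98.0)

    def test_alternating_values_median_is_midpoint(self):
        """Median of an even two-point 50/98 set is the middle-pair mean, 74."""
        profiles = plddt_profile(self._computed_model([50.0, 98.0] * 5))
        assert profiles[0].baseline == pytest.approx(74.0)

    def test_experimental_model_refused(self):
        m = self._computed_model([98.0] * 4)
        m.source_kind = "experimental"
        with pytest.raises(ValueError, match="not a pLDDT"):
            plddt_profile(m)
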