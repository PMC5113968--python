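"""PIR rendering, span resolution, template verification, ligand grafting,
and byte-exact serialization."""

import pytest

from pirkit.alignment_ops import Alignment, AlignmentEntry
from pirkit.pir_builder import (
    LigandSelection,
    PirEntry,
    PirFile,
    SelectionError,
    SpanResolutionError,
    build_job_config,
    build_pir,
    determine_span,
    graft_ligands,
    parse_pir,
    render_pir_sequences,
    verify_template_sequence,
    write_pir,
    write_modeller_script,
)
from pirkit.structure_io import extract_chain_sequence, parse_pdb

from conftest import atom_line, simple_chain_pdb

AGSLK = ["ALA", "GLY", "SER", "LEU", "LYS"]


@pytest.fixture
def tmpl_model():
    """Plain 5-residue template chain (AGSLK), numbered 1-5."""
    return parse_pdb(simple_chain_pdb(AGSLK))


@pytest.fixture
def tmpl_missing_model():
    """Template with SER 3 missing (REMARK 465)."""
    text = simple_chain_pdb(
        ["ALA", "GLY", None, "LEU", "LYS"],
        extra_lines=[
            "REMARK 465 MISSING RESIDUES",
            "REMARK 465   M RES C SSSEQI",
            "REMARK 465     SER A     3",
        ],
    )
    return parse_pdb(text)


@pytest.fixture
def tmpl_ligand_model():
    """AGSLK chain followed by an ADP HETATM at author number 10."""
    return parse_pdb(simple_chain_pdb(AGSLK, ligands=[("ADP", 10)]))


def _aln(target_row, template_row, model, name="tmpl"):
    ann = extract_chain_sequence(model, "A")
    tmpl = AlignmentEntry(name, "template", template_row).with_status_from(ann)
    return Alignment(
        entries=[AlignmentEntry("targ", "target", target_row), tmpl]
    )


class TestRenderPirSequences:
    def test_missing_renders_as_gap(self, tmpl_missing_model):
        aln = _aln("AGSLK", "AGSLK", tmpl_missing_model)
        assert render_pir_sequences(aln)["tmpl"] == "AG-LK"

    def test_modified_renders_as_period(self):
        text = "\n".join(
            [
                atom_line(1, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0),
                atom_line(2, "CA", "MSE", "A", 2, 2.0, 0.0, 0.0, het=True),
                atom_line(3, "CA", "GLY", "A", 3, 3.0, 0.0, 0.0),
                atom_line(4, "CA", "SER", "A", 4, 4.0, 0.0, 0.0),
                "END",
            ]
        )
        model = parse_pdb(text)
        aln = _aln("AMGS", "AMGS", model)
        assert render_pir_sequences(aln)["tmpl"] == "A.GS"

    def test_clean_template_unchanged(self, tmpl_model):
        aln = _aln("AGSLK", "AGSLK", tmpl_model)
        rendered = render_pir_sequences(aln)
        assert rendered["tmpl"] == "AGSLK"
        assert rendered["targ"] == "AGSLK"

    def test_template_without_status_is_contract_error(self):
        aln = Alignment(
            entries=[
                AlignmentEntry("targ", "target", "AG"),
                AlignmentEntry("tmpl", "template", "AG"),  # no status threaded
            ]
        )
        with pytest.raises(ValueError):
            render_pir_sequences(aln)


class TestDetermineSpan:
    def test_interior_span(self):
        codes = ["ALA", "CYS", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS", "LEU"]
        model = parse_pdb(simple_chain_pdb(codes, start=5))  # numbered 5..14
        # residues 7..10 are ASP GLU PHE GLY
        assert determine_span("DEFG", model, "A") == ("7", "10")

    def test_full_chain(self, tmpl_model):
        assert determine_span("AGSLK", tmpl_model, "A") == ("1", "5")

    def test_insertion_codes_in_span(self):
        lines = [
            atom_line(1, "CA", "ALA", "A", 51, 1.0, 0.0, 0.0),
            atom_line(2, "CA", "GLY", "A", 52, 2.0, 0.0, 0.0),
            atom_line(3, "CA", "SER", "A", 52, 3.0, 0.0, 0.0, icode="A"),
            atom_line(4, "CA", "LEU", "A", 53, 4.0, 0.0, 0.0),
            "END",
        ]
        model = parse_pdb("\n".join(lines))
        assert determine_span("AGS", model, "A") == ("51", "52A")

    def test_ambiguous_match_raises(self):
        model = parse_pdb(simple_chain_pdb(["ALA", "GLY", "ALA", "GLY", "ALA", "GLY"]))
        with pytest.raises(SpanResolutionError, match="multiple"):
            determine_span("AG", model, "A")

    def test_no_match_raises(self, tmpl_model):
        with pytest.raises(SpanResolutionError):
            determine_span("WWW", tmpl_model, "A")


class TestVerifyTemplateSequence:
    def test_matching_entry_valid(self, tmpl_model):
        assert verify_template_sequence("AGSLK", tmpl_model, "A", ("1", "5"))

    def test_wrong_letter_invalid(self, tmpl_model):
        verdict = verify_template_sequence("AASLK", tmpl_model, "A", ("1", "5"))
        assert not verdict
        assert verdict.position == 1

    def test_gap_over_observed_residue_invalid(self, tmpl_model):
        verdict = verify_template_sequence("AG-LK", tmpl_model, "A", ("1", "5"))
        assert not verdict

    def test_gap_over_missing_residue_valid(self, tmpl_missing_model):
        assert verify_template_sequence("AG-LK", tmpl_missing_model, "A", ("1", "5"))


class TestGraftLigands:
    def _pir(self, model):
        aln = _aln("AGSLK", "AGSLK", model)
        return build_pir(aln, models={"tmpl": model}, chains={"tmpl": "A"})

    @pytest.fixture
    def two_ligand_model(self):
        return parse_pdb(simple_chain_pdb(AGSLK, ligands=[("ADP", 10), (" MG", 11)]))

    def test_select_all_ligands(self, two_ligand_model):
        pir = self._pir(two_ligand_model)
        out = graft_ligands(
            pir,
            {"tmpl": two_ligand_model},
            [LigandSelection("tmpl", "ADP"), LigandSelection("tmpl", "MG")],
        )
        tmpl, targ = out.entries
        assert tmpl.body == "AGSLK.."
        assert targ.body == "AGSLK.."
        assert tmpl.end_residue == "11"  # the MG author number

    def test_select_subset_keeps_preceding_hetatm_column(self, two_ligand_model):
        pir = self._pir(two_ligand_model)
        out = graft_ligands(
            pir, {"tmpl": two_ligand_model}, [LigandSelection("tmpl", "MG")]
        )
        tmpl, targ = out.entries
        # ADP precedes the last selected ligand: template keeps its column,
        # the target marks only MG with '.'
        assert tmpl.body == "AGSLK.."
        assert targ.body == "AGSLK-."
        assert tmpl.end_residue == "11"

    def test_empty_selection_is_identity(self, two_ligand_model):
        pir = self._pir(two_ligand_model)
        assert graft_ligands(pir, {"tmpl": two_ligand_model}, []) is pir

    def test_absent_ligand_raises(self, two_ligand_model):
        pir = self._pir(two_ligand_model)
        with pytest.raises(SelectionError):
            graft_ligands(
                pir, {"tmpl": two_ligand_model}, [LigandSelection("tmpl", "NAD")]
            )

    def test_equal_lengths_after_graft(self, two_ligand_model):
        pir = self._pir(two_ligand_model)
        out = graft_ligands(
            pir, {"tmpl": two_ligand_model}, [LigandSelection("tmpl", "ADP")]
        )
        out.validate()
        assert len({len(e.body) for e in out.entries}) == 1

    def test_target_period_count_equals_selection_count(self, two_ligand_model):
        pir = self._pir(two_ligand_model)
        before = pir.target.body.count(".")
        out = graft_ligands(
            pir,
            {"tmpl": two_ligand_model},
            [LigandSelection("tmpl", "ADP"), LigandSelection("tmpl", "MG")],
        )
        assert out.target.body.count(".") - before == 2


GOLDEN_SIMPLE = """>P1;tmpl
structureX:tmpl.pdb:1:A:5:A::::
AGSLK*
>P1;targ
sequence:targ::::::::
AGSLK*
"""

GOLDEN_MISSING = """>P1;tmpl
structureX:tmpl.pdb:1:A:5:A::::
AG-LK*
>P1;targ
sequence:targ::::::::
AGSLK*
"""

GOLDEN_LIGAND = """>P1;tmpl
structureX:tmpl.pdb:1:A:10:A::::
AGSLK.*
>P1;targ
sequence:targ::::::::
AGSLK.*
"""


class TestWritePir:
    def test_golden_simple(self, tmpl_model):
        aln = _aln("AGSLK", "AGSLK", tmpl_model)
        pir = build_pir(aln, models={"tmpl": tmpl_model}, chains={"tmpl": "A"})
        assert write_pir(pir) == GOLDEN_SIMPLE

    def test_golden_missing_residue(self, tmpl_missing_model):
        aln = _aln("AGSLK", "AGSLK", tmpl_missing_model)
        pir = build_pir(aln, models={"tmpl": tmpl_missing_model}, chains={"tmpl": "A"})
        assert write_pir(pir) == GOLDEN_MISSING

    def test_golden_ligand_grafted(self, tmpl_ligand_model):
        aln = _aln("AGSLK", "AGSLK", tmpl_ligand_model)
        pir = build_pir(aln, models={"tmpl": tmpl_ligand_model}, chains={"tmpl": "A"})
        pir = graft_ligands(pir, {"tmpl": tmpl_ligand_model}, [LigandSelection("tmpl", "ADP")])
        assert write_pir(pir) == GOLDEN_LIGAND

    def test_wrap_width(self):
        body = "A" * 80
        pir = PirFile(entries=[PirEntry(name="t", kind="sequence", sequence_text=body + "*")])
        text = write_pir(pir)
        lines = text.splitlines()
        assert lines[2] == "A" * 75
        assert lines[3] == "A" * 5 + "*"

    def test_empty_file_refused(self):
        with pytest.raises(ValueError):
            write_pir(PirFile(entries=[]))

    def test_round_trip_preserves_fields(self, tmpl_ligand_model):
        aln = _aln("AGSLK", "AGSLK", tmpl_ligand_model)
        pir = build_pir(aln, models={"tmpl": tmpl_ligand_model}, chains={"tmpl": "A"})
        pir = graft_ligands(pir, {"tmpl": tmpl_ligand_model}, [LigandSelection("tmpl", "ADP")])
        back = parse_pir(write_pir(pir))
        for orig, rt in zip(pir.entries, back.entries):
            assert (orig.name, orig.kind, orig.sequence_text) == (
                rt.name, rt.kind, rt.sequence_text,
            )
            assert (orig.start_residue, orig.end_residue) == (
                rt.start_residue, rt.end_residue,
            )


class TestJobConfig:
    def test_ligand_selection_sets_hetatm_flag(self):
        cfg = build_job_config([LigandSelection("t", "ADP")])
        assert cfg.read_hetatm and not cfg.read_water

    def test_water_selection_sets_water_flag(self):
        cfg = build_job_config([LigandSelection("t", "HOH")])
        assert cfg.read_water and not cfg.read_hetatm

    def test_defaults(self):
        cfg = build_job_config()
        assert (cfg.n_models, cfg.refinement, cfg.read_hetatm, cfg.read_water) == (
            10, "very_slow", False, False,
        )

    def test_unknown_refinement_raises(self):
        with pytest.raises(ValueError):
            build_job_config(refinement="ultra")

    def test_script_stub_reflects_config(self):
        cfg = build_job_config([LigandSelection("t", "ADP")], refinement="fast")
        script = write_modeller_script(cfg, "aln.pir", ["t"], "targ")
        assert "env.io.hetatm = True" in script
        assert "refine.fast" in script
        assert "a.ending_model = 10" in script
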