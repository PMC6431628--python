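"""The synthetic-genome generator: determinism, truth records, edge-case edits."""

import pytest

from aerotype.genome_io import read_genome
from aerotype.report import analyze_genome
from aerotype.simulate import (
    ChaperoneSpec,
    GenomeSpec,
    OperonSpec,
    TruthRecord,
    calibration_curve,
    default_cohort,
    generate,
    mutate_case,
    verify,
    write_bundle,
)

SMALL = dict(total_proteins=30, decoy_count=3)


def _spec(genome_id="sim", seed=17, **kw):
    base = dict(SMALL)
    base.update(kw)
    return GenomeSpec(genome_id, seed, **base)


class TestGenerate:
    def test_deterministic_and_byte_identical(self, tmp_path):
        spec = _spec(operons=(OperonSpec("A1.b", 0.0),))
        b1, b2 = generate(spec), generate(spec)
        assert b1.record == b2.record
        assert b1.truth == b2.truth
        p1 = write_bundle(b1, tmp_path / "a")
        p2 = write_bundle(b2, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_zero_divergence_roundtrip_recovers_label(self):
        spec = _spec(operons=(OperonSpec("A1.b", 0.0),))
        bundle = generate(spec)
        result = analyze_genome(bundle.record)
        assert "A1 subtype b" in result.subtypes
        assert verify(bundle.truth, result) == []

    def test_written_bundle_reimports_identically(self, tmp_path):
        bundle = generate(_spec(operons=(OperonSpec("C_cbb3", 10.0),)))
        paths = write_bundle(bundle, tmp_path)
        rec = read_genome(paths["fasta"], paths["gff"], paths["metadata"])
        assert rec == bundle.record
        truth = TruthRecord.from_json(paths["truth"].read_text())
        assert truth == bundle.truth

    def test_extreme_divergence_is_never_accepted(self, library):
        spec = _spec(operons=(OperonSpec("C_cbb3", 80.0),))
        bundle = generate(spec)
        result = analyze_genome(bundle.record)
        assert "C_cbb3" not in result.repertoire

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="unknown operon template"):
            OperonSpec("X1.z")
        with pytest.raises(ValueError, match="divergence"):
            OperonSpec("A1.a", divergence=90.0)
        with pytest.raises(ValueError, match="cannot drop"):
            generate(_spec(operons=(OperonSpec("A1.a", 10.0, drop_roles=("CydA",)),)))

    def test_calibration_curve_monotone(self):
        """The generator's own divergence/identity oracle: identity decays
        from 100% as planted divergence grows."""
        idents = calibration_curve("A1.COX1", [0, 10, 25, 45, 65, 80], seed=13)
        assert idents[0] == pytest.approx(100.0)
        assert all(a > b for a, b in zip(idents, idents[1:]))
        assert idents[-1] < 35.0


class TestMutateCase:
    def test_drop_cydb_expects_ambiguous_bd(self):
        # the ambiguous single-subunit call is defined for gate-passing genomes
        bundle = generate(_spec(operons=(OperonSpec("bd_I", 10.0),), total_proteins=1005))
        assert bundle.truth.expected_repertoire == ["bd_I"]
        edited = mutate_case(bundle, {"op": "drop_subunit", "operon": 0, "role": "CydB"})
        assert edited.truth.expected_repertoire == []
        assert "single_subunit:bd_I" in edited.truth.expected_flags
        assert verify(edited.truth, analyze_genome(edited.record)) == []

    def test_remove_tyrosine_expects_degenerate_b(self):
        bundle = generate(_spec(operons=(OperonSpec("B.ba3-a1", 10.0),)))
        edited = mutate_case(
            bundle, {"op": "remove_residue", "operon": 0, "role": "COX1",
                     "diagnostic": "catalytic_Tyr"})
        assert edited.truth.expected_repertoire == []
        assert "B_degenerate_present" in edited.truth.expected_flags
        assert verify(edited.truth, analyze_genome(edited.record)) == []

    def test_delete_ctab_expects_magnetospirillum_variant(self):
        bundle = generate(_spec(operons=(OperonSpec("A1.b", 10.0),)))
        assert bundle.truth.expected_subtypes == ["A1 subtype b"]
        edited = mutate_case(bundle, {"op": "drop_subunit", "operon": 0, "role": "CtaB"})
        assert edited.truth.expected_subtypes == ["A1 subtype b-Magnetospirillum"]
        assert verify(edited.truth, analyze_genome(edited.record)) == []

    def test_shuffle_cluster_loses_binomial_label(self):
        bundle = generate(_spec(operons=(OperonSpec("A1.a", 10.0),)))
        edited = mutate_case(bundle, {"op": "shuffle_cluster", "operon": 0})
        assert edited.truth.expected_subtypes == []

    def test_set_completeness_fails_gate(self):
        bundle = generate(_spec(operons=(OperonSpec("A1.a", 10.0),), total_proteins=1005))
        edited = mutate_case(bundle, {"op": "set_completeness", "value": 70.0})
        assert edited.truth.expected_category == "withheld"

    def test_inapplicable_edit_rejected(self):
        bundle = generate(_spec(operons=(OperonSpec("A1.a", 10.0),)))
        with pytest.raises(ValueError):
            mutate_case(bundle, {"op": "drop_subunit", "operon": 0, "role": "CydA"})
        with pytest.raises(ValueError):
            mutate_case(bundle, {"op": "warp_genome"})


class TestDefaultCohort:
    def test_cohort_shape_and_coverage(self):
        specs = default_cohort(1)
        assert len(specs) == 30
        ids = [s.genome_id for s in specs]
        assert len(set(ids)) == 30
        templates = {op.template for s in specs for op in s.operons}
        assert {"A1.a", "A1.a-III", "A1.b", "A2.CyoCAB", "A2.a-I", "B.ba3-a1",
                "bd_I", "Cio", "C_cbb3", "AOX", "NOR"} <= templates
        # expected categories span all four groups plus a withheld genome
        cats = {generate(s).truth.expected_category for s in specs}
        assert cats == {"I", "II", "III", "IV", "withheld"}
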