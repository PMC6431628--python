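"""Alignment, significance, hydropathy and the detection funnel."""

import math

import numpy as np
import pytest

from aerotype.detection import (
    DetectionThresholds,
    align_identity,
    check_diagnostics,
    detect,
    hssp_identity_threshold,
    significance,
    tm_count,
)
from aerotype.profiles import default_library, get_profile, mutate_sequence
from tests.conftest import make_genome, random_protein
from tests.dp_oracle import oracle_score, recount_identity


class TestAlignIdentity:
    def test_self_alignment_is_100_percent(self, rng):
        seq = random_protein(rng, 100)
        res = align_identity(seq, seq)
        assert res.percent_identity == pytest.approx(100.0)
        assert res.ref_coverage == pytest.approx(1.0)

    def test_constructed_half_identity(self, rng):
        """A 60-mer against a copy whose central 30 residues are substituted:
        matching flanks force a full-span local alignment at 50% identity."""
        alphabet = list("ACDEFGHIKLMNQRSTVWY")  # no proline
        ref = "".join(rng.choice(alphabet, size=60))
        query = ref[:15] + "P" * 30 + ref[45:]
        res = align_identity(query, ref)
        assert res.percent_identity == pytest.approx(50.0)
        assert res.aligned_columns == 60

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            align_identity("MKT1", "MKT")
        with pytest.raises(ValueError, match="empty"):
            align_identity("", "MKT")

    @pytest.mark.parametrize("n", [40, 120, 300])
    def test_matches_independent_dp_oracle(self, rng, n):
        """Score equals a from-scratch Gotoh DP; identity equals an
        independent recount over the alignment coordinate map."""
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(n // 2, n + 1)))
            b = random_protein(rng, int(rng.integers(n // 2, n + 1)))
            res = align_identity(a, b)
            assert res.score == pytest.approx(oracle_score(a, b))
            assert res.percent_identity == pytest.approx(recount_identity(a, b, res.ref_to_query))

    def test_oracle_on_related_pairs(self, rng):
        ref = get_profile("A1.COX2").reference
        for d in (5.0, 20.0, 40.0):
            q = mutate_sequence(ref, d, rng)
            res = align_identity(q, ref)
            assert res.score == pytest.approx(oracle_score(q, ref))
            assert res.percent_identity == pytest.approx(recount_identity(q, ref, res.ref_to_query))


class TestSignificance:
    def test_linear_in_search_space(self):
        assert significance(100, 300, 5_000_000) == pytest.approx(
            10 * significance(100, 300, 500_000)
        )

    def test_monotone_decreasing_in_score(self):
        evalues = [significance(s, 300, 1_000_000) for s in (50, 100, 200, 400)]
        assert evalues == sorted(evalues, reverse=True)
        assert significance(5000, 300, 1_000_000) == pytest.approx(0.0, abs=1e-300)

    def test_closed_form(self):
        # independent evaluation of E = K * m * n * exp(-lambda * S)
        s, m, n = 120.0, 250, 800_000
        assert significance(s, m, n) == pytest.approx(
            0.134 * 250 * 800_000 * math.exp(-0.3176 * 120.0)
        )

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            significance(100, 0, 1000)
        with pytest.raises(ValueError):
            significance(100, 100, -5)


class TestTmCount:
    def test_polyleucine_has_a_segment(self):
        assert tm_count("L" * 30) >= 1

    def test_polyaspartate_has_none(self):
        assert tm_count("D" * 30) == 0

    def test_short_sequence_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="shorter than"):
            assert tm_count("MKT") == 0

    def test_two_separated_segments(self):
        seq = "D" * 25 + "L" * 21 + "D" * 25 + "L" * 21 + "D" * 25
        assert tm_count(seq) == 2

    def test_reference_counts_fall_in_frozen_ranges(self, library):
        for p in library:
            lo, hi = p.expected_tm_range
            assert lo <= tm_count(p.reference) <= hi


class TestDiagnostics:
    def test_self_consistency(self, library):
        for p in library:
            if not p.diagnostics:
                continue
            res = align_identity(p.reference, p.reference)
            verdicts = check_diagnostics(res, p, p.reference)
            assert set(verdicts.values()) == {"present"}

    def test_unalignable_when_column_outside_alignment(self):
        profile = get_profile("A1.COX1")
        # query = a short C-terminal fragment: N-terminal diagnostics unalignable
        first_diag = min(d.ref_pos for d in profile.diagnostics)
        frag_start = max(d.ref_pos for d in profile.diagnostics) + 5
        query = profile.reference[frag_start:]
        res = align_identity(query, profile.reference)
        verdicts = check_diagnostics(res, profile, query)
        name = next(d.name for d in profile.diagnostics if d.ref_pos == first_diag)
        assert verdicts[name] == "unalignable"


def _operon_genome(entries, rng, divergence=10.0, **kw):
    genes = []
    for i, pid in enumerate(entries):
        p = get_profile(pid)
        seq = mutate_sequence(p.reference, divergence, rng,
                              protected=[d.ref_pos for d in p.diagnostics],
                              tm_segments=p.tm_segments)
        genes.append((f"g{i:02d}_{pid.replace('.', '_')}", seq))
    return make_genome(genes, **kw)


class TestDetect:
    def test_empty_library_and_empty_genome(self, library):
        g = make_genome([("g1", "MKTAYIAKQRQISFVKSHFSRQ")])
        with pytest.raises(ValueError):
            detect(g, [])
        empty = make_genome([("g1", "MKTAYIAKQRQISFVKSHFSRQ")])
        empty.features = []
        assert detect(empty, library) == []

    def test_planted_subunits_accepted_with_true_targets(self, library, rng):
        genome = _operon_genome(["A1.COX1", "bd_I.CydA", "SCO.SCO", "trait.HydA"], rng)
        hits = {h.gene_id: h for h in detect(genome, library) if h.accepted}
        assert len(hits) == 4
        targets = sorted(h.target for h in hits.values())
        assert targets == ["A1", "HydA", "SCO", "bd_I"]

    def test_degenerate_b_relabel(self, library, rng):
        p = get_profile("B.COX1")
        tyr = next(d for d in p.diagnostics if d.name == "catalytic_Tyr")
        seq = mutate_sequence(p.reference, 10.0, rng,
                              protected=[d.ref_pos for d in p.diagnostics],
                              tm_segments=p.tm_segments)
        seq = seq[:tyr.ref_pos] + "F" + seq[tyr.ref_pos + 1:]
        genome = make_genome([("bcox1", seq)])
        (hit,) = [h for h in detect(genome, library) if h.accepted]
        assert hit.target == "B_degenerate"
        assert "degenerate:missing_catalytic_Tyr" in hit.flags

    def test_quinol_variant_cox2(self, library, rng):
        p = get_profile("A1.COX2")
        seq = mutate_sequence(p.reference, 10.0, rng,
                              protected=[d.ref_pos for d in p.diagnostics],
                              tm_segments=p.tm_segments)
        for d in p.diagnostics:  # strip the whole CuA ligand set
            seq = seq[:d.ref_pos] + ("A" if seq[d.ref_pos] != "A" else "G") + seq[d.ref_pos + 1:]
        genome = make_genome([("cox2", seq)])
        (hit,) = [h for h in detect(genome, library) if h.accepted]
        assert hit.target == "A1" and "quinol_variant" in hit.flags

    def test_missing_required_diagnostic_never_accepted(self, library, rng):
        """An A1 subunit I without the catalytic tyrosine is rejected."""
        p = get_profile("A1.COX1")
        tyr = next(d for d in p.diagnostics if d.name == "catalytic_Tyr")
        seq = mutate_sequence(p.reference, 5.0, rng,
                              protected=[d.ref_pos for d in p.diagnostics],
                              tm_segments=p.tm_segments)
        seq = seq[:tyr.ref_pos] + "F" + seq[tyr.ref_pos + 1:]
        genome = make_genome([("acox1", seq)])
        hits = detect(genome, library)
        assert all(not h.accepted for h in hits)
        # and generally: no accepted hit anywhere carries an absent required diagnostic
        for h in detect(genome, library):
            if h.accepted:
                assert "absent" not in h.residue_verdicts.values()

    def test_decoy_shuffles_yield_no_accepted_hits(self, library, rng):
        refs = [get_profile(pid).reference for pid in
                ("A1.COX1", "bd_I.CydB", "SCO.SCO", "trait.FumB", "AOX.AOX")]
        genes = []
        for i, ref in enumerate(refs):
            for j in range(3):
                shuffled = "".join(np.array(list(ref))[rng.permutation(len(ref))])
                genes.append((f"decoy{i}{j}", shuffled))
        genome = make_genome(genes)
        assert all(not h.accepted for h in detect(genome, library))

    def test_gene_order_permutation_invariance(self, library, rng):
        genome = _operon_genome(["A1.COX1", "A1.COX2", "bd_I.CydA"], rng)
        shuffled = make_genome(
            [(f.gene_id, f.product_seq) for f in reversed(genome.features)],
            genome_id=genome.genome_id,
        )
        key = lambda h: (h.gene_id, h.profile_id, h.status, h.percent_identity)
        assert sorted(map(key, detect(genome, library))) == sorted(
            map(key, detect(shuffled, library))
        )

    def test_identity_threshold_monotonicity(self, library, rng):
        """Lowering the identity threshold never removes an accepted hit."""
        genome = _operon_genome(["A1.COX1", "C_cbb3.CcoN", "trait.HydA"], rng, divergence=35.0)
        strict = {h.gene_id for h in detect(genome, library, DetectionThresholds(min_identity=40.0)) if h.accepted}
        default = {h.gene_id for h in detect(genome, library) if h.accepted}
        loose = {h.gene_id for h in detect(genome, library, DetectionThresholds(min_identity=10.0)) if h.accepted}
        assert strict <= default <= loose

    def test_one_similarity_criterion_yields_ambiguous(self, library, rng):
        """A heavily diverged homolog keeps a significant E-value but falls
        below 25% identity: recorded ambiguous, never accepted or dropped."""
        p = get_profile("trait.MaeB")
        seq = mutate_sequence(p.reference, 78.0, rng, tm_segments=p.tm_segments)
        genome = make_genome([("far", seq)])
        hits = detect(genome, library)
        far = [h for h in hits if h.gene_id == "far" and h.profile_id == "trait.MaeB"]
        if far:  # at this divergence the hit must never be accepted
            assert all(h.status == "ambiguous" for h in far)
        assert all(not h.accepted for h in hits)


class TestHsspCurve:
    def test_short_alignments_need_more_identity(self):
        assert hssp_identity_threshold(20) > hssp_identity_threshold(100) > hssp_identity_threshold(500)
        assert hssp_identity_threshold(500) < 25.0
        assert hssp_identity_threshold(0) == 100.0
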