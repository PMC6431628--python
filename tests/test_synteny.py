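"""Operon clustering and binomial subtype assignment."""

import itertools

import pytest

from aerotype.detection import DetectionHit
from aerotype.genome_io import GeneFeature, GenomeRecord
from aerotype.synteny import (
    ClusterMember,
    OperonCluster,
    SubtypeSignature,
    assign_subtype,
    cluster,
    load_signatures,
)

SIGNATURES = load_signatures()


def _hit(gene_id, role, target="A1", kind="oxidase"):
    return DetectionHit(
        gene_id=gene_id, profile_id=f"{target}.{role}", target=target, kind=kind,
        subunit_role=role, percent_identity=90.0, evalue=1e-80, tm_count=12,
        coverage=1.0, residue_verdicts={}, status="accepted",
    )


def _genome(gene_positions, strand="+"):
    """gene_positions: [(gene_id, start, end)] on one replicon."""
    feats = [
        GeneFeature(g, "chr1", s, e, strand, "M" * 60)
        for g, s, e in gene_positions
    ]
    return GenomeRecord("toy", feats, 98.0, 24)


class TestCluster:
    def test_adjacent_genes_form_one_cluster(self):
        genome = _genome([("a", 100, 400), ("b", 500, 900), ("c", 1000, 1500)])
        hits = [_hit("a", "COX2"), _hit("b", "COX1"), _hit("c", "COX3")]
        out = cluster(hits, genome, max_gap=500)
        assert len(out) == 1 and out[0].roles == ("COX2", "COX1", "COX3")

    def test_distant_genes_form_singletons(self):
        genome = _genome([("a", 100, 400), ("b", 10_500, 10_900)])
        hits = [_hit("a", "COX1"), _hit("b", "COX1")]
        out = cluster(hits, genome, max_gap=500)
        assert [c.roles for c in out] == [("COX1",), ("COX1",)]

    def test_hit_without_coordinates_excluded_with_warning(self):
        genome = _genome([("a", 100, 400)])
        genome.features.append(GeneFeature("orphan", None, None, None, ".", "M" * 60))
        hits = [_hit("a", "COX1"), _hit("orphan", "COX2")]
        with pytest.warns(UserWarning, match="lacks coordinates"):
            out = cluster(hits, genome)
        assert [m.gene_id for c in out for m in c.members] == ["a"]

    @pytest.mark.parametrize("n_genes", [2, 4, 6, 8])
    def test_matches_interval_merging_oracle(self, rng, n_genes):
        """Cluster boundaries equal a brute-force interval-merging oracle over
        random gap patterns."""
        max_gap = 500
        for _ in range(40):
            positions, cursor = [], 100
            for i in range(n_genes):
                start = cursor + int(rng.integers(1, 1500))
                end = start + int(rng.integers(50, 400))
                positions.append((f"g{i}", start, end))
                cursor = end
            genome = _genome(positions)
            hits = [_hit(g, "COX1") for g, _, _ in positions]
            got = [[m.gene_id for m in c.members] for c in cluster(hits, genome, max_gap)]
            # oracle: walk pairs, split where the intergenic gap exceeds max_gap
            expected, run = [], [positions[0][0]]
            for (g1, s1, e1), (g2, s2, e2) in itertools.pairwise(positions):
                if s2 - e1 - 1 > max_gap:
                    expected.append(run)
                    run = []
                run.append(g2)
            expected.append(run)
            assert got == expected


def _cluster_from_roles(roles, family="A1", strand="+", targets=None):
    members = []
    pos = 100
    for i, role in enumerate(roles):
        t = targets[i] if targets else family
        members.append(ClusterMember(f"g{i}", role, t, strand, pos, pos + 300))
        pos += 400
    return OperonCluster("chr1", tuple(members))


class TestAssignSubtype:
    @pytest.mark.parametrize(
        "roles,family,expected",
        [
            # the characteristic COX3 doublet marks subtype a-III
            (("COX2", "COX1", "COX3", "COX3"), "A1", "A1 subtype a-III"),
            (("COX2", "COX1", "COX3"), "A1", "A1 subtype a"),
            (("COX2", "COX1", "CtaB", "CtaG"), "A1", "A1 subtype b"),
            # CtaB missing between COX1 and CtaG: the Magnetospirillum variant
            (("COX2", "COX1", "CtaG"), "A1", "A1 subtype b-Magnetospirillum"),
            (("COX3", "COX2", "COX1", "SCO", "SCO"), "A2", "A2 subtype CyoCAB"),
            # fusion with Alternative Complex III plus SCO genes: subtype a-I
            (("ActB", "ActA", "COX1", "COX2", "SCO"), "A2", "A2 subtype a-I"),
            (("COX1", "COX2", "SCO"), "B", "B subtype ba3-a1"),
            (("CydA", "CydB"), "bd_I", "bd_I subtype bd-I"),
            (("CcoN", "CcoO", "CcoP"), "C_cbb3", "C_cbb3 subtype cbb3"),
        ],
    )
    def test_canonical_patterns(self, roles, family, expected):
        targets = [family if r in ("COX1", "COX2", "COX3", "CydA", "CydB", "CcoN", "CcoO", "CcoP")
                   else ("SCO" if r == "SCO" else "accessory") for r in roles]
        call = assign_subtype(_cluster_from_roles(roles, family, targets=targets), SIGNATURES)
        assert call.binomial == expected

    def test_minus_strand_cluster_matches_reversed_pattern(self):
        roles = ("CtaG", "CtaB", "COX1", "COX2")
        targets = ["CtaG_Cox11", "accessory", "A1", "A1"]
        call = assign_subtype(_cluster_from_roles(roles, "A1", strand="-", targets=targets), SIGNATURES)
        assert call.binomial == "A1 subtype b"
        # the same chromosome order on the plus strand is NOT subtype b
        call_fwd = assign_subtype(_cluster_from_roles(roles, "A1", targets=targets), SIGNATURES)
        assert call_fwd.binomial is None

    def test_cyocab_requires_sco(self):
        call = assign_subtype(_cluster_from_roles(("COX3", "COX2", "COX1"), "A2"), SIGNATURES)
        assert call.binomial != "A2 subtype CyoCAB"

    def test_unclassified_keeps_role_string(self):
        call = assign_subtype(_cluster_from_roles(("COX3", "COX1", "COX2"), "A1"), SIGNATURES)
        assert call.binomial is None
        assert call.diagnostic == "unclassified:COX3,COX1,COX2"

    def test_chimeric_cluster_diagnostic(self):
        c = _cluster_from_roles(("COX1", "CydA"), targets=["A1", "bd_I"])
        assert assign_subtype(c, SIGNATURES).diagnostic == "chimeric_cluster"

    def test_degenerate_b_counts_as_family_b(self):
        c = _cluster_from_roles(("COX1", "COX2", "SCO"), targets=["B_degenerate", "B", "SCO"])
        assert assign_subtype(c, SIGNATURES).binomial == "B subtype ba3-a1"

    def test_singleton_families_without_signatures_are_silent(self):
        call = assign_subtype(_cluster_from_roles(("AOX",), "AOX"), SIGNATURES)
        assert call.binomial is None and call.diagnostic == ""


class TestSignatureValidation:
    def test_shipped_table_loads(self):
        assert any(s.binomial == "A1 subtype b" for s in SIGNATURES)
        comparative = {s.subtype for s in SIGNATURES if s.comparative}
        assert comparative == {"delta", "CyoBAC", "chloroflexian"}

    def test_indistinguishable_signatures_fail_fast(self, tmp_path):
        bad = tmp_path / "sig.yaml"
        bad.write_text(
            "version: 1\nsignatures:\n"
            "  - {family: A1, subtype: x, pattern: [COX1, COX2]}\n"
            "  - {family: A1, subtype: y, pattern: [COX1, COX2]}\n"
        )
        with pytest.raises(ValueError, match="ambiguous signatures"):
            load_signatures(bad)
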