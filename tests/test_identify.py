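import itertools

import pytest

from srnakit.identify import (
    CatalogEntry,
    abundance_threshold,
    apply_abundance_filter,
    assign_names,
    cluster_by_prefix,
    identify_candidates,
    identify_pipeline,
    match_candidate,
    merge_families,
    name_candidate,
    _merged_family_name,
)
from srnakit.preprocess import ReadSet


def literal_match_oracle(query, reference):
    """The quoted rule, verbatim: fewer than 3 mismatches over the
    5'-anchored overlap and fewer than 2 nt difference in length."""
    mismatches = sum(q != r for q, r in zip(query, reference))
    return mismatches < 3 and abs(len(query) - len(reference)) < 2


class TestMatchCandidate:
    REF = "UGACAGAAGAGAGUGAGCACA"

    def test_identity(self):
        m = match_candidate(self.REF, self.REF)
        assert (m.substitutions, m.length_difference, m.is_match) == (0, 0, True)

    def test_three_substitutions_rejected(self):
        query = "ACU" + self.REF[3:]
        assert sum(a != b for a, b in zip(query, self.REF)) == 3
        assert not match_candidate(query, self.REF).is_match

    def test_two_nt_shorter_rejected(self):
        assert not match_candidate(self.REF[:-2], self.REF).is_match

    def test_boundary_two_subs_one_shorter_accepted(self):
        query = "AC" + self.REF[2:-1]
        m = match_candidate(query, self.REF)
        assert m.substitutions == 2 and m.length_difference == -1
        assert m.is_match

    def test_symmetric_for_equal_lengths(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(list("ACGU"), 21))
            b = "".join(rng.choice(list("ACGU"), 21))
            assert (match_candidate(a, b).substitutions
                    == match_candidate(b, a).substitutions)

    def test_exhaustive_small_alphabet_oracle(self):
        # every pair of 5-7-mers over {A,U}: rule equals the literal quote
        seqs = ["".join(p) for n in (5, 6, 7)
                for p in itertools.product("AU", repeat=n)]
        for q in seqs[::7]:
            for r in seqs[::11]:
                assert match_candidate(q, r).is_match == literal_match_oracle(q, r)


class TestIdentifyCandidates:
    def test_exact_read_assigned(self, small_catalog, simple_readset):
        out = identify_candidates(simple_readset, small_catalog)
        by_seq = {a.sequence: a.entry.family for a in out}
        assert by_seq["UGACAGAAGAGAGUGAGCACA"] == "miR156"
        assert "AAAACCCCGGGGUUUUAAAACCCC" not in by_seq  # 24-nt background

    def test_minimal_distance_wins(self):
        ref_a = CatalogEntry("miRA", "AAAAAAAAAAAAAAAAAAAAA")
        ref_b = CatalogEntry("miRB", "CCAAAAAAAAAAAAAAAAAAA")
        read = "CAAAAAAAAAAAAAAAAAAAA"  # 1 sub vs both references
        rs = ReadSet(counts={read: 5})
        out = identify_candidates(rs, [ref_a, ref_b])
        assert out[0].entry.family == "miRA"  # tie on (1, 0) -> lexicographic

    def test_prefers_fewer_substitutions(self):
        ref_a = CatalogEntry("miRA", "AAAAAAAAAAAAAAAAAAAAA")
        ref_b = CatalogEntry("miRB", "GGAAAAAAAAAAAAAAAAAAA")
        read = "GGAAAAAAAAAAAAAAAAAAG"  # 3 subs vs A (no match), 1 vs B
        rs = ReadSet(counts={read: 5})
        out = identify_candidates(rs, [ref_a, ref_b])
        assert out[0].entry.family == "miRB"

    def test_empty_catalog_rejected(self, simple_readset):
        with pytest.raises(ValueError):
            identify_candidates(simple_readset, [])


class TestMergeFamilies:
    def test_one_substitution_merges(self):
        cat = [CatalogEntry("miR156", "UGACAGAAGAGAGUGAGCACA"),
               CatalogEntry("miR157", "UGACAGAAGAGAGUGAGCACU")]
        assert merge_families(cat) == {"miR156": "miR156/7",
                                       "miR157": "miR156/7"}

    def test_distant_families_not_merged(self):
        cat = [CatalogEntry("miR156", "UGACAGAAGAGAGUGAGCACA"),
               CatalogEntry("miR390", "AAGCUCAGGAGGGAUAGCGCC")]
        merged = merge_families(cat)
        assert merged == {"miR156": "miR156", "miR390": "miR390"}

    def test_transitive_closure_matches_union_find_oracle(self):
        # A~B, B~C, A!~C: all three merge
        a = "AAAAAAAAAAAAAAAAAAAAA"
        b = "AAAAAAAAAAAAAAAAAAACC"  # 2 subs vs a
        c = "AAAAAAAAAAAAAAAAACACC"  # 3 subs vs a (no match), 1 vs b
        cat = [CatalogEntry("miR1", a), CatalogEntry("miR2", b),
               CatalogEntry("miR3", c)]
        assert not match_candidate(a, c).is_match
        assert match_candidate(a, b).is_match and match_candidate(b, c).is_match

        # independent union-find oracle
        parent = {f: f for f in ("miR1", "miR2", "miR3")}

        def find(x):
            return x if parent[x] == x else find(parent[x])

        seqs = {"miR1": a, "miR2": b, "miR3": c}
        for fa, fb in itertools.combinations(seqs, 2):
            if literal_match_oracle(seqs[fa], seqs[fb]):
                parent[find(fb)] = find(fa)
        oracle_groups = {f: find(f) for f in seqs}
        assert len(set(oracle_groups.values())) == 1

        merged = merge_families(cat)
        assert len(set(merged.values())) == 1
        assert merged["miR1"] == "miR1/2/3"

    @pytest.mark.parametrize("families,expected", [
        (["miR156", "miR157"], "miR156/7"),
        (["miR170", "miR171"], "miR170/1"),
        (["miR165", "miR166"], "miR165/6"),
        (["miR9", "miR10"], "miR9/10"),
    ])
    def test_merged_name_style(self, families, expected):
        assert _merged_family_name(families) == expected


class TestClusterByPrefix:
    def _asg(self, seq, count, family="miRX"):
        from srnakit.identify import Assignment, MatchResult
        entry = CatalogEntry(family, seq)
        return Assignment(seq, count, entry,
                          MatchResult(family, 0, 0, True))

    def test_shared_prefix_one_cluster(self):
        p = "UGACAGAAGAGAGUGA"  # 16 nt
        a = self._asg(p + "GCACA", 100)
        b = self._asg(p + "GCACAU", 10)
        clusters = cluster_by_prefix([a, b])
        assert len(clusters) == 1
        c = clusters[0]
        assert c.sequence == p + "GCACA"
        assert c.raw_count == 100 and c.cluster_count == 110
        assert c.n_members == 2

    def test_position_16_difference_splits(self):
        base = "UGACAGAAGAGAGUG"
        a = self._asg(base + "AGCACA", 5)
        b = self._asg(base + "CGCACA", 5)
        assert len(cluster_by_prefix([a, b])) == 2

    def test_equal_counts_shorter_representative(self):
        p = "UGACAGAAGAGAGUGA"
        long = self._asg(p + "GCACAU", 50)
        short = self._asg(p + "GCACA", 50)
        clusters = cluster_by_prefix([long, short])
        assert clusters[0].sequence == p + "GCACA"

    def test_partition_property(self, rng):
        assignments = []
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGU"), int(rng.integers(18, 24))))
            assignments.append(self._asg(seq, int(rng.integers(1, 100))))
        clusters = cluster_by_prefix(assignments)
        assert (sum(c.cluster_count for c in clusters)
                == sum(a.count for a in assignments))
        members = [m for c in clusters for m, _ in c.members]
        assert len(members) == len(assignments)


class TestAbundanceFilter:
    def _cluster(self, count):
        from srnakit.identify import MiRNACandidate
        return MiRNACandidate(sequence="A" * 21, family="miRX", arm=None,
                              members=[("A" * 21, count)], raw_count=count,
                              cluster_count=count)

    def test_raw_threshold_at_1m(self):
        # 5 RPM = 5 reads at 1M; raw threshold 10 dominates
        kept = apply_abundance_filter([self._cluster(11), self._cluster(10)],
                                      1_000_000)
        assert [c.raw_count for c in kept] == [11]

    def test_rpm_threshold_at_10m(self):
        # 5 RPM = 50 reads at 10M: count 30 dropped despite >10 reads
        kept = apply_abundance_filter([self._cluster(51), self._cluster(30)],
                                      10_000_000)
        assert [c.raw_count for c in kept] == [51]

    def test_tiny_library_keeps_constant_threshold(self):
        assert abundance_threshold(1) == 10.0

    def test_either_rule(self):
        kept = apply_abundance_filter([self._cluster(30)], 10_000_000,
                                      rule="either")
        assert len(kept) == 1

    def test_matches_literal_oracle_on_random_instances(self, rng):
        # oracle states the quoted rules independently: more than ten raw
        # reads AND more than five RPM ("whichever is higher" = both bind)
        for _ in range(1000):
            count = int(rng.integers(0, 200))
            total = int(rng.integers(1, 50_000_000))
            cluster = self._cluster(count) if count > 0 else None
            if cluster is None:
                continue
            kept = apply_abundance_filter([cluster], total)
            oracle = (count > 10) and (count * 1e6 / total > 5)
            assert (len(kept) == 1) == oracle


class TestNaming:
    def test_published_style_example(self):
        assert (name_candidate("Smo", "miR170/1-3p", 2380, 3761)
                == "Smo-miR170/1-3p.2380_3761")

    def test_simple_name(self):
        assert name_candidate("Era", "miR168", 921, 57) == "Era-miR168.921_57"

    def test_minimal(self):
        assert name_candidate("Sp", "miRX", 1, 1) == "Sp-miRX.1_1"

    def test_serial_must_be_positive(self):
        with pytest.raises(ValueError):
            name_candidate("Sp", "miRX", 0, 5)

    def test_assign_names_orders_by_cluster_count(self):
        from srnakit.identify import MiRNACandidate
        big = MiRNACandidate("A" * 21, "miR1", "5p", [("A" * 21, 90)], 90, 90)
        small = MiRNACandidate("C" * 21, "miR2", None, [("C" * 21, 20)], 20, 20)
        assign_names([small, big], "Sp")
        assert big.name == "Sp-miR1-5p.1_90"
        assert small.name == "Sp-miR2.2_20"


class TestPipelineDeterminism:
    def test_repeat_runs_identical(self, small_catalog):
        counts = {"UGACAGAAGAGAGUGAGCACA": 60,
                  "UGACAGAAGAGAGUGAGCACU": 20,
                  "UCGGACCAGGCUUCAUUCCCC": 30}
        rs = ReadSet(counts=counts, library_id="x")
        rs = ReadSet(counts=counts, total_18_26=110)
        a = identify_pipeline(rs, small_catalog)
        b = identify_pipeline(rs, small_catalog)
        assert [(c.name, c.sequence, c.raw_count) for c in a] == \
               [(c.name, c.sequence, c.raw_count) for c in b]
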