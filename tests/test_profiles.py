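"""Per-genome and pooled functional category profiles."""

import pytest

from fsfcensus import (
    AssignmentRecord,
    GenomeRecord,
    ValidationError,
    build_census,
    group_profiles,
    parse_css,
    pool_summary,
    profile_genome,
    round2,
    scheme_pool,
)
from fsfcensus.profiles import FunctionalProfile
from fsfcensus.simulate import SyntheticConfig, generate_truth


def rec(gid, css, pid="p1"):
    return AssignmentRecord(gid, pid, parse_css(css), ((1, 100),), 1e-9)


def genome(gid, sk="Bacteria", group="X", ls="FL"):
    return GenomeRecord(gid, sk, group, ls)


class TestProfileGenome:
    def test_nona_excluded_from_denominator(self, mini_scheme):
        # 2 Metabolism FSFs + 1 Regulation FSF + 1 NONA
        records = [
            rec("g1", "a.1.1", "p1"),
            rec("g1", "a.1.2", "p2"),
            rec("g1", "g.1.1", "p3"),
            rec("g1", "k.1.1", "p4"),
        ]
        m = build_census(records, [genome("g1")])
        p = profile_genome(m, "g1", mini_scheme)
        assert p.total_annotated == 3
        assert p.general_counts["Metabolism"] == 2
        assert p.general_percent["Metabolism"] == pytest.approx(66.667, abs=1e-3)
        assert p.general_percent["Regulation"] == pytest.approx(33.333, abs=1e-3)
        assert sum(p.general_percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_annotated_genome_all_zero(self, mini_scheme):
        m = build_census([rec("g1", "k.1.1")], [genome("g1")])
        p = profile_genome(m, "g1", mini_scheme)
        assert p.total_annotated == 0
        assert all(v == 0 for v in p.general_counts.values())
        assert all(v == 0.0 for v in p.general_percent.values())

    def test_unknown_genome_rejected(self, mini_scheme):
        m = build_census([rec("g1", "a.1.1")], [genome("g1")])
        with pytest.raises(ValidationError):
            profile_genome(m, "nope", mini_scheme)

    def test_full_fixture_genome_metabolism_share(self, scheme):
        records = [rec("g1", k, f"p{i}") for i, k in enumerate(scheme.fsf_to_minor)]
        m = build_census(records, [genome("g1")])
        p = profile_genome(m, "g1", scheme)
        assert p.total_annotated == 1646
        assert round2(p.general_percent["Metabolism"]) == 32.38

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            FunctionalProfile("g1", {"Metabolism": 2}, {"Energy": 2}, 3)


class TestPoolSummary:
    def test_shared_fsf_counted_once(self, mini_scheme):
        records = [rec("g1", "a.1.1"), rec("g2", "a.1.1"), rec("g2", "c.1.1")]
        m = build_census(records, [genome("g1"), genome("g2")])
        pool = pool_summary(m, ["g1", "g2"], mini_scheme)
        assert pool.general_counts["Metabolism"] == 1
        assert pool.pool_total == 2

    def test_single_genome_pool_equals_profile(self, mini_scheme):
        records = [rec("g1", "a.1.1", "p1"), rec("g1", "g.1.1", "p2"), rec("g1", "k.1.1", "p3")]
        m = build_census(records, [genome("g1")])
        pool = pool_summary(m, ["g1"], mini_scheme)
        p = profile_genome(m, "g1", mini_scheme)
        assert pool.general_counts == p.general_counts
        assert pool.minor_counts == p.minor_counts
        assert pool.pool_total == p.total_annotated

    def test_empty_subset_rejected(self, mini_scheme):
        m = build_census([rec("g1", "a.1.1")], [genome("g1")])
        with pytest.raises(ValidationError):
            pool_summary(m, [], mini_scheme)

    def test_pool_total_bounded_by_sum_of_repertoires(self, mini_scheme):
        # overlapping repertoires: strict inequality
        records = [rec("g1", "a.1.1"), rec("g2", "a.1.1")]
        m = build_census(records, [genome("g1"), genome("g2")])
        pool = pool_summary(m, None, mini_scheme)
        totals = [profile_genome(m, g, mini_scheme).total_annotated for g in ("g1", "g2")]
        assert pool.pool_total < sum(totals)
        # disjoint repertoires: equality
        records = [rec("g1", "a.1.1"), rec("g2", "c.1.1")]
        m = build_census(records, [genome("g1"), genome("g2")])
        pool = pool_summary(m, None, mini_scheme)
        totals = [profile_genome(m, g, mini_scheme).total_annotated for g in ("g1", "g2")]
        assert pool.pool_total == sum(totals)

    def test_published_pool_statistics(self, scheme):
        pool = scheme_pool(scheme)
        assert pool.general_counts == {
            "Metabolism": 533,
            "General": 131,
            "Information": 201,
            "Other": 273,
            "Extracellular processes": 95,
            "Intracellular processes": 208,
            "Regulation": 205,
        }
        gp = pool.general_percent()
        assert round2(gp["Extracellular processes"]) == 5.77
        assert round2(pool.minor_percent()["Viral proteins"]) == 4.43


class TestGroupProfiles:
    def _profiles(self, counts):
        return [
            FunctionalProfile(g, {"Metabolism": c}, {"Energy": c}, c)
            for g, c in counts.items()
        ]

    def test_single_member_groups_echo_values(self):
        profiles = self._profiles({"g1": 100, "g2": 300})
        genomes = [genome("g1", sk="Archaea"), genome("g2", sk="Bacteria")]
        gm = group_profiles(profiles, genomes, "superkingdom")
        assert gm["Archaea"].mean_general_counts["Metabolism"] == 100
        assert gm["Bacteria"].mean_general_counts["Metabolism"] == 300

    def test_two_member_mean(self):
        profiles = self._profiles({"g1": 100, "g2": 300})
        genomes = [genome("g1"), genome("g2")]
        gm = group_profiles(profiles, genomes, "superkingdom")
        assert gm["Bacteria"].mean_general_counts["Metabolism"] == 200
        assert gm["Bacteria"].n_genomes == 2

    def test_missing_metadata_rejected(self):
        profiles = self._profiles({"g1": 1})
        with pytest.raises(ValidationError):
            group_profiles(profiles, [], "superkingdom")

    def test_unknown_key_rejected(self):
        with pytest.raises(ValidationError):
            group_profiles([], [], "phylum")

    def test_generated_cohort_recovers_superkingdom_size_ordering(self, scheme):
        config = SyntheticConfig(
            seed=5,
            n_genomes={("Archaea", "FL"): 50, ("Bacteria", "FL"): 50, ("Eukarya", "FL"): 50},
        )
        cohort = generate_truth(config, scheme)
        gm = group_profiles(cohort.truth_profiles(), cohort.genomes, "superkingdom")
        assert (
            gm["Archaea"].mean_total_annotated
            < gm["Bacteria"].mean_total_annotated
            < gm["Eukarya"].mean_total_annotated
        )


class TestConservationInvariants:
    def test_counts_conserved_across_tiers(self, scheme):
        config = SyntheticConfig(seed=3, n_genomes={("Bacteria", "FL"): 20})
        cohort = generate_truth(config, scheme)
        for p in cohort.truth_profiles():
            assert sum(p.general_counts.values()) == p.total_annotated
            assert sum(p.minor_counts.values()) == p.total_annotated
            # each general equals the sum of its minors
            for g in p.general_counts:
                minors = [
                    m for m in p.minor_counts if scheme.minor_to_general[m] == g
                ]
                assert sum(p.minor_counts[m] for m in minors) == p.general_counts[g]


@pytest.mark.parametrize(
    "x,expected",
    [(32.375, 32.38), (32.384, 32.38), (7.9587, 7.96), (0.005, 0.01), (16.5856, 16.59)],
)
def test_round2_is_half_up(x, expected):
    assert round2(x) == expected
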