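"""Log-rescaling formula and Welch's unequal-variance ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from fsfcensus import (
    GenomeRecord,
    ValidationError,
    compare_superkingdoms,
    normalize_count,
    welch_anova,
)
from fsfcensus.profiles import FunctionalProfile
from fsfcensus.simulate import SyntheticConfig, generate_truth


class TestNormalizeCount:
    def test_fixed_points(self):
        assert normalize_count(350, 350) == pytest.approx(7.0)
        assert normalize_count(1, 5) == 0.0
        assert normalize_count(1, 2) == 0.0

    def test_hand_value(self):
        assert normalize_count(100, 1000) == pytest.approx(14.0 / 3.0, abs=1e-12)

    @pytest.mark.parametrize(
        "n_xy,n_max", [(0, 10), (5, 1), (11, 10), (-1, 10)]
    )
    def test_domain_errors(self, n_xy, n_max):
        with pytest.raises(ValidationError):
            normalize_count(n_xy, n_max)

    @given(
        n_max=st.integers(2, 10_000),
        pair=st.tuples(st.integers(1, 10_000), st.integers(1, 10_000)),
    )
    def test_strictly_increasing_and_bounded(self, n_max, pair):
        a, b = sorted(min(p, n_max) for p in pair)
        va, vb = normalize_count(a, n_max), normalize_count(b, n_max)
        assert 0.0 <= va <= vb <= 7.0
        if a < b:
            assert va < vb


@st.composite
def two_groups(draw):
    def group():
        n = draw(st.integers(3, 25))
        mu = draw(st.floats(-50, 50))
        sd = draw(st.floats(0.1, 10))
        seed = draw(st.integers(0, 2**31 - 1))
        return np.random.default_rng(seed).normal(mu, sd, n)

    return group(), group()


class TestWelchAnova:
    @given(two_groups())
    def test_two_groups_equal_welch_t_squared(self, groups):
        """Oracle: independently implemented Welch two-sample t-test."""
        a, b = groups
        res = welch_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=False)
        assert res.f_stat == pytest.approx(t.statistic**2, abs=1e-9, rel=1e-9)
        assert res.df_den == pytest.approx(t.df, abs=1e-9, rel=1e-9)
        assert res.p_value == pytest.approx(t.pvalue, abs=1e-9)

    def test_three_group_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        samples = [rng.normal(i, 1 + i, 25) for i in range(3)]
        df = pd.DataFrame(
            {
                "y": np.concatenate(samples),
                "g": np.repeat(["a", "b", "c"], 25),
            }
        )
        ref = pg.welch_anova(dv="y", between="g", data=df)
        res = welch_anova(samples)
        assert res.f_stat == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert res.df_den == pytest.approx(float(ref["ddof2"][0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)

    def test_null_case_jittered_constants(self):
        rng = np.random.default_rng(0)
        samples = [200.0 + rng.normal(0, 1e-6, 10) for _ in range(3)]
        res = welch_anova(samples)
        assert res.f_stat < 5
        assert res.p_value > 0.01
        assert res.df_num == 2

    @given(two_groups(), st.floats(-100, 100))
    def test_invariant_to_group_order_and_location_shift(self, groups, shift):
        a, b = groups
        res = welch_anova([a, b])
        flipped = welch_anova([b, a])
        shifted = welch_anova([a + shift, b + shift])
        assert res.f_stat == pytest.approx(flipped.f_stat, rel=1e-9, abs=1e-9)
        assert res.f_stat == pytest.approx(shifted.f_stat, rel=1e-6, abs=1e-6)

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(1)
        samples = [rng.normal(mu, 15, 50) for mu in (200, 260, 330)]
        assert welch_anova(samples).p_value < 1e-4

    @pytest.mark.parametrize(
        "samples",
        [
            [[1.0, 2.0]],  # one group
            [[1.0, 2.0], [3.0]],  # group of size 1
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],  # zero variance
        ],
    )
    def test_degenerate_inputs_rejected(self, samples):
        with pytest.raises(ValidationError):
            welch_anova(samples)


def _fl_cohort(seed=2):
    config = SyntheticConfig(
        seed=seed,
        n_genomes={
            ("Archaea", "FL"): 40,
            ("Bacteria", "FL"): 60,
            ("Eukarya", "FL"): 40,
        },
    )
    cohort = generate_truth(config)
    return cohort.truth_profiles(), cohort.genomes


class TestCompareSuperkingdoms:
    def test_planted_separation_significant_for_all_categories(self):
        profiles, genomes = _fl_cohort()
        for cat in ("Metabolism", "Information", "Regulation"):
            res = compare_superkingdoms(profiles, genomes, cat)
            assert res.p_value < 1e-4
            assert res.group_labels == ("Archaea", "Bacteria", "Eukarya")

    def test_raw_count_mode(self):
        profiles, genomes = _fl_cohort()
        res = compare_superkingdoms(profiles, genomes, "Metabolism", normalize=False)
        assert res.p_value < 1e-4

    def test_single_superkingdom_rejected(self):
        profiles = [
            FunctionalProfile(f"g{i}", {"Metabolism": 10 + i}, {"Energy": 10 + i}, 10 + i)
            for i in range(4)
        ]
        genomes = [GenomeRecord(f"g{i}", "Bacteria", "X", "FL") for i in range(4)]
        with pytest.raises(ValidationError):
            compare_superkingdoms(profiles, genomes, "Metabolism")

    def test_parasites_excluded_from_comparison(self):
        profiles, genomes = _fl_cohort()
        # relabel every Eukarya genome as parasitic: only A & B remain
        relabeled = [
            GenomeRecord(g.genome_id, g.superkingdom, g.group,
                         "OP" if g.superkingdom == "Eukarya" else g.lifestyle)
            for g in genomes
        ]
        res = compare_superkingdoms(profiles, relabeled, "Metabolism")
        assert res.group_labels == ("Archaea", "Bacteria")

    def test_permuted_labels_give_uniform_type_i_error(self):
        """Permutation null oracle: ~5% of label shuffles reach p < 0.05."""
        profiles, genomes = _fl_cohort(seed=9)
        sks = [g.superkingdom for g in genomes]
        rng = np.random.default_rng(123)
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = rng.permutation(sks)
            shuffled = [
                GenomeRecord(g.genome_id, sk, g.group, g.lifestyle)
                for g, sk in zip(genomes, perm)
            ]
            if compare_superkingdoms(profiles, shuffled, "Metabolism").p_value < 0.05:
                hits += 1
        assert 0.03 <= hits / n_perm <= 0.07
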