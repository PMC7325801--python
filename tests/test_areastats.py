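"""Area-level statistics: t-tests, conjunction, core classification, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdcore import (
    BetaTable,
    ValidationError,
    area_ttests,
    conjunction_extended_md,
    core_classification,
    hemisphere_average,
    merge_areas,
    split_half_profile_correlation,
    task_profiles,
)
from mdcore.areastats import one_sample_ttest

from conftest import random_beta_table


def table_from_columns(columns, hemispheres=None):
    """(areas, values-per-subject) dict -> single-contrast BetaTable."""
    areas = tuple(columns)
    beta = np.array([columns[a] for a in areas]).T[:, :, None]
    return BetaTable(
        beta=beta,
        subject_ids=tuple(f"s{i}" for i in range(beta.shape[0])),
        area_ids=areas,
        contrast_ids=("c0",),
        hemispheres=hemispheres,
    )


class TestHemisphereAverage:
    def test_arithmetic_mean_of_hemispheres(self):
        b = BetaTable(
            beta=np.array([[[1.0], [2.0]], [[1.0], [2.0]]]),
            subject_ids=("s0", "s1"),
            area_ids=("A", "A"),
            contrast_ids=("c0",),
            hemispheres=("L", "R"),
        )
        out = hemisphere_average(b)
        np.testing.assert_allclose(out.beta, 1.5)
        assert out.area_ids == ("A",) and out.hemispheres is None

    def test_commutes_with_subject_mean(self):
        rng = np.random.default_rng(0)
        b = random_beta_table(rng, hemispheres=True)
        avg_then_mean = hemisphere_average(b).beta.mean(axis=0)
        n = len(set(b.area_ids))
        mean = b.beta.mean(axis=0)
        mean_then_avg = 0.5 * (mean[:n] + mean[n:])
        np.testing.assert_allclose(avg_then_mean, mean_then_avg, atol=1e-12)

    def test_unpaired_area_raises_naming_the_area(self):
        b = random_beta_table(np.random.default_rng(1), hemispheres=True)
        b2 = BetaTable(
            beta=b.beta[:, :-1, :],
            subject_ids=b.subject_ids,
            area_ids=b.area_ids[:-1],
            contrast_ids=b.contrast_ids,
            hemispheres=b.hemispheres[:-1],
        )
        with pytest.raises(ValidationError, match="A4"):
            hemisphere_average(b2)


class TestAreaTTests:
    def test_closed_form_t_and_p(self):
        b = table_from_columns({"A": [0.5, 1.5, 1.0, 1.0]})
        (s,) = area_ttests(b, "c0", m=1)
        assert s.t == pytest.approx(4.898979, abs=1e-5)
        assert s.df == 3
        assert s.p == pytest.approx(0.01628, abs=2e-4)

    def test_zero_betas_not_significant(self):
        b = table_from_columns({"A": [0.0, 0.0, 0.0]})
        (s,) = area_ttests(b, "c0", m=1)
        assert s.t == 0.0 and not s.significant_positive and s.degenerate

    def test_negative_mean_never_significant_positive(self):
        b = table_from_columns({"A": [-1.0, -2.0, -1.5, -1.5]})
        (s,) = area_ttests(b, "c0", m=1)
        assert s.p < 0.05 and not s.significant_positive

    def test_agrees_with_two_pass_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        b = random_beta_table(rng, n_subjects=9, n_areas=12, n_contrasts=1)
        for s in area_ttests(b, "c0", m=12):
            x = b.beta[:, b.area_ids.index(s.area_id), 0]
            mean = sum(x) / len(x)
            sd = (sum((v - mean) ** 2 for v in x) / (len(x) - 1)) ** 0.5
            t_oracle = mean / (sd / len(x) ** 0.5)
            assert abs(s.t - t_oracle) < 1e-10

    def test_bonferroni_m_must_cover_areas(self):
        b = random_beta_table(np.random.default_rng(2), n_areas=5, n_contrasts=1)
        with pytest.raises(ValidationError, match="Bonferroni"):
            area_ttests(b, "c0", m=3)


class TestConjunction:
    @staticmethod
    def _stats(sig_areas, universe):
        from mdcore.areastats import AreaStat

        return [
            AreaStat(area_id=a, mean_beta=1.0, t=5.0, df=10, p=0.001,
                     significant_positive=a in sig_areas)
            for a in universe
        ]

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(3)
        universe = [f"A{i}" for i in range(30)]
        sig = {c: {a for a in universe if rng.random() < 0.5} for c in "xyz"}
        stats = {c: self._stats(sig[c], universe) for c in "xyz"}
        part = conjunction_extended_md(stats)
        assert part.extended_set == sig["x"] & sig["y"] & sig["z"]

    def test_area_significant_in_two_of_three_excluded(self):
        universe = ["A"]
        stats = {
            "c1": self._stats({"A"}, universe),
            "c2": self._stats(set(), universe),
            "c3": self._stats({"A"}, universe),
        }
        assert conjunction_extended_md(stats).extended_set == frozenset()

    def test_mismatched_universes_rejected(self):
        stats = {
            "c1": self._stats(set(), ["A", "B"]),
            "c2": self._stats(set(), ["A"]),
        }
        with pytest.raises(ValidationError, match="universe"):
            conjunction_extended_md(stats)

    def test_bonferroni_monotonicity_in_alpha(self, default_betas):
        from mdcore import extended_md_pipeline

        _, _, strict = extended_md_pipeline(default_betas, alpha=0.01)
        _, _, loose = extended_md_pipeline(default_betas, alpha=0.10)
        assert strict.extended_set <= loose.extended_set

    def test_conjunction_subset_of_each_contrast(self, default_partition):
        _, stats, extended, _ = default_partition
        for c, per_area in extended.stats.items():
            sig = {a for a, s in per_area.items() if s.significant_positive}
            assert extended.extended_set <= sig


class TestCoreClassification:
    def test_hand_computed_example(self):
        b = table_from_columns({
            "A": [2.0, 2.1, 1.9],
            "B": [1.0, 1.0, 1.0],
            "C": [0.0, -0.1, 0.1],
        })
        part = core_classification(b, {"A", "B", "C"}, alpha=0.05)
        sa = part.stats["c0"]["A"]
        assert sa.t == pytest.approx(17.3205, abs=1e-3)
        assert sa.significant_positive
        assert part.stats["c0"]["B"].t == pytest.approx(0.0, abs=1e-12)
        assert part.stats["c0"]["C"].mean_beta < 0
        assert part.core_full_set == frozenset({"A"})

    def test_identical_areas_give_empty_core(self):
        b = table_from_columns({"A": [1.0, 2.0], "B": [1.0, 2.0], "C": [1.0, 2.0]})
        part = core_classification(b, {"A", "B", "C"})
        assert not part.core_set

    def test_invariant_to_per_subject_offsets(self):
        rng = np.random.default_rng(5)
        b = random_beta_table(rng, n_subjects=8, n_areas=6)
        offsets = rng.normal(size=(8, 1, 1)) * 10
        shifted = BetaTable(
            beta=b.beta + offsets, subject_ids=b.subject_ids,
            area_ids=b.area_ids, contrast_ids=b.contrast_ids,
        )
        p1 = core_classification(b, set(b.area_ids))
        p2 = core_classification(shifted, set(b.area_ids))
        assert p1.core_full_set == p2.core_full_set
        assert p1.core_partial_set == p2.core_partial_set
        for c in b.contrast_ids:
            for a in b.area_ids:
                assert p1.stats[c][a].t == pytest.approx(p2.stats[c][a].t, abs=1e-8)

    def test_recovers_planted_core_split(self, default_config, default_partition):
        _, _, _, core = default_partition
        truth = default_config.ground_truth
        assert core.core_full_set == truth.core_full_set
        assert core.core_partial_set == truth.core_partial_set
        assert core.penumbra_set == truth.penumbra_set

    def test_too_small_extended_set_rejected(self):
        b = table_from_columns({"A": [1.0, 2.0], "B": [0.0, 1.0]})
        with pytest.raises(ValidationError, match=">= 2"):
            core_classification(b, {"A"})


class TestMergeAreas:
    def test_equal_weight_mean(self):
        b = table_from_columns({"A": [1.0, 1.0], "B": [3.0, 3.0]})
        out = merge_areas(b, ["A", "B"])
        np.testing.assert_allclose(out.beta[:, -1, 0], 2.0)
        assert out.area_ids == ("A+B",)

    def test_single_area_identity(self):
        b = table_from_columns({"A": [1.0, 2.0], "B": [0.0, 0.0]})
        out = merge_areas(b, ["A"], merged_id="A")
        np.testing.assert_allclose(out.beta[:, -1, 0], [1.0, 2.0])

    def test_weighted_mean(self):
        b = table_from_columns({"A": [4.0, 4.0], "B": [0.0, 0.0]})
        out = merge_areas(b, ["A", "B"], weights=[0.75, 0.25])
        np.testing.assert_allclose(out.beta[:, -1, 0], 3.0)

    def test_empty_list_rejected(self):
        b = table_from_columns({"A": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="empty"):
            merge_areas(b, [])


class TestTaskProfiles:
    def test_z_scores_with_sample_sd(self):
        b = BetaTable(
            beta=np.array([[[1.0], [2.0], [3.0]]] * 2),
            subject_ids=("s0", "s1"),
            area_ids=("A", "B", "C"),
            contrast_ids=("c0",),
        )
        prof = task_profiles(b, {"A", "B", "C"})
        np.testing.assert_allclose(prof.zbar[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_zbar_columns_mean_zero(self, default_partition, default_config):
        avg, _, extended, _ = default_partition
        prof = task_profiles(avg, extended.extended_set)
        np.testing.assert_allclose(prof.zbar.mean(axis=0), 0.0, atol=1e-12)

    def test_identical_z_across_contrasts_gives_zero_sd(self):
        base = np.array([[1.0, 2.0, 3.0], [0.0, 1.0, 5.0]])
        beta = np.stack([base, 2 * base, 3 * base], axis=2)  # same z per contrast
        b = BetaTable(
            beta=beta, subject_ids=("s0", "s1"),
            area_ids=("A", "B", "C"), contrast_ids=("c0", "c1", "c2"),
        )
        prof = task_profiles(b, {"A", "B", "C"})
        np.testing.assert_allclose(prof.sd_between_tasks, 0.0, atol=1e-12)

    def test_degenerate_subject_named(self):
        b = BetaTable(
            beta=np.array([[[1.0], [1.0], [1.0]], [[1.0], [2.0], [3.0]]]),
            subject_ids=("flat", "ok"),
            area_ids=("A", "B", "C"),
            contrast_ids=("c0",),
        )
        with pytest.raises(ValidationError, match="flat"):
            task_profiles(b, {"A", "B", "C"})


class TestSplitHalfProfiles:
    def test_identical_groups_give_unit_diagonal(self):
        rng = np.random.default_rng(8)
        half = rng.normal(size=(4, 6, 3)) + np.arange(6)[None, :, None]
        b = BetaTable(
            beta=np.concatenate([half, half], axis=0),
            subject_ids=tuple(f"s{i}" for i in range(8)),
            area_ids=tuple(f"A{i}" for i in range(6)),
            contrast_ids=("c0", "c1", "c2"),
        )
        split = np.array([True] * 4 + [False] * 4)
        corr = split_half_profile_correlation(b, set(b.area_ids), split)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-12)

    def test_negated_group_gives_negative_diagonal(self):
        rng = np.random.default_rng(9)
        half = rng.normal(size=(4, 6, 3))
        centered = half - half.mean(axis=1, keepdims=True)
        b = BetaTable(
            beta=np.concatenate([centered, -centered], axis=0),
            subject_ids=tuple(f"s{i}" for i in range(8)),
            area_ids=tuple(f"A{i}" for i in range(6)),
            contrast_ids=("c0", "c1", "c2"),
        )
        split = np.array([True] * 4 + [False] * 4)
        corr = split_half_profile_correlation(b, set(b.area_ids), split)
        np.testing.assert_allclose(np.diag(corr), -1.0, atol=1e-12)

    def test_diagonal_dominance_on_planted_heterogeneity(self, default_partition):
        avg, _, extended, _ = default_partition
        rng = np.random.default_rng(0)
        split = np.zeros(avg.n_subjects, dtype=bool)
        split[rng.permutation(avg.n_subjects)[: avg.n_subjects // 2]] = True
        corr = split_half_profile_correlation(avg, extended.extended_set, split)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.diag(corr).mean() > off.mean()


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(-10, 10), min_size=3, max_size=12))
def test_ttest_matches_scipy(values):
    from scipy import stats as sps

    x = np.asarray(values)
    t, df, p, degen = one_sample_ttest(x)
    if degen:
        assert x.std(ddof=1) == 0.0
    else:
        ref = sps.ttest_1samp(x, 0.0)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)
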