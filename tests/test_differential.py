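from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from core_responder import differential as diff
from core_responder import synthetic_data as syn


def rank_sum_oracle(x, y):
    """Brute-force two-sided rank-sum p: enumerate every group assignment."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = stats.rankdata(pooled)
    n, n1 = len(pooled), len(x)
    w_obs = ranks[:n1].sum()
    mu = ranks.sum() * n1 / n
    hits = total = 0
    for combo in combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxonRankSum:
    def test_separated_groups_exact(self):
        p = diff.wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8])
        assert p == pytest.approx(2 / 70)

    def test_identical_multisets(self):
        assert diff.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0

    def test_all_constant(self):
        assert diff.wilcoxon_rank_sum([5, 5], [5, 5]) == 1.0

    def test_too_small_group(self):
        with pytest.raises(ValueError, match="at least 2"):
            diff.wilcoxon_rank_sum([1], [2, 3])

    def test_symmetry(self):
        x, y = [1.5, 2.2, 0.3, 4.0], [2.0, 0.1, 3.3, 1.1]
        assert diff.wilcoxon_rank_sum(x, y) == pytest.approx(diff.wilcoxon_rank_sum(y, x))

    @settings(max_examples=150, deadline=None)
    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=6),
        st.lists(st.integers(0, 8), min_size=2, max_size=6),
    )
    def test_matches_enumeration_oracle(self, x, y):
        assert diff.wilcoxon_rank_sum(x, y) == pytest.approx(rank_sum_oracle(x, y))

    def test_large_sample_close_to_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=12), rng.normal(0.8, size=12)
        ours = diff.wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)


class TestWelch:
    def test_mirrored_samples(self):
        assert diff.welch_t_test([-2, -1, 1, 2], [-2, -1, 1, 2]) == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        # x=(1..5), y=(2,4,..,10): t=-1.897366596, df=5.882352941
        p = diff.welch_t_test([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert p == pytest.approx(0.10753119493062728, abs=1e-12)

    def test_swap_invariance(self):
        x, y = [1.0, 2.5, 3.1], [0.5, 4.2, 2.2, 1.9]
        assert diff.welch_t_test(x, y) == pytest.approx(diff.welch_t_test(y, x))

    def test_zero_variance_both(self):
        assert diff.welch_t_test([3, 3], [3, 3]) == 1.0
        assert diff.welch_t_test([3, 3], [4, 4]) == 0.0


class TestFoldChange:
    def test_equal_means(self):
        assert diff.fold_change(0.1, 0.1) == pytest.approx(1.0)

    def test_double(self):
        assert diff.fold_change(0.2, 0.1) == pytest.approx(2.0, rel=1e-4)

    def test_both_zero(self):
        assert diff.fold_change(0.0, 0.0) == pytest.approx(1.0)


def _planted_dataset(seed=0, fold=3.0, n_affected=6, group_differential=1.0):
    spec0 = syn.SyntheticSpec(seed=seed, depth_range=(10_000, 10_000))
    elig = syn.eligible_planted_taxa(spec0, 0.003)
    planted = tuple(elig[5:15])
    ecos = spec0.ecotype_names()
    affected = tuple(ecos[1 : 1 + n_affected // 2] + ecos[6 : 6 + n_affected - n_affected // 2])
    spec = syn.SyntheticSpec(
        seed=seed,
        depth_range=(10_000, 10_000),
        group_differential=group_differential,
        planted_effects=(syn.PlantedEffect(planted, affected, fold, "enriched"),),
    )
    return syn.generate_community(spec)


class TestPerEcotypeDA:
    def test_planted_taxon_called_enriched(self):
        table, design, truth, _ = _planted_dataset(seed=1)
        eco = truth.affected_ecotypes[truth.core_taxa()[0]][0]
        da = diff.per_ecotype_da(table, design, eco)
        hits = da[da["taxon"].isin(truth.core_taxa()) & da["significant"]]
        assert (hits["direction"] == "enriched").all()
        assert len(hits) >= 8

    def test_abundance_threshold_excludes(self, small_design):
        import pandas as pd

        from core_responder.io_model import RelativeAbundanceTable

        values = np.tile([0.0005, 0.9995], (8, 1))
        values[::2, 0] = 0.0004  # taxon t1 mean abundance 0.00045 < 0.001
        values[:, 1] = 1 - values[:, 0]
        rel = RelativeAbundanceTable(small_design.sample_ids, ["t1", "t2"], values)
        da = diff.per_ecotype_da(rel, small_design, "E01")
        assert "t1" not in set(da["taxon"])

    def test_missing_treatment_errors(self, small_design):
        table, design, _, _ = _planted_dataset()
        with pytest.raises(ValueError, match="E99"):
            diff.per_ecotype_da(table, design, "E99")

    def test_type_i_rate_near_alpha_with_8v8(self):
        # 8v8 replicates so the discrete null can reach sizes near 0.05
        rng = np.random.default_rng(99)
        rejections = trials = 0
        for _ in range(40):
            x = rng.lognormal(size=(16, 30))
            for j in range(30):
                p = diff.wilcoxon_rank_sum(x[:8, j], x[8:, j])
                rejections += p < 0.05
                trials += 1
        assert 0.03 <= rejections / trials <= 0.07


class TestCoreCall:
    @staticmethod
    def _da_frame(rows):
        import pandas as pd

        return pd.DataFrame(
            rows,
            columns=["ecotype", "taxon", "mean_drought", "mean_control", "p", "fold",
                     "direction", "significant"],
        )

    def _row(self, eco, taxon, fold, sig):
        direction = "enriched" if fold >= 1 else "depleted"
        return (eco, taxon, 0.1, 0.1, 0.01 if sig else 0.5, fold, direction, sig)

    def test_six_of_ten_is_core(self):
        rows = [self._row(f"E{i:02d}", "tA", 1.5 if i <= 6 else 1.0, i <= 6) for i in range(1, 11)]
        core = diff.call_core_responsive(self._da_frame(rows))
        assert core.loc[core["taxon"] == "tA", "status"].item() == "core_enriched"

    def test_four_of_ten_is_none(self):
        rows = [self._row(f"E{i:02d}", "tA", 1.5 if i <= 4 else 1.0, i <= 4) for i in range(1, 11)]
        core = diff.call_core_responsive(self._da_frame(rows))
        assert core.loc[core["taxon"] == "tA", "status"].item() == "none"

    def test_fold_threshold_required(self):
        # significant but folds below 1.2 never count
        rows = [self._row(f"E{i:02d}", "tA", 1.1, True) for i in range(1, 11)]
        core = diff.call_core_responsive(self._da_frame(rows))
        assert core.loc[core["taxon"] == "tA", "status"].item() == "none"

    def test_depletion_symmetric(self):
        rows = [self._row(f"E{i:02d}", "tA", 0.5 if i <= 5 else 1.0, i <= 5) for i in range(1, 11)]
        core = diff.call_core_responsive(self._da_frame(rows))
        assert core.loc[core["taxon"] == "tA", "status"].item() == "core_depleted"

    def test_monotone_in_extra_ecotype(self):
        # adding one more qualifying ecotype never revokes core status
        base = [self._row(f"E{i:02d}", "tA", 1.5 if i <= 5 else 1.0, i <= 5) for i in range(1, 11)]
        more = [self._row(f"E{i:02d}", "tA", 1.5 if i <= 6 else 1.0, i <= 6) for i in range(1, 11)]
        s1 = diff.call_core_responsive(self._da_frame(base))["status"].item()
        s2 = diff.call_core_responsive(self._da_frame(more))["status"].item()
        assert s1 == "core_enriched" and s2 == "core_enriched"

    def test_too_few_ecotypes(self):
        rows = [self._row("E01", "tA", 1.5, True)]
        with pytest.raises(ValueError, match="ecotypes"):
            diff.call_core_responsive(self._da_frame(rows))


class TestGroupFoldContrast:
    def test_higher_in_tolerant(self):
        table, design, truth, _ = _planted_dataset(seed=3, group_differential=1.5)
        da = diff.da_all_ecotypes(table, design)
        core = diff.call_core_responsive(da)
        contrast = diff.group_fold_contrast(core, diff.fold_matrix(da), design)
        planted = contrast[contrast["taxon"].isin(truth.core_taxa())]
        assert len(planted) > 0
        assert (planted["group_contrast"] == "higher_in_tolerant").all()

    def test_equal_means_tie_label(self):
        import pandas as pd

        core = pd.DataFrame(
            {"taxon": ["tA"], "status": ["core_enriched"], "cluster": ["cluster1"],
             "n_ecotypes_tested": [2], "n_ecotypes_enriched": [2], "n_ecotypes_depleted": [0]}
        )
        folds = pd.DataFrame({"E01": [2.0], "E02": [2.0]}, index=["tA"])
        folds.index.name = "taxon"
        rows = []
        ids = []
        for eco, tol in (("E01", "tolerant"), ("E02", "sensitive")):
            for treatment in ("control", "drought"):
                for rep in (1, 2):
                    ids.append(f"{eco}.{treatment}.{rep}")
                    rows.append({"ecotype": eco, "treatment": treatment,
                                 "tolerance_class": tol, "replicate": rep})
        from core_responder.io_model import StudyDesign

        design = StudyDesign(__import__("pandas").DataFrame(rows, index=ids))
        out = diff.group_fold_contrast(core, folds, design)
        assert out["group_contrast"].item() == "equal"
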