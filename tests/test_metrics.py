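"""Group discrimination, randomization null, cutoffs, effect size, power, R²."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import peakcv as pc
from peakcv.loocv import LoocvScores

from conftest import make_table


def scores_from_values(target_vals, other_vals, target="case", other="control"):
    frame = pd.DataFrame({
        "true_group": [target] * len(target_vals) + [other] * len(other_vals),
        "n_rules": 10,
        "pct_target": list(target_vals) + list(other_vals),
    }, index=[f"s{i}" for i in range(len(target_vals) + len(other_vals))])
    return LoocvScores(scores=frame, target_group=target, other_group=other)


class TestGroupDiscriminationP:
    def test_identical_groups_half(self):
        sc = scores_from_values([50, 60, 70], [50, 60, 70])
        assert pc.group_discrimination_p(sc) == pytest.approx(0.5)

    def test_matches_welch_oracle(self):
        sc = scores_from_values([58, 60, 57], [40, 39, 41])
        t, p_two = stats.ttest_ind([58, 60, 57], [40, 39, 41], equal_var=False)
        assert pc.group_discrimination_p(sc) == pytest.approx(p_two / 2.0, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            pc.group_discrimination_p(scores_from_values([50.0], [40, 41]))


class TestRandomizeLabels:
    def test_sizes_preserved_and_reproducible(self, small_table):
        r1 = pc.randomize_labels(small_table, seed=42)
        r2 = pc.randomize_labels(small_table, seed=42)
        assert r1.group_sizes() == small_table.group_sizes()
        assert (r1.samples["group"] == r2.samples["group"]).all()
        r3 = pc.randomize_labels(small_table, seed=43)
        assert not (r1.samples["group"] == r3.samples["group"]).all()

    def test_uniform_over_size_preserving_patterns(self):
        # 4v4 cohort: C(8,4) = 70 equally likely label patterns
        table = make_table(np.ones((8, 3)) + np.arange(8)[:, None], 4, 4)
        patterns = ["".join(p) for p in itertools.combinations("01234567", 4)]
        counts = dict.fromkeys(patterns, 0)
        rng = np.random.default_rng(123)
        n_draws = 10_000
        for _ in range(n_draws):
            labels = pc.randomize_labels(table, rng).samples["group"].to_numpy()
            key = "".join(str(i) for i in np.flatnonzero(labels == "case"))
            counts[key] += 1
        observed = np.array([counts[p] for p in patterns])
        assert observed.sum() == n_draws
        chi2 = ((observed - n_draws / 70) ** 2 / (n_draws / 70)).sum()
        # 69 df; 99.9% quantile ~ 111
        assert chi2 < stats.chi2.ppf(0.999, 69)

    def test_age_stratified_permutes_within_bins(self):
        table = make_table(np.ones((8, 3)) + np.arange(8)[:, None], 4, 4)
        table.samples["age"] = [25, 25, 25, 25, 55, 55, 55, 55]
        for seed in range(20):
            shuffled = pc.randomize_labels(table, seed, age_bins=[40.0])
            for lo, hi in [(0, 4), (4, 8)]:
                orig = sorted(table.samples["group"].iloc[lo:hi])
                new = sorted(shuffled.samples["group"].iloc[lo:hi])
                assert orig == new


class TestRandomizationTest:
    def test_true_p_beats_randomized_on_separated_cohorts(self):
        wins = 0
        n_seeds = 20
        for s in range(n_seeds):
            table = pc.simulate_table(pc.SimConfig(
                n_group_a=8, n_group_b=8, mz_min=400, mz_max=599,
                n_discriminatory=60, effect_delta=2.0, seed=s,
            ))
            cfg = pc.LoocvConfig(target_group="case")
            p_true = pc.group_discrimination_p(pc.run_loocv(table, cfg))
            p_rand = pc.randomization_test(
                table, cfg, pc.MetricsConfig(seed=s)
            )[0]
            wins += p_true < p_rand
        assert wins >= int(0.95 * n_seeds)

    def test_null_true_and_randomized_p_exchangeable(self):
        # under the global null the true labels are themselves a random
        # assignment, so true-label and randomized-label p-values must be
        # drawn from the same distribution
        p_true, p_rand = [], []
        for s in range(60):
            table = pc.simulate_table(pc.SimConfig(
                n_group_a=6, n_group_b=6, mz_min=400, mz_max=599,
                n_discriminatory=0, effect_delta=0.0, seed=s,
            ))
            cfg = pc.LoocvConfig(target_group="case")
            p_true.append(pc.group_discrimination_p(pc.run_loocv(table, cfg)))
            p_rand.append(pc.randomization_test(table, cfg, pc.MetricsConfig(seed=s))[0])
        ks = stats.ks_2samp(p_true, p_rand)
        assert ks.pvalue > 0.01


class TestCutoffAndConfusion:
    def test_cutoff_arithmetic_from_printed_row(self):
        # means 58.16/39.87, SDs 4.24/3.80, k = 2.28
        rng = np.random.default_rng(0)
        sc = scores_from_values(
            58.16 + 4.24 * _std_normals(rng, 21), 39.87 + 3.80 * _std_normals(rng, 20)
        )
        cut = pc.classification_cutoff(sc, pc.MetricsConfig(sd_multiplier=2.28))
        cand_high = 58.16 - 2.28 * 4.24
        cand_low = 39.87 + 2.28 * 3.80
        assert cand_high == pytest.approx(48.49, abs=0.01)
        assert cand_low == pytest.approx(48.53, abs=0.01)
        assert cut == pytest.approx(48.51, abs=0.01)

    def test_k_zero_is_midpoint_of_means(self):
        sc = scores_from_values([60, 62], [40, 42])
        assert pc.classification_cutoff(
            sc, pc.MetricsConfig(sd_multiplier=0.0)
        ) == pytest.approx((61 + 41) / 2)

    def test_equal_distributions_give_shared_mean(self):
        sc = scores_from_values([48, 50, 52], [48, 50, 52])
        assert pc.classification_cutoff(
            sc, pc.MetricsConfig(sd_multiplier=2.28)
        ) == pytest.approx(50.0)

    def test_perfect_confusion_counts(self):
        rng = np.random.default_rng(1)
        sc = scores_from_values(
            55 + 2 * _std_normals(rng, 21), 42 + 2 * _std_normals(rng, 20)
        )
        tm = pc.compute_test_metrics(sc, cutoff=48.5)
        assert (tm.counts.tp, tm.counts.tn, tm.counts.fp, tm.counts.fn) == (21, 20, 0, 0)
        assert tm.sensitivity == 1.0 and tm.specificity == 1.0

    def test_all_misclassified(self):
        sc = scores_from_values([10, 20], [80, 90])
        tm = pc.compute_test_metrics(sc, cutoff=50.0)
        assert tm.sensitivity == 0.0 and tm.specificity == 0.0

    def test_counting_oracle(self):
        rng = np.random.default_rng(2)
        t_vals = rng.uniform(0, 100, size=9)
        o_vals = rng.uniform(0, 100, size=7)
        cut = float(rng.uniform(0, 100))
        tm = pc.compute_test_metrics(scores_from_values(t_vals, o_vals), cut)
        assert tm.counts.tp == int(sum(v > cut for v in t_vals))
        assert tm.counts.tn == int(sum(v <= cut for v in o_vals))
        assert tm.counts.n_positive == 9 and tm.counts.n_negative == 7


class TestCohensD:
    def test_equal_means_zero_and_antisymmetry(self):
        assert pc.cohens_d(5, 1, 10, 5, 2, 10) == 0.0
        d = pc.cohens_d(58.16, 4.24, 21, 39.87, 3.80, 20)
        assert pc.cohens_d(39.87, 3.80, 20, 58.16, 4.24, 21) == pytest.approx(-d)

    def test_zero_sds_rejected(self):
        with pytest.raises(ValueError):
            pc.cohens_d(5, 0, 10, 4, 0, 10)


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert pc.power_from_d(0.0, 20, 20, alpha=0.05) == pytest.approx(0.05)

    def test_matches_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        for d, n1, n2 in [(0.5, 20, 20), (1.0, 15, 12), (2.0, 8, 10)]:
            ref = TTestIndPower().power(
                effect_size=d, nobs1=n1, ratio=n2 / n1, alpha=0.05,
                alternative="two-sided",
            )
            assert pc.power_from_d(d, n1, n2) == pytest.approx(ref, rel=1e-6)

    def test_matches_monte_carlo(self):
        # d = 1.0, n = 20/20: simulate two-sample t tests at the true effect
        rng = np.random.default_rng(5)
        n_rep = 4000
        xa = rng.normal(0.0, 1.0, size=(n_rep, 20))
        xb = rng.normal(1.0, 1.0, size=(n_rep, 20))
        p = stats.ttest_ind(xa, xb, axis=1).pvalue
        mc = (p < 0.05).mean()
        mc_err = np.sqrt(mc * (1 - mc) / n_rep)
        assert abs(pc.power_from_d(1.0, 20, 20) - mc) <= 3 * mc_err

    def test_monotone_in_d_n_alpha(self):
        grid = [pc.power_from_d(d, 10, 10) for d in (0.2, 0.5, 1.0, 2.0)]
        assert grid == sorted(grid)
        assert pc.power_from_d(1.0, 30, 30) > pc.power_from_d(1.0, 10, 10)
        assert pc.power_from_d(1.0, 10, 10, alpha=0.10) > pc.power_from_d(1.0, 10, 10)


class TestCovariateR2:
    def test_covariate_equal_to_scores(self):
        sc = scores_from_values([50, 60, 70], [30, 20, 10])
        sc.scores["covariate:x"] = sc.scores["pct_target"]
        assert pc.covariate_r2(sc, "covariate:x") == pytest.approx(1.0)

    def test_orthogonal_covariate(self):
        sc = scores_from_values([40, 50, 60], [40, 50, 60])
        sc.scores["covariate:x"] = [1, 0, -1, -1, 0, 1]
        assert pc.covariate_r2(sc, "covariate:x") == pytest.approx(0.0, abs=1e-12)

    def test_corr_squared_oracle(self):
        rng = np.random.default_rng(3)
        sc = scores_from_values(rng.uniform(0, 100, 8), rng.uniform(0, 100, 8))
        x = rng.normal(size=16)
        sc.scores["age"] = x
        y = sc.scores["pct_target"].to_numpy()
        assert pc.covariate_r2(sc, "age") == pytest.approx(
            np.corrcoef(x, y)[0, 1] ** 2
        )

    def test_constant_covariate_rejected(self):
        sc = scores_from_values([50, 60], [30, 20])
        sc.scores["age"] = 40.0
        with pytest.raises(ValueError, match="constant"):
            pc.covariate_r2(sc, "age")


def _std_normals(rng, n):
    """Standardized normal draws: exact sample mean 0 and SD 1."""
    x = rng.normal(size=n)
    return (x - x.mean()) / x.std(ddof=1)
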