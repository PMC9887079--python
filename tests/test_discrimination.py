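"""Cohort statistics: ROC/AUC, Kruskal-Wallis, operating point, normality."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import bmgrowth as bg


def pair_count_auc(pos, neg):
    """Mann-Whitney oracle: (#concordant + 0.5*#tied) / (n_pos*n_neg)."""
    conc = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                conc += 1
            elif p == n:
                ties += 1
    return (conc + 0.5 * ties) / (len(pos) * len(neg))


def exhaustive_kw_permutation_p(values, n1):
    """Exact permutation p for the two-group H statistic by enumerating
    every assignment of n1 values to group one."""
    values = np.asarray(values, dtype=float)
    obs = stats.kruskal(values[:n1], values[n1:]).statistic
    count = total = 0
    for comb in itertools.combinations(range(values.size), n1):
        mask = np.zeros(values.size, dtype=bool)
        mask[list(comb)] = True
        h = stats.kruskal(values[mask], values[~mask]).statistic
        total += 1
        if h >= obs - 1e-12:
            count += 1
    return count / total


class TestRankAuc:
    def test_perfect_separation(self):
        auc, roc = bg.rank_auc([2.0, 3.0], [0.0, 1.0])
        assert auc == 1.0
        assert roc[0][1] == 0.0 and roc[-1][1] == 1.0

    def test_identical_distributions_are_chance(self):
        auc, _ = bg.rank_auc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert auc == pytest.approx(0.5)

    def test_matches_pair_count_oracle(self, rng):
        for _ in range(100):
            pos = rng.normal(0.5, 1.0, 15)
            neg = rng.normal(0.0, 1.0, 15)
            if rng.random() < 0.3:  # force ties sometimes
                pos = np.round(pos)
                neg = np.round(neg)
            auc, _ = bg.rank_auc(pos, neg)
            assert auc == pytest.approx(pair_count_auc(pos, neg), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        pos = rng.normal(1.0, 1.0, 20)
        neg = rng.normal(0.0, 1.0, 25)
        auc0, _ = bg.rank_auc(pos, neg)
        auc1, _ = bg.rank_auc(np.exp(pos), np.exp(neg))
        assert auc1 == pytest.approx(auc0, abs=1e-12)

    def test_swapping_groups_complements_auc(self, rng):
        a = rng.normal(0.3, 1.0, 12)
        b = rng.normal(0.0, 1.0, 17)
        assert bg.rank_auc(a, b)[0] + bg.rank_auc(b, a)[0] == pytest.approx(1.0)

    def test_roc_monotone_from_origin_to_one(self, rng):
        pos, neg = rng.normal(1, 1, 10), rng.normal(0, 1, 10)
        _, roc = bg.rank_auc(pos, neg)
        tpr = [p[1] for p in roc]
        fpr = [p[2] for p in roc]
        assert (tpr[0], fpr[0]) == (0.0, 0.0) and (tpr[-1], fpr[-1]) == (1.0, 1.0)
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bg.rank_auc([], [1.0])


class TestKruskalWallis:
    def test_identical_groups_are_null(self):
        stat, p = bg.kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert p > 0.5
        stat, p = bg.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert (stat, p) == (0.0, 1.0)

    def test_small_sample_enumeration_oracle(self):
        """At n=3+3 with complete separation the exact permutation p is 2/20;
        the chi-squared approximation is not valid at this size (it gives
        ~0.05), so only the oracle's own value is asserted here and the
        asymptotic agreement is checked at larger n below."""
        values = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        assert exhaustive_kw_permutation_p(values, 3) == pytest.approx(0.1)

    def test_chi2_p_matches_permutation_oracle_at_moderate_n(self):
        """Seeded 20,000-permutation oracle at n=12+12, mid-range effect:
        the chi-squared p agrees within 10% relative."""
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 1.0, 12)
        y = rng.normal(0.55, 1.0, 12)
        _, p_chi2 = bg.kruskal_wallis([x, y])
        pooled = np.concatenate([x, y])
        obs = stats.kruskal(x, y).statistic
        prng = np.random.default_rng(1)
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            perm = prng.permutation(pooled)
            if stats.kruskal(perm[:12], perm[12:]).statistic >= obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert p_chi2 == pytest.approx(p_perm, rel=0.10)

    def test_two_group_p_equals_mann_whitney(self, rng):
        """Tie-corrected two-group H is the square of the Mann-Whitney
        z-score, so the p-values coincide to 3 decimals (asymptotic, no
        continuity correction) on 100 random cohorts."""
        for _ in range(100):
            x = rng.normal(0, 1, rng.integers(8, 30))
            y = rng.normal(rng.uniform(0, 1), 1, rng.integers(8, 30))
            _, p_kw = bg.kruskal_wallis([x, y])
            p_mw = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            ).pvalue
            assert p_kw == pytest.approx(p_mw, abs=1e-3)

    def test_type_one_error_calibrated(self):
        """Empirical size at alpha=0.05 within [0.03, 0.07] over 2,000 null
        cohorts of the study's group sizes (60+41)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.normal(0, 1, 60)
            y = rng.normal(0, 1, 41)
            _, p = bg.kruskal_wallis([x, y])
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestOperatingPoint:
    def test_perfect_separation_hits_both_ones(self):
        _, roc = bg.rank_auc([2.0, 3.0], [0.0, 1.0])
        _, sens, spec = bg.optimal_operating_point(roc)
        assert sens == 1.0 and spec == 1.0

    def test_no_signal_bound(self):
        scores = list(range(10))
        _, roc = bg.rank_auc(scores[::2], scores[1::2])
        thr, sens, spec = bg.optimal_operating_point(roc)
        assert sens + spec - 1 <= 2 / 5

    def test_matches_exhaustive_threshold_sweep(self, rng):
        pos = list(rng.normal(0.7, 1.0, 5))
        neg = list(rng.normal(0.0, 1.0, 5))
        _, roc = bg.rank_auc(pos, neg)
        thr, sens, spec = bg.optimal_operating_point(roc)
        # brute force: J over every candidate cut between sorted scores
        best_j = -np.inf
        for cut in sorted(pos + neg) + [np.inf]:
            s = np.mean([p >= cut for p in pos])
            sp = np.mean([n < cut for n in neg])
            best_j = max(best_j, s + sp - 1)
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)


class TestNormalityCheck:
    def test_conservative_for_normal_data(self):
        """With the reference normal fitted to the sample, p-values are
        biased high for genuinely normal data, so they should essentially
        never be small."""
        rng = np.random.default_rng(5)
        ps = [bg.normality_check(rng.normal(0, 1, 1000)) for _ in range(50)]
        assert min(ps) > 0.05
        assert np.mean(ps) > 0.5

    def test_rejects_exponential_data(self):
        rng = np.random.default_rng(6)
        assert bg.normality_check(rng.exponential(1.0, 1000)) < 0.01

    def test_degenerate_branch(self):
        with pytest.warns(UserWarning):
            assert bg.normality_check([2.0] * 10) == 0.0

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            bg.normality_check([1.0, 2.0, 3.0])


class TestRunDiscrimination:
    @staticmethod
    def _toy_fits(beta_pd, beta_rn, subgroups=None):
        fits = []
        for i, beta in enumerate(list(beta_pd) + list(beta_rn)):
            label = "PD" if i < len(beta_pd) else "RN"
            series = bg.LesionSeries(
                f"L{i}", f"P{i}", (0.0, 3.0, 5.5),
                tuple(bg.vb_trajectory(
                    bg.VBParameters(0.5, 0.1, 0.0, 0.0), (0.0, 3.0, 5.5)
                )),
                label=label,
                subgroup=None if subgroups is None else subgroups[i],
            )
            fit = bg.FitResult(
                params=bg.VBParameters(0.5, 0.1, beta, 0.0),
                ratio_residual=0.0,
                bracket=(-5, 10),
                iterations=1,
                status="converged",
            )
            fits.append((series, fit))
        return fits

    def test_separated_cohort_gives_auc_one_and_significance(self):
        fits = self._toy_fits([0.1, 0.2, 0.3, 0.4, 0.5], [2.0, 2.1, 2.2, 2.3, 2.4])
        result = bg.run_discrimination(fits)
        assert result.auc == 1.0
        assert result.p_value < 0.05
        assert result.operating_point[1] == result.operating_point[2] == 1.0

    def test_permuted_labels_centre_auc_on_chance(self, default_cohort_fits):
        """Random label permutation destroys the signal: the permuted AUC
        distribution is centred on 0.5 (500 permutations)."""
        fits = [(s, f) for s, f in default_cohort_fits if f.converged]
        betas_rn = [f.params.beta for s, f in fits if s.label == "RN"]
        betas_pd = [f.params.beta for s, f in fits if s.label == "PD"]
        all_betas = np.array(betas_rn + betas_pd)
        n_rn = len(betas_rn)
        rng = np.random.default_rng(99)
        aucs = []
        for _ in range(500):
            perm = rng.permutation(all_betas)
            auc, _ = bg.rank_auc(perm[:n_rn], perm[n_rn:])
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_default_cohort_headline_direction(self, default_cohort_fits):
        """Calibrated default cohort: RN exponents exceed PD exponents with
        P < .001, and both rate orderings are exposed for inspection."""
        result = bg.run_discrimination(default_cohort_fits)
        assert result.beta_summary_rn["mean"] > result.beta_summary_pd["mean"]
        assert result.p_value < 0.001
        assert set(result.lambda_summary) == {"PD", "RN"}
        for grp in ("PD", "RN"):
            assert math.isfinite(result.lambda_summary[grp]["lambda1_mean"])
            assert math.isfinite(result.lambda_summary[grp]["lambda2_mean"])

    def test_strata_filter_and_bonferroni(self, default_cohort_fits):
        suite = bg.run_discrimination_suite(
            default_cohort_fits, strata=("all", "SRS", "FSRT", "WBRT")
        )
        for stratum, result in suite.items():
            if isinstance(result, bg.StratumError):
                continue
            assert result.p_adjusted == pytest.approx(
                min(1.0, result.p_value * 4)
            )
            assert result.subgroup_tag == stratum
        # subgroup memberships partition the SRS/FSRT axis
        all_res = suite["all"]
        if not isinstance(suite["SRS"], bg.StratumError) and not isinstance(
            suite["FSRT"], bg.StratumError
        ):
            assert (
                suite["SRS"].n_pd + suite["FSRT"].n_pd == all_res.n_pd
            )

    def test_empty_stratum_raises_named_error(self):
        fits = self._toy_fits([0.1, 0.2], [2.0, 2.1])
        with pytest.raises(bg.StratumError, match="WBRT"):
            bg.run_discrimination(fits, stratum="WBRT")

    def test_unlabelled_series_rejected(self):
        fits = self._toy_fits([0.1], [2.0])
        series = bg.LesionSeries("LX", "PX", (0, 1, 2), (1.0, 2.0, 4.0))
        fit = bg.fit_vb_exponent(series)
        with pytest.raises(ValueError, match="label"):
            bg.run_discrimination(fits + [(series, fit)])

    def test_robust_only_filters_lesions(self, default_cohort_fits):
        subset = default_cohort_fits[45:75]  # spans both label groups
        robustness = {}
        for i, (series, fit) in enumerate(subset):
            robustness[series.lesion_id] = bg.assess_robustness(
                series, n_reps=50, seed=i
            )
        result = bg.run_discrimination(
            subset,
            robust_only=True,
            robustness=robustness,
        )
        n_robust = sum(r.robust_by_mean for r in robustness.values())
        assert result.n_pd + result.n_rn == n_robust
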