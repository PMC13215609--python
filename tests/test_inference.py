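import numpy as np
import pandas as pd
import pytest

from chronomem import inference as inf
from chronomem import synthetic_behavior as sb
from chronomem.errors import ConfigError, DataError, SeparationError


def _trial_frame(rts, subject="s01"):
    n = len(rts)
    return pd.DataFrame(
        {
            "subject_id": subject,
            "group": 1,
            "block": 1,
            "trial_index": np.arange(1, n + 1),
            "image_id": [f"i{k}" for k in range(n)],
            "duration_ms": 500.0,
            "response": "long",
            "rt_ms": rts,
        }
    )


class TestRtFilter:
    def test_homogeneous_none_removed(self):
        rng = np.random.default_rng(0)
        trials = _trial_frame(np.exp(rng.uniform(6.0, 6.2, 100)))
        filtered, removed = inf.filter_rt_outliers(trials)
        assert len(filtered) == 100
        assert removed == {"s01": 0}

    def test_injected_outlier_exactly_removed(self):
        rng = np.random.default_rng(1)
        base = np.exp(rng.normal(6.2, 0.25, 200))
        trials = _trial_frame(base)
        log_rt = np.log(trials["rt_ms"])
        # place one trial 10 subject-sds above the subject log-mean
        idx = 57
        trials.loc[idx, "rt_ms"] = np.exp(log_rt.mean() + 10 * log_rt.std(ddof=1))
        filtered, removed = inf.filter_rt_outliers(trials)
        # z-score oracle on the contaminated distribution
        x = np.log(trials["rt_ms"].to_numpy())
        z = (x - x.mean()) / x.std(ddof=1)
        expect_removed = set(trials.index[np.abs(z) > 3])
        assert set(trials.index) - set(filtered["trial_index"].map(lambda i: i - 1)) == expect_removed
        assert removed["s01"] == len(expect_removed)
        assert idx in expect_removed

    def test_boundary_retained(self):
        x = np.array([0.0, 0.0, 1.0, -1.0, 3.0])  # last point at exactly 3 sd? construct directly
        trials = _trial_frame(np.exp(6 + x / 10))
        filtered, _ = inf.filter_rt_outliers(trials)
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.all(np.abs(z) <= 3)  # nothing beyond 3 sd in this frame
        assert len(filtered) == len(trials)

    def test_filtered_output_has_no_outliers_wrt_frozen_stats(self):
        rng = np.random.default_rng(2)
        rts = np.exp(rng.normal(6.2, 0.25, 500))
        rts[::50] *= 8.0
        trials = _trial_frame(rts)
        x = np.log(trials["rt_ms"].to_numpy())
        mu, sd = x.mean(), x.std(ddof=1)
        filtered, _ = inf.filter_rt_outliers(trials)
        z = (np.log(filtered["rt_ms"].to_numpy()) - mu) / sd
        assert np.all(np.abs(z) <= 3)

    def test_upper_tail_mode(self):
        rng = np.random.default_rng(3)
        base = np.exp(rng.normal(6.2, 0.25, 300))
        trials = _trial_frame(base)
        x = np.log(trials["rt_ms"])
        trials.loc[0, "rt_ms"] = np.exp(x.mean() - 10 * x.std(ddof=1))  # fast outlier
        both, _ = inf.filter_rt_outliers(trials, tail="both")
        upper, _ = inf.filter_rt_outliers(trials, tail="upper")
        assert len(both) < len(trials)
        assert len(upper) == len(trials)  # fast outlier survives upper-only mode

    def test_small_subject_skipped_with_warning(self, caplog):
        trials = _trial_frame(np.exp(np.array([5.0, 6.0, 20.0])))
        with caplog.at_level("WARNING"):
            filtered, removed = inf.filter_rt_outliers(trials)
        assert len(filtered) == 3
        assert removed == {"s01": 0}
        assert any("RT filter skipped" in r.message for r in caplog.records)

    def test_nonpositive_rt_raises(self):
        trials = _trial_frame(np.array([100.0, -5.0] + [200.0] * 10))
        with pytest.raises(DataError):
            inf.filter_rt_outliers(trials)

    def test_bad_tail_raises(self):
        with pytest.raises(ConfigError):
            inf.filter_rt_outliers(_trial_frame(np.full(20, 500.0)), tail="left")


class TestGlmm:
    def test_plain_logit_matches_statsmodels(self, slow_stimuli, slow_test_scores):
        import statsmodels.api as sm

        params = sb.ChoiceModelParams(beta_mem=1.0, beta_speed=-0.3)
        subs = [f"s{i}" for i in range(4)]
        trials = sb.simulate_bisection(subs, slow_stimuli, params, seed=5, n_blocks=1)
        fit = inf.fit_choice_glmm(
            trials, slow_test_scores, fixed=("memorability", "speed"), random=(), include_duration=True
        )
        X, names, y, _ = inf._design(trials, slow_test_scores, ("memorability", "speed"), True)
        sm_fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        for j, name in enumerate(names):
            assert fit.coefficients[name][0] == pytest.approx(sm_fit.params[j], abs=1e-6)
            assert fit.coefficients[name][1] == pytest.approx(sm_fit.bse[j], rel=1e-4)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-6)

    def test_zero_sds_reduce_to_plain_logit(self, slow_stimuli, slow_test_scores):
        params = sb.ChoiceModelParams(beta_mem=1.0)
        subs = [f"s{i}" for i in range(4)]
        trials = sb.simulate_bisection(subs, slow_stimuli, params, seed=6, n_blocks=1)
        mixed0 = inf.fit_choice_glmm(
            trials, slow_test_scores, fixed=("memorability",), random=("intercept", "speed"),
            fix_sds=(0.0, 0.0), include_duration=True,
        )
        plain = inf.fit_choice_glmm(
            trials, slow_test_scores, fixed=("memorability",), random=(), include_duration=True
        )
        for name in plain.coefficients:
            assert mixed0.coefficients[name][0] == pytest.approx(plain.coefficients[name][0], abs=1e-4)

    def test_constant_response_separation_error(self, slow_test_scores):
        trials = pd.DataFrame(
            {
                "subject_id": ["a"] * 10 + ["b"] * 10,
                "image_id": list(slow_test_scores["image_id"].head(10)) * 2,
                "duration_ms": 500.0,
                "response": "long",
            }
        )
        with pytest.raises(SeparationError):
            inf.fit_choice_glmm(trials, slow_test_scores, fixed=("memorability",), random=())

    def test_single_subject_rejected(self, slow_test_scores):
        trials = pd.DataFrame(
            {
                "subject_id": "only",
                "image_id": slow_test_scores["image_id"].head(10),
                "duration_ms": 500.0,
                "response": ["long", "short"] * 5,
            }
        )
        with pytest.raises(DataError):
            inf.fit_choice_glmm(trials, slow_test_scores, fixed=("memorability",), random=())

    def test_interaction_requires_main_effects(self, slow_stimuli, slow_test_scores):
        params = sb.ChoiceModelParams()
        trials = sb.simulate_bisection(["a", "b"], slow_stimuli, params, seed=1, n_blocks=1)
        with pytest.raises(ConfigError):
            inf.fit_choice_glmm(trials, slow_test_scores, fixed=("interaction",), random=())

    def test_recovery_mixed_model(self, slow_stimuli, slow_test_scores):
        # single-replicate sanity check; the 100-replicate version is in acceptance
        params = sb.ChoiceModelParams(
            beta_mem=1.2, beta_speed=-0.3, beta_interaction=0.5,
            sd_subject_intercept=0.5, sd_subject_speed_slope=0.2,
        )
        subs = [f"s{i:02d}" for i in range(20)]
        trials = sb.simulate_bisection(subs, slow_stimuli, params, seed=11)
        filtered, _ = inf.filter_rt_outliers(trials)
        fit = inf.fit_choice_glmm(filtered, slow_test_scores, include_duration=True)
        assert fit.converged
        assert fit.coefficients["memorability"][0] == pytest.approx(1.2, abs=0.25)
        assert fit.coefficients["speed"][0] < 0
        assert fit.coefficients["interaction"][0] > 0
        assert 0.2 < fit.random_effect_sds["intercept"] < 0.9


class TestLrTest:
    def _fit(self, loglik, terms, n_obs=100, random_terms=("intercept",)):
        coeffs = {t: (0.0, 1.0, 0.0) for t in terms}
        return inf.GlmmFit(
            coefficients=coeffs, random_effect_sds={t: 0.5 for t in random_terms},
            loglik=loglik, n_obs=n_obs, converged=True,
            fixed_terms=tuple(terms), random_terms=tuple(random_terms),
        )

    def test_equal_loglik_gives_null_result(self):
        # a dropped term that changes nothing: chi2 = 0, p = 1
        full = self._fit(-50.0, ["intercept", "memorability"])
        reduced = self._fit(-50.0, ["intercept"])
        res = inf.lr_test(full, reduced)
        assert res.value == 0.0
        assert res.p == 1.0

    def test_identical_models_rejected(self):
        full = self._fit(-50.0, ["intercept", "memorability"])
        with pytest.raises(DataError):
            inf.lr_test(full, full)

    def test_df_counts_dropped_terms(self):
        full = self._fit(-40.0, ["intercept", "memorability", "speed", "interaction"])
        reduced = self._fit(-45.0, ["intercept", "memorability"])
        res = inf.lr_test(full, reduced)
        assert res.df == 2.0
        assert res.value == pytest.approx(10.0)

    def test_non_nested_raises(self):
        full = self._fit(-40.0, ["intercept", "memorability"])
        other = self._fit(-42.0, ["intercept", "speed"])
        with pytest.raises(DataError):
            inf.lr_test(full, other)

    def test_different_data_raises(self):
        full = self._fit(-40.0, ["intercept", "memorability"], n_obs=100)
        reduced = self._fit(-42.0, ["intercept"], n_obs=90)
        with pytest.raises(DataError):
            inf.lr_test(full, reduced)


class TestBinnedPsychometric:
    def test_all_long_means_one(self, slow_stimuli, slow_test_scores):
        trials = sb.simulate_bisection(["a", "b"], slow_stimuli, sb.ChoiceModelParams(), seed=0, n_blocks=1)
        trials["response"] = "long"
        surface = inf.binned_psychometric(trials, slow_test_scores)
        assert np.nanmin(surface.cell_means) == 1.0

    def test_toy_matches_groupby_oracle(self, slow_test_scores):
        rng = np.random.default_rng(4)
        ids = slow_test_scores["image_id"].to_numpy()
        trials = pd.DataFrame(
            {
                "subject_id": rng.choice(["a", "b"], 30),
                "image_id": rng.choice(ids, 30),
                "duration_ms": 500.0,
                "response": rng.choice(["long", "short"], 30),
            }
        )
        surface = inf.binned_psychometric(trials, slow_test_scores, n_mem_bins=2, n_speed_bins=2)
        # brute-force group-by oracle
        from chronomem.coding import code_covariates

        merged = trials.merge(slow_test_scores, on="image_id")
        coding = code_covariates(merged)
        speed = coding.speed(merged["A"])
        mem = merged["memorability"].to_numpy()
        for mi in range(2):
            for si in range(2):
                me, se_ = surface.mem_edges, surface.speed_edges
                m_mask = (mem >= me[mi]) & ((mem < me[mi + 1]) | (mi == 1) & (mem <= me[2]))
                s_mask = (speed >= se_[si]) & ((speed < se_[si + 1]) | (si == 1) & (speed <= se_[2]))
                cell = merged.loc[m_mask & s_mask, "response"] == "long"
                if len(cell) == 0:
                    assert np.isnan(surface.cell_means[mi, si])
                else:
                    assert surface.cell_means[mi, si] == pytest.approx(cell.mean())
                    assert surface.cell_counts[mi, si] == len(cell)

    def test_speed_only_layout_11_cells(self, slow_stimuli, slow_test_scores):
        trials = sb.simulate_bisection(["a", "b"], slow_stimuli, sb.ChoiceModelParams(), seed=2, n_blocks=1)
        surface = inf.binned_psychometric(trials, slow_test_scores, n_mem_bins=None, n_speed_bins=11)
        assert surface.cell_means.shape == (11,)
        assert surface.mem_edges is None

    def test_means_in_unit_interval(self, slow_stimuli, slow_test_scores):
        trials = sb.simulate_bisection(["a", "b"], slow_stimuli, sb.ChoiceModelParams(), seed=3, n_blocks=1)
        surface = inf.binned_psychometric(trials, slow_test_scores)
        ok = ~np.isnan(surface.cell_means)
        assert ((surface.cell_means[ok] >= 0) & (surface.cell_means[ok] <= 1)).all()


class TestFitInvertedU:
    def _surface(self, x, y, counts=None):
        counts = np.full(len(x), 100) if counts is None else counts
        h = x[1] - x[0]  # uniform grid: edges chosen so bin centers equal x
        edges = np.concatenate([x - h / 2, [x[-1] + h / 2]])
        return inf.BinnedSurface(
            mem_edges=None, speed_edges=edges, cell_means=np.asarray(y, dtype=float),
            cell_counts=np.asarray(counts), subject_means=pd.DataFrame(),
        )

    def test_noiseless_parabola_exact(self):
        x = np.linspace(-1, 3, 11)
        y = -0.5 * (x - 1.0) ** 2 + 0.8
        fit = inf.fit_inverted_u(self._surface(x, y))
        assert fit.M1 == pytest.approx(0.5, abs=1e-9)
        assert fit.M2 == pytest.approx(1.0, abs=1e-9)
        assert fit.M3 == pytest.approx(0.8, abs=1e-9)
        assert fit.inverted_u

    def test_monotone_data_flagged(self):
        x = np.linspace(0, 1, 8)
        fit = inf.fit_inverted_u(self._surface(x, 0.1 + 0.5 * x**2))
        assert not fit.inverted_u

    def test_too_few_bins(self):
        x = np.array([0.0, 1.0, 2.0])
        with pytest.raises(DataError):
            inf.fit_inverted_u(self._surface(x, x))

    def test_weights_matter(self):
        x = np.linspace(-1, 1, 9)
        y = -0.5 * (x - 0.2) ** 2 + 0.7
        y_bad = y.copy()
        y_bad[0] = 0.0  # corrupted low-count cell
        counts = np.full(9, 1000)
        counts[0] = 1
        fit = inf.fit_inverted_u(self._surface(x, y_bad, counts))
        assert fit.M2 == pytest.approx(0.2, abs=0.05)


class TestRecognitionSummary:
    def _toy(self):
        rows = []
        for subject, hits in (("a", [1, 1, 0, 0]), ("b", [1, 0, 1, 0])):
            for k, h in enumerate(hits):
                rows.append(
                    {"subject_id": subject, "image_id": f"i{k}", "is_old": 1,
                     "response": "old" if h else "new", "correct": h}
                )
            rows.append({"subject_id": subject, "image_id": "f0", "is_old": 0, "response": "new", "correct": 1})
        return pd.DataFrame(rows), {"i0": 1, "i1": 1, "i2": 2, "i3": 2, "f0": 1}

    def test_perfect_responder(self, slow_stimuli):
        subs = ["a", "b"]
        recog = sb.simulate_recognition(
            subs, slow_stimuli, hit_model=lambda m, a: np.ones_like(m), fa_rate=0.0, seed=0
        )
        summary = inf.recognition_summary(recog, slow_stimuli.per_bin_assignment)
        assert (summary.per_bin_hit_rate == 1.0).all()
        assert summary.spread == 0.0
        assert summary.overall_hit_rate == 1.0

    def test_toy_hand_computed(self):
        recog, bins = self._toy()
        summary = inf.recognition_summary(recog, bins)
        # subject a: bin1 hits (1,1)->1.0, bin2 (0,0)->0.0 ; b: bin1 (1,0)->0.5, bin2 (1,0)->0.5
        assert summary.subject_matrix.loc["a", 1] == 1.0
        assert summary.subject_matrix.loc["a", 2] == 0.0
        assert summary.per_bin_hit_rate[1] == pytest.approx(0.75)
        assert summary.per_bin_hit_rate[2] == pytest.approx(0.25)
        assert summary.spread == pytest.approx(0.5)
        assert summary.overall_hit_rate == pytest.approx(0.5)

    def test_missing_bin_assignment_raises(self):
        recog, bins = self._toy()
        del bins["i0"]
        with pytest.raises(DataError):
            inf.recognition_summary(recog, bins)


class TestRmAnova:
    def test_df_bookkeeping_20x7(self):
        rng = np.random.default_rng(0)
        res = inf.rm_anova(rng.random((20, 7)))
        assert res.df == (6.0, 114.0)

    def test_all_equal_cells(self):
        res = inf.rm_anova(np.full((5, 4), 0.3))
        assert res.value == 0.0
        assert res.extras["partial_eta_sq"] == 0.0

    def test_hand_3x3_decomposition(self):
        m = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 3.0, 3.0]])
        # textbook two-way (subject x condition) sum-of-squares oracle
        grand = m.mean()
        ss_cond = 3 * ((m.mean(0) - grand) ** 2).sum()
        ss_subj = 3 * ((m.mean(1) - grand) ** 2).sum()
        ss_err = ((m - grand) ** 2).sum() - ss_cond - ss_subj
        f_expect = (ss_cond / 2) / (ss_err / 4)
        res = inf.rm_anova(m)
        assert res.value == pytest.approx(f_expect)
        assert res.extras["partial_eta_sq"] == pytest.approx(ss_cond / (ss_cond + ss_err))

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        m = rng.random((8, 5))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 5),
                "cond": np.tile(np.arange(5), 8),
                "y": m.reshape(-1),
            }
        )
        res_pg = pg.rm_anova(data=long, dv="y", within="cond", subject="subject")
        res = inf.rm_anova(m)
        assert res.value == pytest.approx(float(res_pg["F"].iloc[0]), rel=1e-6)
        assert res.p == pytest.approx(float(res_pg["p_unc"].iloc[0]), rel=1e-6)

    def test_needs_two_subjects(self):
        with pytest.raises(DataError):
            inf.rm_anova(np.ones((1, 4)))


class TestGroupContrast:
    def test_identical_groups_null(self):
        g = {"a": [0.4, 0.5, 0.6, 0.5], "b": [0.4, 0.5, 0.6, 0.5]}
        res = inf.group_contrast(g)[0]
        assert res.value == 0.0
        assert res.extras["cohens_d"] == 0.0
        assert res.p == 1.0

    def test_three_groups_three_comparisons(self):
        rng = np.random.default_rng(2)
        g = {k: rng.random(5) for k in "abc"}
        results = inf.group_contrast(g)
        assert len(results) == 3
        assert all(r.extras["n_comparisons"] == 3 for r in results)
        assert all(r.p >= r.extras["p_raw"] for r in results)  # Bonferroni >= raw

    def test_hand_computed_pooled_t(self):
        from scipy import stats

        x = np.array([0.1, 0.3, 0.2, 0.4, 0.25])
        y = np.array([0.5, 0.6, 0.55, 0.7, 0.65])
        res = inf.group_contrast({"x": x, "y": y})[0]
        t_ref, p_ref = stats.ttest_ind(x, y, equal_var=True)
        assert res.value == pytest.approx(t_ref)
        assert res.p == pytest.approx(min(1.0, p_ref))
        n1 = n2 = 5
        pooled = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
        assert res.extras["cohens_d"] == pytest.approx((x.mean() - y.mean()) / pooled)

    def test_small_group_rejected(self):
        with pytest.raises(DataError):
            inf.group_contrast({"a": [0.1], "b": [0.2, 0.3]})


class TestInteractionSignProperty:
    def test_positive_interaction_recovered(self, fast_stimuli, fast_test_scores):
        # light version of the >=90% property: 8 of 10 replicates must agree
        params = sb.ChoiceModelParams(
            beta_mem=1.0, beta_speed=-0.2, beta_interaction=0.8,
            sd_subject_intercept=0.3, sd_subject_speed_slope=0.1,
        )
        subs = [f"s{i:02d}" for i in range(12)]
        hits = 0
        for rep in range(10):
            trials = sb.simulate_bisection(subs, fast_stimuli, params, seed=300 + rep, n_blocks=3)
            fit = inf.fit_choice_glmm(
                trials, fast_test_scores, include_duration=True, compute_se=False
            )
            hits += fit.coefficients["interaction"][0] > 0
        assert hits >= 8
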