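import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mcrstress.exceptions import ComputationError, DomainError
from mcrstress.validation_stats import (bh_adjust, construct_validity_report,
                                        delong_one_sided_test,
                                        face_validity_ols,
                                        fit_univariate_logistic, kde_overlap,
                                        partial_spearman_age,
                                        roc_auc_delong_ci, spearman)


def _brute_force_auc(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# face validity


def _simulate_planes(beta, n_subjects=40, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        healthy = i % 2 == 0
        for m in range(4):
            for c in range(4):
                mu = (beta[0] + beta[1] * m + beta[2] * c + beta[3] * healthy
                      + beta[4] * m * healthy + beta[5] * c * healthy)
                rows.append({
                    "subject_id": f"P{i}",
                    "group": "healthy" if healthy else "diagnosed",
                    "motor_level": m, "cognitive_level": c,
                    "score": mu + noise * rng.standard_normal(),
                })
    return pd.DataFrame(rows)


class TestFaceValidityOLS:
    def test_exact_recovery_on_noiseless_linear_data(self):
        beta = (0.4, -0.3, -0.25, 0.6, 0.05, -0.02)
        result = face_validity_ols(_simulate_planes(beta))
        estimates = [result.params[k] for k in
                     ("intercept", "motor", "cognitive", "healthy",
                      "motor:healthy", "cognitive:healthy")]
        assert np.allclose(estimates, beta, atol=1e-10)

    def test_group_labels_mapping_accepted(self):
        frame = _simulate_planes((0, -1, -1, 1, 0, 0))
        labels = frame.drop_duplicates("subject_id").set_index("subject_id")["group"]
        bare = frame.drop(columns="group")
        result = face_validity_ols(bare, labels)
        assert result.params["motor"] == pytest.approx(-1.0)

    def test_rank_deficient_design_rejected(self):
        frame = _simulate_planes((0, -1, -1, 1, 0, 0))
        frame["motor_level"] = 0
        with pytest.raises(ComputationError):
            face_validity_ols(frame)

    def test_pvalues_in_unit_interval(self):
        result = face_validity_ols(_simulate_planes((0, -1, -1, 1, 0, 0),
                                                    noise=0.5, seed=2))
        assert all(0 <= p <= 1 for p in result.pvalues.values())


# ---------------------------------------------------------------------------
# density overlap


class TestKdeOverlap:
    def test_identical_samples_overlap_fully(self):
        x = np.random.default_rng(0).normal(size=200)
        assert kde_overlap(x, x) >= 0.99

    def test_disjoint_samples_overlap_nowhere(self):
        rng = np.random.default_rng(1)
        assert kde_overlap(rng.normal(-100, 1, 300), rng.normal(100, 1, 300)) <= 0.01

    def test_matches_analytic_normal_overlap(self):
        """Overlap of N(0,1) and N(1,1) densities is 2*Phi(-1/2) ~ 0.6171."""
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 20_000)
        b = rng.normal(1, 1, 20_000)
        assert kde_overlap(a, b) == pytest.approx(2 * sps.norm.cdf(-0.5), abs=0.02)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 400)
        b = rng.normal(0.7, 1.3, 300)
        assert kde_overlap(a, b) == pytest.approx(kde_overlap(b, a), abs=1e-12)
        assert kde_overlap(3 * a + 5, 3 * b + 5) == pytest.approx(
            kde_overlap(a, b), abs=1e-6)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ComputationError):
            kde_overlap([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        with pytest.raises(ComputationError):
            kde_overlap([1.0], [0.0, 1.0])


# ---------------------------------------------------------------------------
# ROC / DeLong


class TestRocAucDeLong:
    def test_textbook_pair_counting_example(self):
        scores = np.array([2.0, 4.0, 3.0, 5.0])
        labels = np.array([0, 0, 1, 1])
        assert roc_auc_delong_ci(scores, labels).auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        res = roc_auc_delong_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.ci_high == 1.0

    def test_all_ties_give_chance_level(self):
        res = roc_auc_delong_ci([5.0] * 8, [0, 1] * 4)
        assert res.auc == 0.5

    def test_ci_brackets_auc_within_unit_interval(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        res = roc_auc_delong_ci(scores, labels)
        assert 0 <= res.ci_low <= res.auc <= res.ci_high <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ComputationError):
            roc_auc_delong_ci([1.0, 2.0], [1, 1])

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_brute_force_pair_counting(self, data):
        n = data.draw(st.integers(4, 30))
        scores = np.array(data.draw(st.lists(
            st.integers(0, 6), min_size=n, max_size=n)), dtype=float)
        labels = np.array(data.draw(st.lists(
            st.booleans(), min_size=n, max_size=n)))
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        auc = roc_auc_delong_ci(scores, labels).auc
        assert auc == pytest.approx(_brute_force_auc(scores[labels],
                                                     scores[~labels]))

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(9)
        scores = rng.normal(size=200) + np.repeat([0.0, 1.0], 100)
        labels = np.repeat([0, 1], 100)
        assert roc_auc_delong_ci(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores))


class TestDeLongComparison:
    def test_identical_classifiers_give_half(self):
        scores = np.arange(10.0)
        labels = np.array([0, 1] * 5)
        cmp = delong_one_sided_test(scores, scores, labels)
        assert cmp.z == 0.0
        assert cmp.p_one_sided == 0.5

    def test_swapping_arguments_reflects_p(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([0, 1], 30)
        signal = labels + rng.normal(scale=1.0, size=60)
        noise = labels + rng.normal(scale=3.0, size=60)
        ab = delong_one_sided_test(signal, noise, labels)
        ba = delong_one_sided_test(noise, signal, labels)
        assert ab.p_one_sided == pytest.approx(1 - ba.p_one_sided, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            delong_one_sided_test([1, 2, 3], [1, 2], [0, 1, 1])

    def test_dominant_classifier_detected(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([0, 1], 60)
        strong = labels * 2.0 + rng.normal(scale=0.5, size=120)
        weak = labels * 0.3 + rng.normal(scale=1.5, size=120)
        cmp = delong_one_sided_test(strong, weak, labels)
        assert cmp.p_one_sided < 0.01


class TestLogisticDirection:
    def test_auc_invariant_under_fitted_logistic_link(self):
        """AUC on predicted probabilities equals AUC on raw scores because the
        logistic link is monotone; a negative slope flips the orientation."""
        rng = np.random.default_rng(6)
        labels = np.repeat([0, 1], 50)
        scores = labels * 1.2 + rng.normal(size=100)
        slope = fit_univariate_logistic(scores, labels)
        probs = 1 / (1 + np.exp(-slope * scores))
        auc_scores = roc_auc_delong_ci(scores, labels).auc
        oriented = probs if slope > 0 else 1 - probs
        # probabilities with positive slope are a monotone map of scores
        assert roc_auc_delong_ci(oriented, labels).auc == pytest.approx(
            auc_scores if slope > 0 else 1 - auc_scores)
        assert slope > 0


# ---------------------------------------------------------------------------
# correlations and multiplicity


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -x ** 3)[0] == pytest.approx(-1.0)

    def test_midrank_tie_handling_matches_hand_oracle(self):
        x = [1.0, 2.0, 2.0, 4.0]
        y = [3.0, 1.0, 4.0, 4.0]
        rx = sps.rankdata(x)  # [1, 2.5, 2.5, 4]
        ry = sps.rankdata(y)  # [2, 1, 3.5, 3.5]
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(oracle)

    def test_constant_vector_rejected(self):
        with pytest.raises(ComputationError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_observations_rejected(self):
        with pytest.raises(DomainError):
            spearman([1.0, 2.0], [2.0, 1.0])


class TestBHAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        adjusted = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, 0.04)

    def test_adjusted_never_below_raw_and_order_preserved(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=25)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_agrees_with_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.2])


class TestPartialSpearman:
    def test_constant_age_falls_back_with_warning(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        with pytest.warns(UserWarning):
            rho, p = partial_spearman_age(x, y, np.full(30, 50.0))
        assert rho == pytest.approx(spearman(x, y)[0])

    def test_perfectly_coupled_variables(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        age = rng.normal(size=40)
        rho, p = partial_spearman_age(x, x, age)
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_age_driven_association_vanishes_after_adjustment(self):
        rng = np.random.default_rng(4)
        age = rng.uniform(20, 80, size=500)
        x = age + rng.normal(scale=5, size=500)
        y = -age + rng.normal(scale=5, size=500)
        rho_plain, _ = spearman(x, y)
        rho_adj, _ = partial_spearman_age(x, y, age)
        assert abs(rho_plain) > 0.8
        assert abs(rho_adj) < 0.1

    def test_agrees_with_pingouin_partial_correlation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        frame = pd.DataFrame({"x": rng.normal(size=50),
                              "y": rng.normal(size=50),
                              "age": rng.normal(size=50)})
        frame["y"] += 0.5 * frame["x"] + 0.3 * frame["age"]
        expected = pingouin.partial_corr(frame, x="x", y="y", covar="age",
                                         method="spearman")
        rho, p = partial_spearman_age(frame["x"], frame["y"], frame["age"])
        assert rho == pytest.approx(float(expected["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(expected["p_val"].iloc[0]), abs=1e-9)


class TestConstructValidityReport:
    def test_one_row_per_proxy_and_region(self, default_cohort, analysed):
        report = construct_validity_report(analysed["mcr"],
                                           default_cohort.subjects,
                                           mri=default_cohort.mri,
                                           age_adjust_mri=True)
        clinical = report[report["family"] == "clinical"]
        mri_rows = report[report["family"] == "mri"]
        assert clinical["variable"].is_unique
        assert mri_rows["variable"].is_unique
        assert len(mri_rows) == len(default_cohort.mri.columns) - 1
        assert (report["p_adj"] >= report["p"] - 1e-12).all()

    def test_index_tracks_latent_reserve(self, default_cohort, analysed):
        truth = default_cohort.truth.drop_duplicates("subject_id")
        merged = analysed["mcr"].merge(truth, on="subject_id")
        rho, _ = spearman(merged["mcr_index"], merged["latent_reserve"])
        assert rho >= 0.7

    def test_missing_subjects_reported(self, default_cohort, analysed):
        subjects = default_cohort.subjects.iloc[:-5]
        with pytest.raises(DomainError):
            construct_validity_report(analysed["mcr"], subjects)
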