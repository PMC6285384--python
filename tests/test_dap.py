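"""Protocol components: MCC, ranking, folds, bootstrap, and full runs."""

import numpy as np
import pytest
from scipy.stats import f_oneway, pearsonr

from cdrp.dap import (CDRPEstimator, ConfusionMatrix, DAPConfig, DAPResult,
                      SklearnTaskEstimator, anova_f_rank, bootstrap_ci,
                      confusion_from_labels, external_validate, mcc,
                      random_feature_check, run_dap, select_split,
                      stratified_folds)
from cdrp.experiments import fast_training_config


def _confusion_vectors(c):
    """Reconstruct label vectors realizing a confusion matrix."""
    y_true = [1] * c.tp + [0] * c.tn + [0] * c.fp + [1] * c.fn
    y_pred = [1] * c.tp + [0] * c.tn + [1] * c.fp + [0] * c.fn
    return np.array(y_true), np.array(y_pred)


class TestMCC:
    def test_boundary_cases(self):
        assert mcc(ConfusionMatrix(10, 10, 0, 0)) == 1.0
        assert mcc(ConfusionMatrix(0, 0, 10, 10)) == -1.0
        assert mcc(ConfusionMatrix(25, 25, 25, 25)) == 0.0

    def test_zero_denominator_convention(self):
        # no positive predictions at all
        assert mcc(ConfusionMatrix(0, 30, 0, 10)) == 0.0

    def test_printed_formula_example(self):
        c = ConfusionMatrix(tp=40, tn=20, fp=10, fn=5)
        num = 40 * 20 - 10 * 5
        den = np.sqrt((40 + 10) * (40 + 5) * (20 + 10) * (20 + 5))
        assert mcc(c) == pytest.approx(num / den)
        assert mcc(c) == pytest.approx(0.5774, abs=5e-4)

    def test_equals_pearson_of_binary_vectors(self, rng):
        """Formula agrees with the phi/Pearson correlation (oracle)."""
        for _ in range(300):
            counts = rng.integers(0, 20, size=4)
            c = ConfusionMatrix(*map(int, counts))
            y_true, y_pred = _confusion_vectors(c)
            if len(np.unique(y_true)) < 2 or len(np.unique(y_pred)) < 2:
                assert mcc(c) == 0.0
                continue
            r, _ = pearsonr(y_true, y_pred)
            assert mcc(c) == pytest.approx(r, abs=1e-12)


class TestRanking:
    def test_constant_gene_scores_zero(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        rank = anova_f_rank(X, y)
        assert rank.gene_ids[-1] == "0"
        assert rank.scores[-1] == 0.0

    def test_hand_computed_f(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        rank = anova_f_rank(X, y)
        # SSB = 13.5, MSW = 1 → F = 13.5
        assert rank.scores[0] == pytest.approx(13.5)

    def test_location_invariance(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.integers(0, 2, 30)
        y[:3], y[-3:] = 0, 1
        r1 = anova_f_rank(X, y)
        r2 = anova_f_rank(X + 7.3, y)
        np.testing.assert_allclose(r1.scores, r2.scores, rtol=1e-9)
        assert r1.gene_ids == r2.gene_ids

    def test_matches_scipy_oneway(self, rng):
        X = rng.normal(size=(40, 6))
        y = np.array([0] * 20 + [1] * 20)
        rank = anova_f_rank(X, y)
        score = dict(zip(rank.gene_ids, rank.scores))
        for j in range(6):
            F, _ = f_oneway(X[y == 0, j], X[y == 1, j])
            assert score[str(j)] == pytest.approx(F, rel=1e-9)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            anova_f_rank(rng.normal(size=(10, 3)), np.zeros(10, dtype=int))


class TestStratifiedFolds:
    def test_exact_class_proportions(self):
        y = np.array([1] * 10 + [0] * 40)
        folds = stratified_folds(y, n_folds=5, repeats=3, seed=0)
        for rep in folds:
            for _, te in rep:
                assert y[te].sum() == 2 and len(te) == 10

    def test_partition_properties(self):
        y = np.array([0, 1] * 25)
        folds = stratified_folds(y, 5, 2, seed=1)
        for rep in folds:
            tests = [set(te) for _, te in rep]
            assert set().union(*tests) == set(range(50))
            for i in range(5):
                for j in range(i + 1, 5):
                    assert not tests[i] & tests[j]

    def test_seed_reproducibility_and_repeat_variation(self):
        y = np.array([0, 1] * 30)
        f1 = stratified_folds(y, 5, 2, seed=3)
        f2 = stratified_folds(y, 5, 2, seed=3)
        assert all(
            np.array_equal(a[1], b[1])
            for r1, r2 in zip(f1, f2) for a, b in zip(r1, r2))
        assert any(
            not np.array_equal(f1[0][i][1], f1[1][i][1]) for i in range(5))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer samples"):
            stratified_folds(np.array([1, 1, 0, 0, 0, 0, 0, 0]), 5, 1, 0)


class TestBootstrapCI:
    def test_constant_vector_zero_width(self):
        lo, hi = bootstrap_ci([0.4] * 20)
        assert lo == hi == pytest.approx(0.4)

    def test_contains_sample_mean(self, rng):
        v = rng.normal(0.3, 0.1, size=50)
        lo, hi = bootstrap_ci(v, seed=1)
        assert lo <= v.mean() <= hi

    def test_coverage_of_true_mean(self):
        """~95% coverage of the true mean on Gaussian samples (oracle)."""
        rng = np.random.default_rng(0)
        hit = 0
        n_sim = 400
        for _ in range(n_sim):
            v = rng.normal(0.0, 1.0, size=50)
            lo, hi = bootstrap_ci(v, n_boot=400,
                                  seed=int(rng.integers(2**31)))
            hit += lo <= 0.0 <= hi
        assert 0.91 <= hit / n_sim <= 0.985


def _lsvm_factory(seed, task="efs"):
    from sklearn.svm import LinearSVC
    return SklearnTaskEstimator(LinearSVC(random_state=seed), task=task)


class TestRunDAP:
    def test_signal_recovered_and_audit_clean(self, small_cohort):
        x, clinical, _ = small_cohort
        res = run_dap(x, clinical, "efs",
                      lambda s: _lsvm_factory(s),
                      DAPConfig(repeats=2, folds=5, k_grid=(25, 50), seed=0))
        assert res.cv_mcc_median > 0.3
        assert res.audit_clean
        assert res.per_fold.shape[0] == 2 * 5 * 2
        counts = res.per_sample_correct["correct"]
        assert counts.between(0, 2).all()

    def test_null_cohort_scores_nothing(self):
        from cdrp.simulate import CohortConfig, generate
        cfg = CohortConfig(n_samples=200, n_genes=100, n_informative=20,
                           severity_effect=0.0, seed=21)
        x, clinical, _ = generate(cfg)
        res = run_dap(x, clinical, "efs", lambda s: _lsvm_factory(s),
                      DAPConfig(repeats=2, folds=5, k_grid=(25,), seed=0))
        assert abs(res.cv_mcc_median) < 0.1

    def test_hr_restriction_subsets_cohort(self, small_cohort):
        x, clinical, _ = small_cohort
        res = run_dap(x, clinical, "efs_hr", lambda s: _lsvm_factory(s),
                      DAPConfig(repeats=1, folds=3, k_grid=(25,), seed=0))
        n_hr = int(clinical.column("hr").sum())
        assert len(res.per_sample_correct) == n_hr

    def test_random_label_run_near_zero(self, small_cohort):
        x, clinical, _ = small_cohort
        res = run_dap(x, clinical, "efs", lambda s: _lsvm_factory(s),
                      DAPConfig(repeats=1, folds=5, k_grid=(25,), seed=5,
                                scheme="random_label"))
        assert abs(res.cv_mcc_median) < 0.25

    def test_random_feature_scheme_runs(self, small_cohort):
        x, clinical, _ = small_cohort
        out = random_feature_check(x, clinical, "efs",
                                   lambda s: _lsvm_factory(s),
                                   DAPConfig(repeats=1, folds=3,
                                             k_grid=(25,), seed=2),
                                   n_runs=2)
        assert out["mccs"].shape == (2,)

    def test_result_round_trips_through_json(self, small_cohort, tmp_path):
        x, clinical, _ = small_cohort
        res = run_dap(x, clinical, "efs", lambda s: _lsvm_factory(s),
                      DAPConfig(repeats=1, folds=3, k_grid=(25,), seed=0))
        path = tmp_path / "res.json"
        res.to_json(path)
        import json
        back = DAPResult.from_dict(json.loads(path.read_text()))
        assert back.task == res.task
        assert back.best_k == res.best_k
        assert back.cv_mcc_median == res.cv_mcc_median
        assert back.per_fold.equals(res.per_fold.reset_index(drop=True))
        assert back.per_sample_correct.equals(res.per_sample_correct)


class TestExternalValidation:
    def test_resubstitution_is_optimistic(self, small_cohort):
        """Validating on the training set itself scores at least the CV
        median (resubstitution optimism)."""
        x, clinical, _ = small_cohort
        gaps = []
        for seed in range(3):
            res = run_dap(x, clinical, "efs", lambda s: _lsvm_factory(s),
                          DAPConfig(repeats=1, folds=5, k_grid=(25,),
                                    seed=seed))
            ext = external_validate(res, x, clinical)
            gaps.append(ext["mcc"] - res.cv_mcc_median)
        assert np.median(gaps) >= 0.0

    def test_swapped_halves_both_directions(self, small_cohort):
        x, clinical, _ = small_cohort
        half = x.n_samples // 2
        a = x.subset_samples(x.sample_ids[:half])
        b = x.subset_samples(x.sample_ids[half:])
        cfg = DAPConfig(repeats=1, folds=3, k_grid=(25,), seed=0)
        factory = lambda s: _lsvm_factory(s)
        res_ab = run_dap(a, clinical, "efs", factory, cfg)
        m_ab = external_validate(res_ab, b, clinical)["mcc"]
        res_ba = run_dap(b, clinical, "efs", factory, cfg)
        m_ba = external_validate(res_ba, a, clinical)["mcc"]
        assert np.isfinite(m_ab) and np.isfinite(m_ba)

    def test_gene_set_mismatch_rejected(self, small_cohort):
        x, clinical, _ = small_cohort
        res = run_dap(x, clinical, "efs", lambda s: _lsvm_factory(s),
                      DAPConfig(repeats=1, folds=3, k_grid=(25,), seed=0))
        stranger = x.subset_genes(x.gene_ids[:10])
        renamed = type(x)(stranger.values, list(stranger.sample_ids),
                          [f"zz{j}" for j in range(10)], None)
        with pytest.raises(ValueError, match="lacks"):
            external_validate(res, renamed, clinical)


class TestSelectSplit:
    def test_single_candidate_returned_and_reproducible(self, small_cohort):
        x, clinical, _ = small_cohort
        s1 = select_split(x, clinical, n_candidates=1, seed=4)
        s2 = select_split(x, clinical, n_candidates=1, seed=4)
        assert s1.train_ids == s2.train_ids
        assert s1.test_ids == s2.test_ids
        assert set(s1.train_ids) | set(s1.test_ids) == set(x.sample_ids)

    def test_returns_argmax_of_documented_criterion(self, small_cohort):
        """The chosen split maximizes val MCC − λ·max(0, overfit gap),
        verified by independently rescoring every candidate."""
        from sklearn.model_selection import train_test_split
        from sklearn.svm import LinearSVC
        from cdrp.cohort import apply_standardizer, fit_standardizer
        from cdrp.dap import _labels_for, _take

        x, clinical, _ = small_cohort
        seed, n_cand = 7, 6
        chosen = select_split(x, clinical, n_candidates=n_cand, seed=seed)
        y = _labels_for(clinical, x.sample_ids)["efs"]
        scores = {}
        for i in range(n_cand):
            tr, te = train_test_split(np.arange(x.n_samples), test_size=0.5,
                                      stratify=y, random_state=seed + i)
            params = fit_standardizer(_take(x, tr))
            z_tr = apply_standardizer(params, _take(x, tr))
            z_te = apply_standardizer(params, _take(x, te))
            clf = LinearSVC().fit(z_tr.values, y[tr])
            m_tr = mcc(confusion_from_labels(y[tr], clf.predict(z_tr.values)))
            m_te = mcc(confusion_from_labels(y[te], clf.predict(z_te.values)))
            scores[i] = (m_te - max(0.0, m_tr - m_te),
                         frozenset(x.sample_ids[j] for j in te))
        best_i = max(scores, key=lambda i: scores[i][0])
        assert frozenset(chosen.test_ids) == scores[best_i][1]


class TestCDRPEstimatorInProtocol:
    def test_cdrp_fold_run(self, small_cohort):
        """The networks plug into the protocol and learn planted signal."""
        x, clinical, _ = small_cohort
        factory = lambda s: CDRPEstimator(use_embedding=True,
                                          cfg=fast_training_config(s),
                                          seed=s)
        res = run_dap(x, clinical, "efs", factory,
                      DAPConfig(repeats=1, folds=3, k_grid=(25,), seed=0))
        assert res.cv_mcc_median > 0.2
        assert res.audit_clean
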