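import numpy as np
import pytest

from conftest import random_instance
from fgmdr.fixtures import brute_force_ba, toy_dataset
from fgmdr.glm_scores import scores_for
from fgmdr.membership import MembershipFunction
from fgmdr.model_search import (
    SearchConfig,
    cross_validated_search,
    evaluate_combination,
    make_folds,
    run_method,
    search_membership,
)


def test_evaluate_single_locus_hand_value(rng):
    from fgmdr.io_formats import GenotypeMatrix
    from fgmdr.glm_scores import ScoreVector

    genos = GenotypeMatrix(
        samples=["a", "b", "c", "d"], snps=["SNP1"],
        values=np.array([[0], [0], [1], [2]], dtype=np.int8),
    )
    scores = ScoreVector(s=np.array([1.0, -1.0, 2.0, -3.0]), family="gaussian")
    ba = evaluate_combination(genos, scores, ["SNP1"], MembershipFunction.indicator(0.0))
    # H cells (means 0, 2) hold all pos mass (SEN 1) and neg mass 1 of 4
    # (SPE 3/4): BA = (1 + 3/4)/2
    assert ba == pytest.approx(0.875)
    assert ba == pytest.approx(brute_force_ba(genos, ["SNP1"], scores, MembershipFunction.indicator(0.0)))


def test_evaluate_order_invariance(rng):
    genos, scores = random_instance(rng, n=60, p=3)
    f = MembershipFunction.sigmoid(-0.3, 0.3)
    assert evaluate_combination(genos, scores, ["SNP1", "SNP2"], f) == pytest.approx(
        evaluate_combination(genos, scores, ["SNP2", "SNP1"], f), abs=1e-14
    )


def test_make_folds_sizes_and_determinism():
    f1 = make_folds(20, 10, seed=7)
    f2 = make_folds(20, 10, seed=7)
    assert np.array_equal(f1, f2)
    sizes = np.bincount(f1, minlength=10)
    assert sizes.tolist() == [2] * 10
    f3 = make_folds(23, 10, seed=7)
    sizes3 = np.bincount(f3, minlength=10)
    assert sizes3.max() - sizes3.min() <= 1


def test_stratified_folds_preserve_balance():
    labels = np.array([1] * 100 + [0] * 100)
    folds = make_folds(200, 10, labels=labels, seed=3, stratify=True)
    for f_id in range(10):
        in_fold = folds == f_id
        assert labels[in_fold].sum() == 10
        assert in_fold.sum() == 20


def test_stratified_fold_without_both_classes_errors():
    labels = np.array([1] * 3 + [0] * 9)
    with pytest.raises(ValueError, match="class"):
        make_folds(12, 6, labels=labels, seed=0, stratify=True)


def test_search_counts_combinations_and_cvc_sums(rng):
    genos, scores = random_instance(rng, n=50, p=5)
    config = SearchConfig(order=2, n_folds=5, method="gmdr", seed=1)
    results = cross_validated_search(genos, scores, config)
    assert len(results) == 10  # C(5,2)
    assert sum(r.cvc for r in results) == 5
    assert results[0].cvc == max(r.cvc for r in results)
    assert all(0 <= r.ba_train <= 1 for r in results)


def test_combination_budget_enforced(rng):
    genos, scores = random_instance(rng, n=30, p=6)
    config = SearchConfig(order=3, n_folds=3, method="gmdr", combination_budget=10)
    with pytest.raises(ValueError, match="budget"):
        cross_validated_search(genos, scores, config)


def test_search_agrees_with_brute_force_per_fold(rng):
    genos, scores = random_instance(rng, n=48, p=4)
    for method in ("gmdr", "fgmdr"):
        config = SearchConfig(order=2, n_folds=4, method=method, seed=5)
        results = cross_validated_search(genos, scores, config)
        folds = make_folds(48, 4, seed=5)
        for r in results:
            for f_id in range(4):
                train = folds != f_id
                sub_genos = type(genos)(
                    samples=[s for s, m in zip(genos.samples, train) if m],
                    snps=genos.snps,
                    values=genos.values[train],
                )
                from fgmdr.glm_scores import ScoreVector

                sub_scores = ScoreVector(s=scores.s[train], family=scores.family)
                f = search_membership(config, scores.s[train])
                oracle = brute_force_ba(sub_genos, r.combination, sub_scores, f)
                # summation order differs between oracle and bincount path
                assert abs(r.fold_train_ba[f_id] - oracle) <= 1e-12


def test_zero_width_band_equals_indicator(rng):
    genos, scores = random_instance(rng, n=60, p=4)
    crisp = cross_validated_search(genos, scores, SearchConfig(order=2, n_folds=5, method="gmdr", seed=2))
    fuzzy0 = cross_validated_search(
        genos, scores, SearchConfig(order=2, n_folds=5, method="fgmdr", t_l=0.0, t_h=0.0, seed=2)
    )
    for a, b in zip(crisp, fuzzy0):
        assert a.combination == b.combination
        assert a.ba_train == b.ba_train
        assert a.cvc == b.cvc


def test_separable_fixture_recovered_exactly():
    genos, phenos = toy_dataset("separable", seed=4)
    config = SearchConfig(order=2, n_folds=5, method="gmdr", seed=4, stratify=True)
    results = run_method(genos, phenos, config)
    best = results[0]
    assert tuple(sorted(best.combination)) == ("SNP1", "SNP2")
    assert best.cvc == 5
    assert best.ba_train == pytest.approx(1.0)
    assert best.ba_test == pytest.approx(1.0)


def test_mdr_equals_gmdr_without_covariates():
    genos, phenos = toy_dataset("separable", seed=9)
    a = run_method(genos, phenos, SearchConfig(order=2, n_folds=5, method="mdr", seed=1))
    b = run_method(genos, phenos, SearchConfig(order=2, n_folds=5, method="gmdr", seed=1))
    for ra, rb in zip(a, b):
        assert ra.combination == rb.combination
        assert ra.ba_train == pytest.approx(rb.ba_train, abs=1e-14)
        assert ra.cvc == rb.cvc


def test_covariates_warn_for_covariate_blind_methods():
    genos, phenos = toy_dataset("covariate_confounded", seed=2)
    with pytest.warns(UserWarning, match="ignores covariates"):
        run_method(genos, phenos, SearchConfig(order=2, n_folds=5, method="mdr", seed=1))


def test_results_independent_of_column_order(rng):
    genos, scores = random_instance(rng, n=60, p=4)
    config = SearchConfig(order=2, n_folds=5, method="gmdr", seed=6)
    res_a = cross_validated_search(genos, scores, config)
    perm = [2, 0, 3, 1]
    from fgmdr.io_formats import GenotypeMatrix

    genos_p = GenotypeMatrix(
        samples=genos.samples,
        snps=[genos.snps[j] for j in perm],
        values=genos.values[:, perm],
    )
    res_b = cross_validated_search(genos_p, scores, config)
    assert [r.combination for r in res_a] == [r.combination for r in res_b]
    assert np.allclose([r.ba_train for r in res_a], [r.ba_train for r in res_b])
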