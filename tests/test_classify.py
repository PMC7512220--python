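"""LOOCV classifier and permutation test: oracles, determinism, formulas."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

import swathms as sm
from swathms.classify import (
    RIDGE_ALPHA,
    _fit_ridge_logistic,
    _fold_scores,
    _predict_proba,
)
from swathms.errors import ConfigurationError

from conftest import quantify


@pytest.fixture(scope="module")
def separated_cohort():
    """Strong planted effects in every case: LOOCV should be error-free."""
    cfg = sm.CohortConfig(
        n_cases=11,
        n_controls=9,
        n_subgroup_cases=11,
        n_proteins=60,
        n_de_proteins=20,
        effect_log10fc=(1.0, 1.0),
        noise_cv=0.05,
        replicate_cv=0.05,
        peptides_per_protein=(3, 8),
        fragments_per_peptide=(4, 6),
        seed=2,
    )
    cohort = sm.generate_cohort(cfg)
    return cohort, quantify(cohort)


@pytest.fixture(scope="module")
def toy6():
    """Six-sample cohort whose label arrangements are exhaustively enumerable."""
    cfg = sm.CohortConfig(
        n_cases=3,
        n_controls=3,
        n_subgroup_cases=3,
        n_proteins=30,
        n_de_proteins=8,
        effect_log10fc=(0.6, 0.6),
        peptides_per_protein=(3, 6),
        fragments_per_peptide=(4, 6),
        seed=13,
    )
    cohort = sm.generate_cohort(cfg)
    return cohort, quantify(cohort)


def test_wide_separation_gives_zero_errors(separated_cohort):
    cohort, avg = separated_cohort
    for policy in ("refit_per_fold", "global"):
        res = sm.pc_logistic_loocv(avg, cohort.samples, 3, policy)
        assert res.error_count == 0
        assert res.pca_policy == policy
        probs = res.per_sample["held_out_probability"].to_numpy()
        assert ((probs >= 0) & (probs <= 1)).all()


def test_loocv_is_deterministic(planted_averaged):
    _, cohort, avg = planted_averaged
    a = sm.pc_logistic_loocv(avg, cohort.samples)
    b = sm.pc_logistic_loocv(avg, cohort.samples)
    pd.testing.assert_frame_equal(a.per_sample, b.per_sample)
    assert a.error_count == b.error_count


def test_error_count_matches_per_sample_table(planted_averaged):
    _, cohort, avg = planted_averaged
    res = sm.pc_logistic_loocv(avg, cohort.samples)
    mismatches = (res.per_sample["predicted_label"] != res.per_sample["true_label"]).sum()
    assert res.error_count == int(mismatches)


def test_newton_fit_matches_sklearn_oracle(planted_averaged):
    """The dedicated ridge-logistic solver reproduces sklearn's probabilities."""
    _, cohort, avg = planted_averaged
    folds = _fold_scores(avg, 3, "refit_per_fold")
    y = np.array([1 if g == "case" else 0 for g in cohort.samples["group"]])
    for i, (train_s, test_s) in enumerate(folds[:8]):
        y_train = np.delete(y, i)
        w = _fit_ridge_logistic(train_s, y_train.astype(float))
        mine = _predict_proba(w, test_s)[0]
        ref = LogisticRegression(C=1 / RIDGE_ALPHA, max_iter=20000, tol=1e-12).fit(
            train_s, y_train
        )
        theirs = ref.predict_proba(test_s)[0, list(ref.classes_).index(1)]
        assert mine == pytest.approx(theirs, abs=1e-6)


def test_permutation_p_value_formula(planted_averaged):
    _, cohort, avg = planted_averaged
    obs = sm.pc_logistic_loocv(avg, cohort.samples)
    perm = sm.permutation_test(avg, cohort.samples, 3, obs, n_permutations=60, seed=4)
    assert perm.method == "sampled"  # C(20,11) >> exhaustive bound
    assert len(perm.null_errors) == 60
    expected = (1 + (perm.null_errors <= perm.observed_error).sum()) / 61
    assert perm.p_value == pytest.approx(expected, rel=1e-12)
    assert perm.p_value >= 1 / 61


def test_permutation_determinism(planted_averaged):
    _, cohort, avg = planted_averaged
    obs = sm.pc_logistic_loocv(avg, cohort.samples)
    a = sm.permutation_test(avg, cohort.samples, 3, obs, n_permutations=40, seed=9)
    b = sm.permutation_test(avg, cohort.samples, 3, obs, n_permutations=40, seed=9)
    np.testing.assert_array_equal(a.null_errors, b.null_errors)
    assert a.p_value == b.p_value


def test_exhaustive_permutation_matches_enumeration_oracle(toy6):
    """On 6 samples the test enumerates all C(6,3)=20 label arrangements."""
    from itertools import combinations

    cohort, avg = toy6
    obs = sm.pc_logistic_loocv(avg, cohort.samples, k_components=2)
    perm = sm.permutation_test(avg, cohort.samples, 2, obs, seed=0)
    assert perm.method == "exhaustive"
    assert perm.n_permutations == 20

    # independent oracle: relabel the metadata explicitly and rerun LOOCV
    ids = list(avg.data.columns)
    null = []
    for case_set in combinations(range(6), 3):
        relabeled = pd.DataFrame(
            {
                "sample_id": ids,
                "group": ["case" if i in case_set else "control" for i in range(6)],
            }
        )
        null.append(
            sm.pc_logistic_loocv(avg, relabeled, k_components=2).error_count
        )
    null = np.array(null)
    assert perm.p_value == pytest.approx((null <= obs.error_count).mean(), rel=1e-12)
    np.testing.assert_array_equal(np.sort(perm.null_errors), np.sort(null))


def test_worst_possible_error_gives_p_one(toy6):
    cohort, avg = toy6
    obs = sm.pc_logistic_loocv(avg, cohort.samples, k_components=2)
    worst = sm.ClassifierResult(
        k_components=2,
        per_sample=obs.per_sample,
        error_count=6,
        pca_policy=obs.pca_policy,
    )
    perm = sm.permutation_test(avg, cohort.samples, 2, worst, seed=0)
    assert perm.p_value == 1.0


def test_chance_level_on_null_cohort(null_averaged):
    _, cohort, avg = null_averaged
    res = sm.pc_logistic_loocv(avg, cohort.samples)
    assert res.error_count >= 4  # no signal: errors well above the separated regime


def test_validation_errors(planted_averaged):
    _, cohort, avg = planted_averaged
    with pytest.raises(ValueError, match="k_components"):
        sm.pc_logistic_loocv(avg, cohort.samples, k_components=19)
    with pytest.raises(ConfigurationError, match="pca_policy"):
        sm.pc_logistic_loocv(avg, cohort.samples, pca_policy="bogus")
    obs = sm.pc_logistic_loocv(avg, cohort.samples)
    with pytest.raises(ConfigurationError, match="n_permutations"):
        sm.permutation_test(avg, cohort.samples, 3, obs, n_permutations=0)
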