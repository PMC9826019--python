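"""Network population training, ROC/AUC, response curves, cut-points."""



import numpy as np
import pandas as pd
import pytest

from her2refine.ann import (
    FAINT_TOTAL,
    FEATURES,
    AnnConfig,
    UnlearnableTargetError,
    derive_cutpoints,
    design_matrix,
    permutation_importance,
    response_curve,
    roc_auc,
    ruleset_from_cutpoints,
    train_population,
)
from her2refine.profiles import RefinedRuleSet
from her2refine.synthetic import GeneratorConfig, generate_binary_cohort

FAST = AnnConfig(hidden_nodes=(4, 8), n_models=4, max_rounds=12, seed=0)


@pytest.fixture(scope="module")
def small_population():
    """A compact population on a noiseless planted-rule cohort."""
    df, labels = generate_binary_cohort(220, GeneratorConfig(seed=21, rule_noise=0.0))
    return train_population(df, labels, FAST)


# ---------------------------------------------------------------------------
# roc_auc
# ---------------------------------------------------------------------------


def test_auc_trivial_cases():
    assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5
    assert roc_auc([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9]) == 0.0


def test_auc_hand_example_matches_pairwise_concordance():
    y = [1, 0, 1, 0, 1, 0]
    s = [0.9, 0.8, 0.8, 0.3, 0.2, 0.1]
    # pairs: (0.9 beats all 3 negs) + (0.8 ties 0.8, beats 0.3, 0.1 -> 2.5)
    # + (0.2 beats 0.1 only -> 1) = 6.5 of 9
    assert roc_auc(y, s) == pytest.approx(6.5 / 9)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([1, 1], [0.2, 0.3])


def test_auc_equals_brute_force_concordance(rng):
    for _ in range(100):
        n = int(rng.integers(4, 100))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            continue
        s = np.round(rng.random(n), 2)  # coarse scores force ties
        pos, neg = s[y == 1], s[y == 0]
        conc = np.mean(
            (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        )
        assert roc_auc(y, s) == pytest.approx(conc)


def test_auc_matches_sklearn(rng):
    sk = pytest.importorskip("sklearn.metrics")
    y = rng.integers(0, 2, size=200)
    y[:2] = [0, 1]
    s = rng.random(200)
    assert roc_auc(y, s) == pytest.approx(sk.roc_auc_score(y, s))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def test_population_learns_a_noiseless_planted_rule(small_population):
    assert small_population.pooled_test_auc() > 0.97
    assert small_population.classification_rate() > 0.93
    assert len(small_population.models) == FAST.n_models


def test_training_is_deterministic_given_seed():
    df, labels = generate_binary_cohort(120, GeneratorConfig(seed=3, rule_noise=0.0))
    cfg = AnnConfig(hidden_nodes=(4,), n_models=2, max_rounds=8, seed=5)
    a = train_population(df, labels, cfg)
    b = train_population(df, labels, cfg)
    assert a.pooled_test_auc() == b.pooled_test_auc()
    for ma, mb in zip(a.models, b.models):
        assert np.array_equal(ma.test_proba, mb.test_proba)
        assert ma.hidden == mb.hidden


def test_permuted_labels_yield_chance_auc(rng):
    df, labels = generate_binary_cohort(200, GeneratorConfig(seed=4, rule_noise=0.0))
    shuffled = rng.permutation(labels)
    pop = train_population(df, shuffled, FAST)
    assert pop.pooled_test_auc() == pytest.approx(0.5, abs=0.15)


def test_single_class_labels_are_unlearnable():
    df, labels = generate_binary_cohort(80, GeneratorConfig(seed=5))
    with pytest.raises(UnlearnableTargetError):
        train_population(df, ["low"] * len(df), FAST)


def test_non_finite_features_are_rejected():
    df, labels = generate_binary_cohort(80, GeneratorConfig(seed=5))
    df.loc[0, "pct_weak_complete"] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        train_population(df, labels, FAST)


def test_design_matrix_adds_total_positive():
    df, _ = generate_binary_cohort(60, GeneratorConfig(seed=6))
    X = design_matrix(df)
    assert tuple(X.columns) == FEATURES
    patterns = [c for c in FEATURES if c not in ("pct_cytoplasmic", "pct_total_positive")]
    assert np.allclose(X["pct_total_positive"], X[patterns].sum(axis=1))


def test_informative_feature_ranks_first_in_participation(rng):
    """With one planted feature and nine noise columns, that feature tops
    both the univariate-AUC oracle and the derived participation ranking."""
    n = 200
    X = pd.DataFrame(0.0, index=range(n), columns=list(FEATURES))
    X["pct_weak_incomplete"] = rng.choice([0, 5, 10, 15, 20, 30], size=n)
    for col in ("pct_cytoplasmic",):
        X[col] = rng.choice([0, 5, 10, 15, 20, 30], size=n)
    labels = np.where(X["pct_weak_incomplete"] > 10, "high", "low")
    if len(set(labels)) < 2:  # pragma: no cover - guard
        pytest.skip("degenerate draw")
    pop = train_population(X.to_numpy(), labels, FAST)
    pop.feature_names = FEATURES
    uni = {c: abs(roc_auc(labels, X[c]) - 0.5) for c in ("pct_weak_incomplete", "pct_cytoplasmic")}
    assert max(uni, key=uni.get) == "pct_weak_incomplete"
    curves = [response_curve(pop, c) for c in ("pct_weak_incomplete", "pct_cytoplasmic")]
    rules = derive_cutpoints(curves)
    ranked = sorted(rules, key=lambda r: r.balanced_accuracy, reverse=True)
    assert ranked[0].parameter == "pct_weak_incomplete"
    assert ranked[0].selected and not ranked[1].selected


# ---------------------------------------------------------------------------
# response curves and cut-points
# ---------------------------------------------------------------------------


def test_faint_response_curve_crosses_half_at_the_planted_threshold(small_population):
    curve = response_curve(small_population, FAINT_TOTAL)
    p = curve.mean_predicted_probability
    g = curve.grid
    assert p[g <= 15].max() < 0.5
    assert p[(g >= 20) & (g <= 60)].min() > 0.5


def test_null_feature_curve_is_flat_where_observed(small_population):
    curve = response_curve(small_population, "pct_cytoplasmic")
    p = curve.mean_predicted_probability
    obs = curve.grid <= np.percentile(curve.values, 99)
    assert p[obs].max() - p[obs].min() < 0.2


def test_sensitivity_specificity_are_monotone_along_threshold(small_population):
    curve = response_curve(small_population, FAINT_TOTAL)
    assert np.all(np.diff(curve.sensitivity) <= 1e-12)
    assert np.all(np.diff(curve.specificity) >= -1e-12)
    assert np.all((curve.mean_predicted_probability >= 0) &
                  (curve.mean_predicted_probability <= 1))


def test_unknown_parameter_is_an_error(small_population):
    with pytest.raises(KeyError, match="unknown"):
        response_curve(small_population, "pct_nonexistent")


def test_descending_grid_is_rejected(small_population):
    with pytest.raises(ValueError, match="ascending"):
        response_curve(small_population, FAINT_TOTAL, grid=np.array([10.0, 5.0, 1.0]))


def test_cutpoints_feed_a_refined_ruleset(small_population):
    # Sweep every candidate: elimination can only reject the total-positive
    # input once the per-pattern rules jointly cover all true positives.
    from her2refine.cli import SWEEP_PARAMETERS

    curves = [response_curve(small_population, p) for p in SWEEP_PARAMETERS]
    imp = permutation_importance(small_population)
    rules = derive_cutpoints(curves, importances=imp)
    by_param = {r.parameter: r for r in rules}
    assert not by_param["pct_cytoplasmic"].selected
    assert not by_param["pct_total_positive"].selected
    ruleset = ruleset_from_cutpoints(rules)
    assert isinstance(ruleset, RefinedRuleSet)
    if by_param[FAINT_TOTAL].selected:
        assert ruleset.faint_total_threshold == by_param[FAINT_TOTAL].threshold


def test_alternative_criteria_run_and_stay_in_range(small_population):
    curves = [response_curve(small_population, FAINT_TOTAL)]
    for criterion in ("youden", "crossing", "probability"):
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                (rule,) = derive_cutpoints(curves, criterion=criterion, eliminate=False)
        assert 0.0 < rule.threshold < 100.0


def test_config_validation():
    with pytest.raises(ValueError):
        AnnConfig(n_models=0)
    with pytest.raises(ValueError):
        AnnConfig(test_fraction=1.5)
    with pytest.raises(ValueError):
        AnnConfig(hidden_nodes=(0,))
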