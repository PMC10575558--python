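"""Screening, cross-entropy objectives, sigma fitting, model comparison."""

import numpy as np
import pandas as pd
import pytest

from triconf import (
    ChoiceDistribution,
    KDESpec,
    ModelConfCache,
    ScreeningRules,
    SigmaFitter,
    SubjectData,
    behavior_summary,
    categorize_choice,
    compare_models,
    confidence_cells,
    easiest_condition,
    model_confidence_cells,
    screen_subjects,
    subject_choice_distribution,
    type1_cross_entropy,
    type2_cross_entropy,
    type2_cross_entropy_joint,
)
from triconf import SignalGrid, generate_observer
from triconf.selection import CATEGORIES


# ---------------------------------------------------------------------------
# Choice categorization
# ---------------------------------------------------------------------------


def test_categorize_choice_published_design_cases():
    coh = [0, 0.0001, 0.56]
    arr = {"lowest": 2, "second": 3, "highest": 1}
    assert categorize_choice(coh, arr, 1) == "highest"
    coh2 = [0.56, 0.72, 0.80]
    arr2 = {"lowest": 1, "second": 2, "highest": 3}
    assert categorize_choice(coh2, arr2, 2) == "second"


def test_categorize_choice_arrangement_invariance():
    coh = [0.1, 0.2, 0.3]
    for perm in [(1, 2, 3), (3, 1, 2), (2, 3, 1)]:
        arr = dict(zip(CATEGORIES, perm))
        # track the position holding "second" through the permutation
        assert categorize_choice(coh, arr, arr["second"]) == "second"


def test_categorize_choice_unresolved_tie_errors():
    with pytest.raises(ValueError, match="tie-epsilon"):
        categorize_choice([0, 0, 0.56], {"lowest": 1, "second": 2, "highest": 3}, 1)


# ---------------------------------------------------------------------------
# Screening and summaries
# ---------------------------------------------------------------------------


def _subject_with_accuracies(accs: dict[str, float], n: int = 50,
                             sid: str = "s1") -> SubjectData:
    rng = np.random.default_rng(sum(map(ord, sid)))
    rows = []
    idx = 0
    for cond, acc in accs.items():
        n_correct = int(round(acc * n))
        cats = ["highest"] * n_correct + ["second"] * (n - n_correct)
        for cat in cats:
            rows.append({
                "subject_id": sid, "trial_index": idx, "condition_id": cond,
                "coh_highest": 0.56, "coh_second": 0.0001, "coh_lowest": 0.0,
                "pos_highest": 1, "pos_second": 2, "pos_lowest": 3,
                "choice_position": 1 if cat == "highest" else 2,
                "choice_category": cat,
                "confidence_raw": rng.uniform(0, 100), "rt_ms": 500.0,
            })
            idx += 1
    return SubjectData(subject_id=sid, trials=pd.DataFrame(rows))


def test_screening_rules_partition():
    rules = ScreeningRules(easiest_condition_id="c1")
    low = _subject_with_accuracies({"c1": 0.30, "c2": 0.30, "c3": 0.30}, sid="low")
    ok = _subject_with_accuracies({"c1": 0.70, "c2": 0.43, "c3": 0.42}, sid="ok")
    inverted = _subject_with_accuracies({"c1": 0.45, "c2": 0.50, "c3": 0.44},
                                        sid="inv")
    retained, excluded = screen_subjects([low, ok, inverted], rules)
    assert [s.subject_id for s in retained] == ["ok"]
    reasons = {s.subject_id: r for s, r in excluded}
    assert "below" in reasons["low"]
    assert "surpass" in reasons["inv"]


def test_easiest_condition_is_largest_gap(design):
    assert easiest_condition(design) == "cond1"


def test_behavior_summary_matches_loop_oracle():
    s = _subject_with_accuracies({"c1": 0.8, "c2": 0.5, "c3": 0.4}, sid="x")
    summary = behavior_summary([s]).set_index("condition_id")
    for cond in ("c1", "c2", "c3"):
        sub = s.trials[s.trials["condition_id"] == cond]
        acc = sum(c == "highest" for c in sub["choice_category"]) / len(sub)
        assert summary.loc[cond, "accuracy"] == pytest.approx(acc)
    # z-scoring makes the per-subject grand mean of confidence zero
    assert s.trials["confidence_z"].mean() == pytest.approx(0.0, abs=1e-9)
    assert s.trials["confidence_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Type-1 cross entropy
# ---------------------------------------------------------------------------


def _cd(*rows, counts=None):
    return ChoiceDistribution(
        condition_ids=tuple(f"c{i}" for i in range(len(rows))),
        probs=np.array(rows), counts=None if counts is None else np.array(counts),
    )


def test_ce1_hand_values():
    p = _cd([0.5, 0.5, 0.0])
    assert type1_cross_entropy(p, p) == pytest.approx(np.log(2), abs=1e-9)
    exact = _cd([1.0, 0.0, 0.0])
    assert type1_cross_entropy(exact, exact) == pytest.approx(0.0, abs=1e-12)
    q = _cd([0.25, 0.25, 0.5])
    assert type1_cross_entropy(p, q) == pytest.approx(-np.log(0.25), abs=1e-9)


def test_ce1_infinite_on_unsupported_category():
    p = _cd([0.5, 0.5, 0.0])
    q = _cd([1.0, 0.0, 0.0])
    assert type1_cross_entropy(p, q) == np.inf


def test_ce1_rejects_unnormalized_subject():
    with pytest.raises(ValueError):
        type1_cross_entropy(_cd([0.5, 0.2, 0.0]), _cd([1 / 3, 1 / 3, 1 / 3]))


def test_ce1_gibbs_inequality_on_random_distributions():
    rng = np.random.default_rng(5)
    for _ in range(50):
        p = rng.dirichlet(np.ones(3))
        q = rng.dirichlet(np.ones(3))
        pd_ = _cd(p)
        entropy = type1_cross_entropy(pd_, pd_)
        assert type1_cross_entropy(pd_, _cd(q)) >= entropy - 1e-12


# ---------------------------------------------------------------------------
# Sigma fitting
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def fitter(design):
    return SigmaFitter(design, sim_n=2000, seed=17)


def test_fit_sigma_recovers_generating_noise(design, fitter):
    subj = generate_observer("rce", 2.0, design, n_trials_per_condition=5000,
                             seed=23)
    p = subject_choice_distribution(subj, design)
    sigma_hat, ce1, curve = fitter.fit(p, "shared")
    assert 1.7 <= sigma_hat <= 2.3
    assert ce1 == curve.min()
    assert np.all(ce1 <= curve + 1e-12)  # argmin definition


def test_maxd_models_share_fitted_sigma(design, fitter):
    subj = generate_observer("aio", 1.5, design, n_trials_per_condition=1000,
                             seed=29)
    p = subject_choice_distribution(subj, design)
    fits = {m: fitter.fit(p, m)[0] for m in ("plio", "aio", "rce")}
    assert len(set(fits.values())) == 1


def test_subject_choice_distribution_normalized(design):
    subj = generate_observer("plh", 1.0, design, n_trials_per_condition=150,
                             seed=31)
    p = subject_choice_distribution(subj, design)
    assert np.allclose(p.probs.sum(axis=1), 1.0)
    assert p.counts.tolist() == [150, 150, 150]


# ---------------------------------------------------------------------------
# Type-2 cross entropy
# ---------------------------------------------------------------------------


def test_ce2_gibbs_self_sample_is_minimal():
    rng = np.random.default_rng(11)
    subj = {("c1", "highest"): rng.standard_normal(200)}
    same = {("c1", "highest"): subj[("c1", "highest")]}
    other = {("c1", "highest"): rng.standard_normal(200) * 1.5 + 0.7}
    ce, _ = type2_cross_entropy_joint(subj, {"same": same, "other": other})
    # identical samples give identical KDEs, so the plug-in entropy of the
    # shared estimate lower-bounds every other candidate on the same grid
    assert ce["same"] < ce["other"]
    solo, info = type2_cross_entropy(subj, same)
    assert info["finite"] and np.isfinite(solo)


def test_ce2_difference_matches_gaussian_cross_entropy_oracle():
    # for equal-variance Gaussians the cross-entropy excess of a mean-shifted
    # model is (mu_p - mu_q)^2 / 2; the KDE estimator must reproduce it
    rng = np.random.default_rng(13)
    subj = {("c1", "highest"): rng.standard_normal(400)}
    near = {("c1", "highest"): rng.standard_normal(4000)}
    far = {("c1", "highest"): rng.standard_normal(4000) + 3.0}
    ce, _ = type2_cross_entropy_joint(subj, {"near": near, "far": far})
    assert ce["far"] - ce["near"] == pytest.approx(4.5, rel=0.25)


def test_ce2_infinite_when_supports_disjoint():
    rng = np.random.default_rng(17)
    subj = {("c1", "highest"): rng.standard_normal(100)}
    impossible = {("c1", "highest"): rng.standard_normal(100) + 100.0}
    ce, info = type2_cross_entropy(subj, impossible)
    assert ce == np.inf
    assert not info["finite"]


def test_ce2_skips_small_cells():
    rng = np.random.default_rng(19)
    subj = {("c1", "highest"): rng.standard_normal(100),
            ("c1", "lowest"): np.array([0.3])}  # below min_cell_count
    model = {("c1", "highest"): rng.standard_normal(500)}
    ce, info = type2_cross_entropy(subj, model)
    assert np.isfinite(ce)
    assert info["skipped_cells"] == [("c1", "lowest")]


# ---------------------------------------------------------------------------
# End-to-end comparison
# ---------------------------------------------------------------------------


def test_compare_models_self_consistency_plh(design, fitter):
    grid = SignalGrid()
    cache = ModelConfCache(design, grid, sim_n=4000, seed=101)
    subj = generate_observer("plh", 1.0, design, n_trials_per_condition=1500,
                             seed=37)
    fit = compare_models(subj, design, fitter, cache)
    assert fit.best_model == "plh"
    assert not fit.excluded_nonfinite
    assert all(v >= 0 or not np.isfinite(v) for v in fit.ce2.values())


def test_results_invariant_to_confidence_scale(design, fitter):
    grid = SignalGrid()
    cache = ModelConfCache(design, grid, sim_n=2000, seed=103)
    subj = generate_observer("rce", 1.5, design, n_trials_per_condition=300,
                             seed=41)
    rescaled_trials = subj.trials.copy()
    rescaled_trials["confidence_raw"] = (
        50.0 + 10.0 * rescaled_trials["confidence_raw"]
    )
    rescaled = SubjectData(subject_id="rescaled", trials=rescaled_trials)
    fit_a = compare_models(subj, design, fitter, cache)
    fit_b = compare_models(rescaled, design, fitter, cache)
    for m in fit_a.ce2:
        assert fit_a.ce2[m] == pytest.approx(fit_b.ce2[m], abs=1e-9)
    assert fit_a.best_model == fit_b.best_model
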