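"""Label alignment, congruence tiers, dissociation, membership regression."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rppkit import (
    GroupingResult,
    InvalidInputError,
    align_labels,
    congruence_report,
    dissociation,
    multinom_fit,
    stepwise_select,
)


def brute_best_agreement(la, lb):
    """Maximum agreement over all permutations of b's group labels."""
    groups_b = sorted(set(lb))
    best = 0
    for perm in itertools.permutations(sorted(set(la)) + [None] * max(0, len(groups_b) - len(set(la)))):
        mapping = dict(zip(groups_b, perm))
        best = max(
            best, sum(1 for x, y in zip(la, lb) if mapping[y] == x)
        )
    return best


def grouping(method, labels, k=None):
    return GroupingResult(
        method=method,
        k=k or max(labels.values()),
        labels=labels,
        objective=0.0,
    )


class TestAlignLabels:
    def test_permuted_identical_partitions(self):
        la = {f"e{i}": 1 + i % 3 for i in range(12)}
        lb = {e: {1: 3, 2: 1, 3: 2}[g] for e, g in la.items()}
        _, pct = align_labels(grouping("a", la), grouping("b", lb))
        assert pct == 100.0

    def test_one_of_ten_differs(self):
        la = {f"e{i}": 1 if i < 5 else 2 for i in range(10)}
        lb = dict(la)
        lb["e0"] = 2
        _, pct = align_labels(grouping("a", la), grouping("b", lb))
        assert pct == pytest.approx(90.0)

    def test_matches_exhaustive_permutation_maximum(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            n = 100
            la_arr = rng.integers(1, 5, n)
            lb_arr = rng.integers(1, 5, n)
            la = {f"e{i}": int(g) for i, g in enumerate(la_arr)}
            lb = {f"e{i}": int(g) for i, g in enumerate(lb_arr)}
            _, pct = align_labels(grouping("a", la), grouping("b", lb))
            assert pct == pytest.approx(
                100.0 * brute_best_agreement(la_arr, lb_arr) / n
            )

    def test_disjoint_element_sets_rejected(self):
        with pytest.raises(InvalidInputError):
            align_labels(
                grouping("a", {"x": 1, "y": 2}), grouping("b", {"p": 1, "q": 2})
            )

    def test_symmetry_of_agreement(self):
        rng = np.random.default_rng(8)
        la = {f"e{i}": int(g) for i, g in enumerate(rng.integers(1, 4, 30))}
        lb = {f"e{i}": int(g) for i, g in enumerate(rng.integers(1, 4, 30))}
        _, ab = align_labels(grouping("a", la), grouping("b", lb))
        _, ba = align_labels(grouping("b", lb), grouping("a", la))
        assert ab == pytest.approx(ba)


class TestCongruenceReport:
    def test_four_identical_groupings(self):
        labels = {f"e{i}": 1 + i % 3 for i in range(12)}
        gs = [grouping(m, dict(labels)) for m in ("kmeans", "gbtm", "dtw_hclust", "ed_hclust")]
        rep = congruence_report(gs)
        off_diag = rep.pairwise.values[~np.eye(4, dtype=bool)]
        assert np.allclose(off_diag, 100.0)
        assert rep.tiers[4] == 100.0
        assert all(rep.overall[m] == pytest.approx(300.0) for m in rep.overall)

    def test_two_groupings_overall_equals_pairwise(self):
        la = {f"e{i}": 1 if i < 6 else 2 for i in range(10)}
        lb = dict(la)
        lb["e9"] = 1
        rep = congruence_report([grouping("kmeans", la), grouping("gbtm", lb)])
        assert rep.overall["kmeans"] == pytest.approx(rep.pairwise.loc["kmeans", "gbtm"])

    def test_constructed_tier_counts(self):
        # 10 elements; methods m2-m4 copy the reference except for controlled
        # disagreements: e0 differs in one method, e1 in two methods
        ref = {f"e{i}": 1 + i % 2 for i in range(10)}
        m2 = dict(ref)
        m2["e0"] = 3
        m3 = dict(ref)
        m3["e1"] = 3
        m4 = dict(ref)
        m4["e1"] = 4
        gs = [
            grouping("kmeans", ref, k=4),
            grouping("gbtm", m2, k=4),
            grouping("dtw_hclust", m3, k=4),
            grouping("ed_hclust", m4, k=4),
        ]
        rep = congruence_report(gs)
        assert rep.tiers[4] == pytest.approx(80.0)  # 8 untouched elements
        assert rep.tiers[3] == pytest.approx(10.0)  # e0
        assert rep.tiers[2] == pytest.approx(10.0)  # e1
        assert rep.reference == "kmeans"


class TestDissociation:
    def test_caption_rule_signatures(self):
        labels = {}
        # specimen A: 4 bones all one group -> "0"
        for i in range(4):
            labels[f"A:{i}"] = 1
        # specimen B: 4 bones split 1 and 3 -> "1-3"
        labels.update({"B:0": 2, "B:1": 1, "B:2": 1, "B:3": 1})
        # specimen C: 6 bones split 1/2/3 -> "1-2-3"
        labels.update(
            {"C:0": 1, "C:1": 2, "C:2": 2, "C:3": 3, "C:4": 3, "C:5": 3}
        )
        g = grouping("kmeans", labels, k=3)
        spec_map = {e: e.split(":")[0] for e in labels}
        sigs = {s.specimen_id: s for s in dissociation(g, spec_map)}
        assert sigs["A"].signature == "0" and sigs["A"].level == 1
        assert sigs["B"].signature == "1-3" and sigs["B"].level == 2
        assert sigs["C"].signature == "1-2-3" and sigs["C"].level == 3

    def test_counts_sum_and_relabelling_invariance(self):
        rng = np.random.default_rng(4)
        labels = {f"s{i // 5}:{i}": int(g) for i, g in enumerate(rng.integers(1, 5, 40))}
        spec_map = {e: e.split(":")[0] for e in labels}
        g1 = grouping("kmeans", labels, k=4)
        perm = {1: 4, 2: 3, 3: 1, 4: 2}
        g2 = grouping("kmeans", {e: perm[v] for e, v in labels.items()}, k=4)
        sig1 = {s.specimen_id: s.signature for s in dissociation(g1, spec_map)}
        sig2 = {s.specimen_id: s.signature for s in dissociation(g2, spec_map)}
        assert sig1 == sig2
        for s in dissociation(g1, spec_map):
            if s.signature != "0":
                assert sum(int(c) for c in s.signature.split("-")) == s.n_bones

    def test_unmapped_element_rejected(self):
        g = grouping("kmeans", {"e1": 1, "e2": 2})
        with pytest.raises(InvalidInputError):
            dissociation(g, {"e1": "s1"})


def softmax_sample(rng, X, betas):
    eta = X @ betas  # (n, C) with class 0 as reference column of zeros
    P = np.exp(eta - eta.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    return np.array([rng.choice(P.shape[1], p=p) + 1 for p in P]), P


def synth_membership(seed=0, n=200):
    """Labels drawn from a known softmax in age + dev_strategy, plus a
    pure-noise numeric predictor; returns (labels, design, betas, bayes%)."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(0, 50, n)
    dev = rng.choice(["altricial", "precocial"], n)
    X = np.column_stack([np.ones(n), age, (dev == "precocial").astype(float)])
    betas = np.array(
        [[0.0, -3.0, -6.0], [0.0, 0.12, 0.18], [0.0, 1.0, -0.5]]
    )  # features x classes (class 1 reference)
    y, P = softmax_sample(rng, X, betas)
    ids = [f"e{i}" for i in range(n)]
    design = pd.DataFrame(
        {"age": age, "dev": dev, "noise": rng.normal(size=n)}, index=ids
    )
    labels = grouping("kmeans", dict(zip(ids, map(int, y))), k=3)
    bayes = 100.0 * float(P.max(axis=1).mean())
    return labels, design, betas, bayes


class TestMultinomFit:
    def synth(self, seed=0, n=200):
        return synth_membership(seed, n)

    def test_coefficient_recovery_within_2_se(self):
        labels, design, betas, _ = self.synth(seed=3)
        fit = multinom_fit(labels, design, ["age", "dev"])
        est = fit.coef.to_numpy()
        se = fit.se.to_numpy()
        assert np.all(np.abs(est - betas[:, 1:]) <= 2 * se)

    def test_pm_close_to_bayes_rate(self):
        labels, design, _, bayes = self.synth(seed=4)
        fit = multinom_fit(labels, design, ["age", "dev"])
        assert fit.pm_percent >= bayes - 5.0

    def test_intercept_only_predicts_modal_class(self):
        labels, design, _, _ = self.synth(seed=5)
        design = design.assign(const=1.0)
        fit = multinom_fit(labels, design, [])
        counts = pd.Series(list(labels.labels.values())).value_counts()
        modal = counts.index[0]
        assert set(fit.fitted.values()) == {modal}
        assert fit.pm_percent == pytest.approx(100.0 * counts.iloc[0] / fit.n)

    def test_aic_aicc_closed_forms(self):
        labels, design, _, _ = self.synth(seed=6, n=60)
        fit = multinom_fit(labels, design, ["age"])
        p = fit.n_parameters
        assert p == 2 * 2  # (C-1)=2 classes x (intercept + age)
        assert fit.aic == pytest.approx(2 * p - 2 * fit.log_lik)
        assert fit.aicc == pytest.approx(
            fit.aic + 2 * p * (p + 1) / (fit.n - p - 1)
        )
        assert fit.aicc >= fit.aic

    def test_matches_statsmodels_loglik(self):
        sm = pytest.importorskip("statsmodels.api")
        labels, design, _, _ = self.synth(seed=7, n=150)
        fit = multinom_fit(labels, design, ["age", "dev"])
        y = np.array([labels.labels[i] for i in design.index]) - 1
        X = pd.DataFrame(
            {
                "const": 1.0,
                "age": design["age"],
                "dev": (design["dev"] == "precocial").astype(float),
            }
        )
        ref = sm.MNLogit(y, X).fit(disp=0)
        assert fit.log_lik == pytest.approx(ref.llf, abs=1e-3)

    def test_separable_predictor_flags_warning(self):
        ids = [f"e{i}" for i in range(40)]
        group = np.array([1] * 20 + [2] * 20)
        design = pd.DataFrame(
            {"flag": ["x"] * 20 + ["y"] * 20}, index=ids
        )
        labels = grouping("kmeans", dict(zip(ids, map(int, group))), k=2)
        fit = multinom_fit(labels, design, ["flag"])
        assert fit.pm_percent == 100.0
        assert fit.separation_warning

    def test_single_class_rejected(self):
        ids = ["a", "b"]
        design = pd.DataFrame({"x": [1.0, 2.0]}, index=ids)
        with pytest.raises(InvalidInputError):
            multinom_fit(grouping("kmeans", {"a": 1, "b": 1}, k=1), design)


class TestStepwise:
    def test_noise_predictor_is_first_drop_candidate(self):
        # backward elimination must rank the pure-noise predictor as the most
        # expendable: of all single-drop models the one without noise has the
        # lowest AIC (whether the drop is accepted depends on chance
        # correlation, an intrinsic property of AIC)
        t = TestMultinomFit()
        labels, design, _, _ = t.synth(seed=11)
        res = stepwise_select(labels, design, ["age", "dev", "noise"])
        step1 = res.path[res.path["step"] == 1]
        best = step1.loc[step1["AIC"].idxmin(), "model"]
        assert "noise" not in best

    def test_single_predictor_model_path(self):
        t = TestMultinomFit()
        labels, design, _, _ = t.synth(seed=12)
        res = stepwise_select(labels, design, ["age"])
        assert res.aic_best.predictors == ("age",)
        assert res.path["model"].iloc[0].endswith("age")

    def test_path_table_columns(self):
        t = TestMultinomFit()
        labels, design, _, _ = t.synth(seed=13)
        res = stepwise_select(labels, design, ["age", "dev"])
        assert {"model", "AIC", "AICc", "PM%"} <= set(res.path.columns)

    def test_best_model_pm_not_below_intercept_only(self):
        t = TestMultinomFit()
        for seed in (20, 21, 22):
            labels, design, _, _ = t.synth(seed=seed)
            res = stepwise_select(labels, design, ["age", "dev", "noise"])
            base = multinom_fit(labels, design.assign(z=0.0), [])
            assert res.aic_best.pm_percent >= base.pm_percent
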