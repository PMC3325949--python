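import itertools

import numpy as np
import pandas as pd
import pytest

from parkoct import (CombinedRule, ThresholdRule, candidate_cutoffs,
                     evaluate_named_rule_in_context, psp_rule, search_rules)
from parkoct.search import SearchSpace


def small_features(rng, n=8, features=("f1", "f2", "f3")):
    rows = []
    for i in range(n):
        row = {"subject_id": f"s{i}", "group": "PSP" if i < n // 2 else "PD"}
        for f in features:
            row[f] = float(np.round(rng.uniform(10, 50), 1))
        rows.append(row)
    return pd.DataFrame(rows)


def small_space(features=("f1", "f2", "f3")):
    return SearchSpace(base_features=tuple(features), ratio_pairs=(),
                       max_components=2, max_cutoffs_conjunction=None)


def brute_force(features, space, positive_group="PSP"):
    """Independent enumeration of every rule's (sens, spec) by direct count."""
    is_pos = (features["group"] == positive_group).to_numpy()
    singles = []
    for f in space.base_features:
        v = features[f].to_numpy(dtype=float)
        u = np.unique(v)
        cuts = [(a + b) / 2 for a, b in zip(u[:-1], u[1:])]
        for c in cuts:
            for direction in ("below", "above"):
                singles.append((f, direction, c))

    def decide(f, direction, c):
        v = features[f].to_numpy(dtype=float)
        return v < c if direction == "below" else v > c

    out = []
    for spec_tuple in singles:
        d = decide(*spec_tuple)
        out.append(((spec_tuple,), _counts(d, is_pos)))
    for s1, s2 in itertools.combinations(singles, 2):
        if s1[0] == s2[0]:
            continue
        d = decide(*s1) & decide(*s2)
        out.append(((s1, s2), _counts(d, is_pos)))
    return out


def _counts(decisions, is_pos):
    tp = int((decisions & is_pos).sum())
    fn = int((~decisions & is_pos).sum())
    fp = int((decisions & ~is_pos).sum())
    tn = int((~decisions & ~is_pos).sum())
    sens, spec = tp / (tp + fn), tn / (tn + fp)
    return sens, spec


class TestCandidateCutoffs:
    def test_midpoints(self):
        assert candidate_cutoffs([1.0, 2.0, 4.0]).tolist() == [1.5, 3.0]

    def test_all_identical_empty(self):
        assert candidate_cutoffs([5.0, 5.0, 5.0]).size == 0

    def test_n_distinct_gives_n_minus_one(self, rng):
        v = rng.permutation(np.arange(17.0))
        assert candidate_cutoffs(v).size == 16

    def test_duplicates_collapse(self):
        assert candidate_cutoffs([1.0, 1.0, 2.0]).tolist() == [1.5]


class TestOracleEquivalence:
    def test_full_search_matches_brute_force(self, rng):
        """On ≤10 subjects / ≤3 features the search equals direct enumeration."""
        feats = small_features(rng, n=8)
        space = small_space()
        ranked = search_rules(feats, "PSP", ["PD"], space=space, top_k=None)
        oracle = brute_force(feats, space)
        assert len(ranked) == len(oracle)
        mine = sorted(round(r.metrics.sensitivity + r.metrics.specificity - 1,
                            10) for r in ranked)
        theirs = sorted(round(s + p - 1, 10) for _, (s, p) in oracle)
        assert mine == theirs
        # best criterion value agrees exactly
        assert ranked[0].criterion_value == pytest.approx(
            max(s + p - 1 for _, (s, p) in oracle))

    def test_perfect_separator_found_as_single_rule(self, rng):
        feats = small_features(rng, n=10)
        feats["f1"] = np.where(feats["group"] == "PSP", 10.0, 30.0) + \
            rng.uniform(0, 1, len(feats))
        ranked = search_rules(feats, "PSP", ["PD"], space=small_space(),
                              top_k=5)
        top = ranked[0]
        assert top.criterion_value == pytest.approx(1.0)
        assert len(top.rule.components) == 1
        assert top.rule.components[0].feature == "f1"

    def test_constant_features_give_empty_space_error(self):
        feats = pd.DataFrame({"subject_id": list("abcd"),
                              "group": ["PSP", "PSP", "PD", "PD"],
                              "f1": [3.0] * 4})
        ranked = search_rules(feats, "PSP", ["PD"],
                              space=small_space(("f1",)), top_k=None)
        assert ranked == []


class TestInvariances:
    def test_subject_order_invariance(self, rng):
        feats = small_features(rng)
        r1 = search_rules(feats, "PSP", ["PD"], space=small_space(),
                          top_k=None)
        r2 = search_rules(feats.iloc[::-1].reset_index(drop=True), "PSP",
                          ["PD"], space=small_space(), top_k=None)
        assert [x.criterion_value for x in r1] == \
            [x.criterion_value for x in r2]
        assert [x.rule.describe() for x in r1[:10]] == \
            [x.rule.describe() for x in r2[:10]]

    def test_affine_monotone_transform_preserves_decision_sets(self, rng):
        feats = small_features(rng)
        transformed = feats.copy()
        transformed["f1"] = 3.0 * transformed["f1"] + 7.0
        r1 = search_rules(feats, "PSP", ["PD"], space=small_space(),
                          top_k=None)
        r2 = search_rules(transformed, "PSP", ["PD"], space=small_space(),
                          top_k=None)
        assert sorted(round(x.criterion_value, 10) for x in r1) == \
            sorted(round(x.criterion_value, 10) for x in r2)

    def test_conjunction_never_gains_sensitivity_or_loses_specificity(
            self, rng):
        """Adding a component can only shrink the positive set."""
        feats = small_features(rng, n=10)
        ranked = search_rules(feats, "PSP", ["PD"], space=small_space(),
                              top_k=None)
        singles = {r.rule.components[0]: r.metrics
                   for r in ranked if len(r.rule.components) == 1}
        pairs = [r for r in ranked if len(r.rule.components) == 2]
        assert pairs, "search should enumerate conjunctions"
        for r in pairs:
            for comp in r.rule.components:
                m1 = singles[comp]
                assert r.metrics.sensitivity <= m1.sensitivity + 1e-12
                assert r.metrics.specificity >= m1.specificity - 1e-12


class TestNamedRuleContext:
    def test_degenerate_cohort_psp_rule_in_top_tie_group(
            self, degenerate_features):
        ctx = evaluate_named_rule_in_context(
            psp_rule(), degenerate_features, "PSP", ["PD"])
        assert ctx["criterion_value"] == pytest.approx(1.0)
        assert ctx["rank"] == 1          # nothing can beat J = 1
        assert ctx["best_criterion_value"] == pytest.approx(1.0)

    def test_rule_outside_space_ranked_by_insertion(self, rng):
        feats = small_features(rng)
        rule = CombinedRule((ThresholdRule("f1", "below", -1e9),))
        ctx = evaluate_named_rule_in_context(rule, feats, "PSP", ["PD"],
                                             space=small_space(("f2",)))
        assert ctx["criterion_value"] == pytest.approx(0.0)  # never positive
        assert 1 <= ctx["rank"] <= ctx["n_rules_searched"] + 1

    def test_rank_deterministic(self, study_features):
        space = SearchSpace(max_cutoffs_conjunction=8)
        c1 = evaluate_named_rule_in_context(psp_rule(), study_features,
                                            "PSP", ["PD"], space=space)
        c2 = evaluate_named_rule_in_context(psp_rule(), study_features,
                                            "PSP", ["PD"], space=space)
        assert c1["rank"] == c2["rank"]
        assert c1["criterion_value"] == c2["criterion_value"]


class TestCriteria:
    def test_lexicographic_prefers_sensitivity(self, rng):
        feats = small_features(rng, n=10)
        r_j = search_rules(feats, "PSP", ["PD"], space=small_space(),
                           criterion="youden", top_k=None)
        r_s = search_rules(feats, "PSP", ["PD"], space=small_space(),
                           criterion="sensitivity_then_specificity",
                           top_k=None)
        best_s = r_s[0].metrics
        assert best_s.sensitivity == max(r.metrics.sensitivity for r in r_j)

    def test_unknown_criterion_rejected(self, rng):
        with pytest.raises(ValueError, match="criterion"):
            search_rules(small_features(rng), "PSP", ["PD"],
                         space=small_space(), criterion="accuracy")
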