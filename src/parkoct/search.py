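"""Exhaustive threshold-rule search over retinal features.

Substantiates the claim that no other single threshold or two-feature
conjunction over the measured layers and their pairwise ratios separates
PSP from the comparison groups better than the chosen ONL/OPL + INL
rule.  The search enumerates, for every feature (and every configured
pairwise ratio), every decision-distinct cutoff (midpoints between
consecutive distinct observed values) in both directions, plus all
conjunctions of two such threshold tests on distinct features, and ranks
them by a declared criterion — Youden's J = sensitivity + specificity − 1
by default, or lexicographic (sensitivity, specificity).

All reported performance is in-sample (resubstitution): the search is
run and evaluated on the same cohort, exactly as the original analysis
was, and carries no optimism correction.

Implementation note: single-rule decisions are precomputed as boolean
matrices over the positive- and negative-class subjects; conjunction
confusion counts for *all* rule pairs then reduce to two integer matrix
products, which keeps the full quadratic enumeration tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rules import (CombinedRule, Confusion2x2, DiagnosticMetrics,
                    ThresholdRule, metrics)

#: Default base features: the per-subject layer summaries a clinician
#: could read off the same scans the rule uses.
DEFAULT_BASE_FEATURES = (
    "rnfl_mean", "mt_total", "mt_central", "mt_peripheral", "mv_total",
    "mean_rgc_ipl", "mean_inl", "mean_opl", "onl",
)

#: Default ratio pairs: all ordered pairs of the segmented-layer
#: summaries (the "ratios" arm of the claim).
DEFAULT_RATIO_PAIRS = tuple(
    (a, b)
    for a in ("onl", "mean_inl", "mean_opl", "mean_rgc_ipl")
    for b in ("onl", "mean_inl", "mean_opl", "mean_rgc_ipl")
    if a != b
)


@dataclass
class SearchSpace:
    """What the rule search enumerates.

    ``max_cutoffs_conjunction`` bounds the per-feature grid used for the
    quadratic conjunction stage (an evenly spaced subset of the midpoint
    grid); single rules always use the complete midpoint grid.  ``None``
    disables the bound (used for exact small-instance work).
    """

    base_features: tuple[str, ...] = DEFAULT_BASE_FEATURES
    ratio_pairs: tuple[tuple[str, str], ...] = DEFAULT_RATIO_PAIRS
    max_components: int = 2
    max_cutoffs_conjunction: int | None = 12

    def __post_init__(self):
        for a, b in self.ratio_pairs:
            if a == b:
                raise ValueError(f"ratio pair ({a},{b}) degenerate")
        if self.max_components not in (1, 2):
            raise ValueError("max_components must be 1 or 2")


@dataclass
class RankedRule:
    """One searched rule with its in-sample metrics and rank."""

    rule: CombinedRule
    confusion: Confusion2x2
    metrics: DiagnosticMetrics
    criterion_value: float
    rank: int = 0


def candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values.

    This is the complete set of decision-distinct thresholds for the
    observed sample: any other cutoff classifies identically to one of
    these.  All-identical input yields an empty list.
    """
    v = np.unique(np.asarray(values, dtype=float))
    v = v[~np.isnan(v)]
    if v.size < 2:
        return np.empty(0)
    return (v[:-1] + v[1:]) / 2.0


def _criterion_fn(criterion: str):
    if criterion == "youden":
        return lambda sens, spec: sens + spec - 1.0
    if criterion == "sensitivity_then_specificity":
        # lexicographic via a composite key that preserves ordering:
        # sensitivity dominates, specificity breaks ties
        return lambda sens, spec: sens + spec / 1e6
    raise ValueError(f"unknown criterion {criterion!r}")


def _feature_matrix(features: pd.DataFrame, space: SearchSpace
                    ) -> tuple[list[str], np.ndarray]:
    """Resolve base features + ratio columns to a dense value matrix."""
    names, cols = [], []
    for f in space.base_features:
        if f not in features.columns:
            raise ValueError(f"feature {f!r} not in feature table")
        names.append(f)
        cols.append(features[f].to_numpy(dtype=float))
    for a, b in space.ratio_pairs:
        name = f"ratio_{a}_over_{b}"
        num = features[a].to_numpy(dtype=float)
        den = features[b].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(den > 0, num / den, np.nan)
        names.append(name)
        cols.append(r)
    return names, np.column_stack(cols)


def _single_rules(names: list[str], X: np.ndarray,
                  space: SearchSpace, for_conjunction: bool
                  ) -> list[ThresholdRule]:
    rules = []
    for j, name in enumerate(names):
        cuts = candidate_cutoffs(X[:, j])
        if for_conjunction and space.max_cutoffs_conjunction is not None \
                and cuts.size > space.max_cutoffs_conjunction:
            idx = np.linspace(0, cuts.size - 1,
                              space.max_cutoffs_conjunction).round().astype(int)
            cuts = cuts[np.unique(idx)]
        for c in cuts:
            rules.append(ThresholdRule(name, "below", float(c)))
            rules.append(ThresholdRule(name, "above", float(c)))
    return rules


def _decisions(rules: list[ThresholdRule], names: list[str],
               X: np.ndarray) -> np.ndarray:
    """len(rules) × n matrix: 1 positive, 0 negative, NaN missing."""
    D = np.empty((len(rules), X.shape[0]))
    col = {n: i for i, n in enumerate(names)}
    for i, r in enumerate(rules):
        v = X[:, col[r.feature]]
        if r.direction == "below":
            d = (v < r.cutoff) if r.strict else (v <= r.cutoff)
        else:
            d = (v > r.cutoff) if r.strict else (v >= r.cutoff)
        D[i] = np.where(np.isnan(v), np.nan, d.astype(float))
    return D


def search_rules(features: pd.DataFrame, positive_group: str,
                 negative_groups: list[str] | tuple[str, ...],
                 space: SearchSpace | None = None,
                 criterion: str = "youden",
                 top_k: int | None = 100) -> list[RankedRule]:
    """Evaluate every rule in the space; return them ranked.

    Rows with a missing value for a rule's feature(s) are excluded from
    that rule's 2×2 table (matching :func:`parkoct.rules.confusion`).
    Ranking is total: by criterion value descending, then fewer
    components, then feature name(s), then smaller cutoff(s).
    ``top_k=None`` returns the complete ranked list.
    """
    space = space or SearchSpace()
    crit = _criterion_fn(criterion)
    neg = set(negative_groups)
    sel = features.loc[features["group"].isin(neg | {positive_group})]
    if not (sel["group"] == positive_group).any():
        raise ValueError(f"empty positive class {positive_group!r}")
    if not sel["group"].isin(neg).any():
        raise ValueError(f"empty negative class {sorted(neg)}")

    names, X = _feature_matrix(sel, space)
    is_pos = (sel["group"] == positive_group).to_numpy()

    singles = _single_rules(names, X, space, for_conjunction=False)
    results: list[RankedRule] = []

    def add(rule: CombinedRule, tp: int, fn: int, fp: int, tn: int):
        if tp + fn == 0 or tn + fp == 0:
            return
        c = Confusion2x2(tp, fp, tn, fn)
        m = metrics(c)
        results.append(RankedRule(rule, c, m,
                                  crit(m.sensitivity, m.specificity)))

    D = _decisions(singles, names, X)
    Dpos, Dneg = D[:, is_pos], D[:, ~is_pos]
    tp_s = np.nansum(Dpos == 1, axis=1).astype(int)
    fn_s = np.nansum(Dpos == 0, axis=1).astype(int)
    fp_s = np.nansum(Dneg == 1, axis=1).astype(int)
    tn_s = np.nansum(Dneg == 0, axis=1).astype(int)
    for i, r in enumerate(singles):
        add(CombinedRule((r,)), int(tp_s[i]), int(fn_s[i]),
            int(fp_s[i]), int(tn_s[i]))

    if space.max_components >= 2:
        conj_singles = _single_rules(names, X, space, for_conjunction=True)
        Dc = _decisions(conj_singles, names, X)
        Cpos, Cneg = Dc[:, is_pos], Dc[:, ~is_pos]
        # conjunction positive where both positive; missing where either
        # missing — encode positive=1/other=0 and valid masks, then count
        # via integer matrix products over subjects
        pos1 = (Cpos == 1).astype(np.float32)
        neg1 = (Cneg == 1).astype(np.float32)
        vpos = (~np.isnan(Cpos)).astype(np.float32)
        vneg = (~np.isnan(Cneg)).astype(np.float32)
        TP = pos1 @ pos1.T
        NP = vpos @ vpos.T          # evaluable positives per pair
        FP = neg1 @ neg1.T
        NN = vneg @ vneg.T
        feats = np.array([r.feature for r in conj_singles])
        R = len(conj_singles)
        iu, ju = np.triu_indices(R, k=1)
        distinct = feats[iu] != feats[ju]
        iu, ju = iu[distinct], ju[distinct]
        for i, j in zip(iu, ju):
            tp = int(TP[i, j]); npos = int(NP[i, j])
            fp = int(FP[i, j]); nneg = int(NN[i, j])
            add(CombinedRule((conj_singles[i], conj_singles[j])),
                tp, npos - tp, fp, nneg - fp)

    results.sort(key=_rank_key, reverse=False)
    for k, r in enumerate(results):
        r.rank = k + 1
    return results[:top_k] if top_k is not None else results


def _rank_key(r: RankedRule):
    feats = tuple(sorted(c.feature for c in r.rule.components))
    cuts = tuple(c.cutoff for c in r.rule.components)
    return (-r.criterion_value, len(r.rule.components), feats, cuts)


def evaluate_named_rule_in_context(rule: CombinedRule, features: pd.DataFrame,
                                   positive_group: str,
                                   negative_groups: list[str] | tuple[str, ...],
                                   space: SearchSpace | None = None,
                                   criterion: str = "youden") -> dict:
    """Rank a named rule (e.g. the PSP rule) within the full search.

    The named rule's criterion value is computed on the same data and its
    rank is its insertion position among all searched rules: 1 + the
    number of searched rules with a strictly greater criterion value.
    Returns a dict with the rule's metrics, criterion value, rank, the
    number of rules searched and the best searched criterion value.
    """
    from .rules import confusion as _confusion
    ranked = search_rules(features, positive_group, negative_groups,
                          space=space, criterion=criterion, top_k=None)
    crit = _criterion_fn(criterion)
    c, _ = _confusion(rule, features, positive_group, list(negative_groups))
    m = metrics(c)
    value = crit(m.sensitivity, m.specificity)
    n_better = sum(1 for r in ranked if r.criterion_value > value + 1e-12)
    return {
        "rule": rule, "metrics": m, "criterion_value": value,
        "rank": n_better + 1, "n_rules_searched": len(ranked),
        "best_criterion_value": ranked[0].criterion_value if ranked else math.nan,
    }


def ranked_rules_frame(ranked: list[RankedRule]) -> pd.DataFrame:
    """Flatten ranked rules to a DataFrame for CSV export."""
    rows = []
    for r in ranked:
        m = r.metrics
        rows.append({
            "rank": r.rank, "rule": r.rule.describe(),
            "n_components": len(r.rule.components),
            "sensitivity": m.sensitivity, "specificity": m.specificity,
            "lr_pos": m.lr_pos, "lr_neg": m.lr_neg,
            "youden_j": m.sensitivity + m.specificity - 1.0,
            "criterion_value": r.criterion_value,
            "tp": r.confusion.tp, "fp": r.confusion.fp,
            "tn": r.confusion.tn, "fn": r.confusion.fn,
            "evaluation": "in-sample (resubstitution)",
        })
    return pd.DataFrame(rows)
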