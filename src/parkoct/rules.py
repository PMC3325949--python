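"""Threshold diagnostic rules, two-by-two screening metrics and LR bands.

The screening rule of interest flags a subject as PSP when the ONL/OPL
thickness ratio falls below 3.1 *and* the mean INL is below 46 µm.  This
module provides the rule types (a directional threshold on one feature,
and conjunctions thereof), their application to a feature table with
explicit missing-data handling, confusion-matrix accumulation, the
standard screening metrics

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    LR+ = sensitivity / (1 − specificity)
    LR− = (1 − sensitivity) / specificity

and the qualitative likelihood-ratio bands: LR+ above 50 / LR− below
0.05 excellent, LR+ 10–50 / LR− 0.05–0.1 good, LR+ 2–10 / LR− 0.1–0.3
fair.  Band edges are applied half-open ([lower, upper)) for LR+ and as
<0.05 / [0.05, 0.1) / [0.1, 0.3] for LR−; this inclusivity convention is
a documented choice, as the verbal band definitions do not pin it down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


class RuleConfigError(ValueError):
    """A rule references a feature absent from the feature table."""


@dataclass(frozen=True)
class ThresholdRule:
    """A directional cut-off on one feature.

    ``below`` means the test is positive when the feature is under the
    cutoff (strictly, when ``strict``); ``above`` the reverse.
    """

    feature: str
    direction: str            # "below" | "above"
    cutoff: float
    strict: bool = True

    def __post_init__(self):
        if self.direction not in ("below", "above"):
            raise ValueError(f"direction={self.direction!r}")
        if not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    def test(self, value: float) -> float:
        """1.0 positive, 0.0 negative, NaN if the value is missing."""
        if value is None or math.isnan(value):
            return math.nan
        if self.direction == "below":
            hit = value < self.cutoff if self.strict else value <= self.cutoff
        else:
            hit = value > self.cutoff if self.strict else value >= self.cutoff
        return 1.0 if hit else 0.0

    def describe(self) -> str:
        op = {"below": "<" if self.strict else "<=",
              "above": ">" if self.strict else ">="}[self.direction]
        return f"{self.feature} {op} {self.cutoff:g}"


@dataclass(frozen=True)
class CombinedRule:
    """Conjunction of threshold rules on distinct features."""

    components: tuple[ThresholdRule, ...]

    def __post_init__(self):
        if len(self.components) < 1:
            raise ValueError("a rule needs >= 1 component")
        feats = [c.feature for c in self.components]
        if len(set(feats)) != len(feats):
            raise ValueError("conjunction components must use distinct features")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(c.feature for c in self.components)

    def describe(self) -> str:
        return " AND ".join(c.describe() for c in self.components)


def psp_rule() -> CombinedRule:
    """The PSP screening rule: ONL/OPL ratio < 3.1 AND mean INL < 46 µm.

    Both inequalities are strict; the rule direction follows the disease
    pattern (PSP shows the thinnest ONL and the thickest OPL of all
    groups, hence the lowest ratio, together with a thin INL).
    """
    return CombinedRule((
        ThresholdRule("ratio_onl_opl", "below", 3.1, strict=True),
        ThresholdRule("mean_inl", "below", 46.0, strict=True),
    ))


def apply_rule(rule: CombinedRule | ThresholdRule, row) -> float:
    """Evaluate a rule on one feature row.

    ``row`` is a mapping (or pandas Series) of feature name → value.
    Returns 1.0 (positive), 0.0 (negative) or NaN when any feature the
    rule needs is missing — such subjects are excluded from the 2×2
    table, not counted either way.
    """
    comps = rule.components if isinstance(rule, CombinedRule) else (rule,)
    result = 1.0
    for c in comps:
        if c.feature not in row:
            raise RuleConfigError(f"feature {c.feature!r} not in row")
        v = row[c.feature]
        r = c.test(float(v) if v is not None else math.nan)
        if math.isnan(r):
            return math.nan
        result = min(result, r)
    return result


@dataclass(frozen=True)
class Confusion2x2:
    """Counts of a diagnostic two-by-two table."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")


def confusion(rule: CombinedRule, features: pd.DataFrame,
              positive_group: str, negative_groups: list[str] | tuple[str, ...],
              ) -> tuple[Confusion2x2, list[dict]]:
    """Two-by-two table of a rule over a feature table.

    The positive class is ``positive_group`` (disease of interest), the
    negative class the union of ``negative_groups``.  Rows with missing
    rule features are excluded and logged.  Raises ``ValueError`` naming
    the empty class if either class has no evaluable rows.
    """
    neg = set(negative_groups)
    sel = features.loc[features["group"].isin(neg | {positive_group})]
    log: list[dict] = []
    tp = fp = tn = fn = 0
    for _, row in sel.iterrows():
        r = apply_rule(rule, row)
        if math.isnan(r):
            log.append({"subject_id": row.get("subject_id", "?"),
                        "group": row["group"],
                        "reason": "missing rule feature"})
            continue
        is_pos_class = row["group"] == positive_group
        if is_pos_class:
            tp += r == 1.0
            fn += r == 0.0
        else:
            fp += r == 1.0
            tn += r == 0.0
    if tp + fn == 0:
        raise ValueError(f"no evaluable subjects in positive class "
                         f"{positive_group!r}")
    if tn + fp == 0:
        raise ValueError(f"no evaluable subjects in negative class {sorted(neg)}")
    return Confusion2x2(int(tp), int(fp), int(tn), int(fn)), log


def _round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed LR values)."""
    if math.isnan(x) or math.isinf(x):
        return x
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Screening metrics of a 2×2 table, raw and as conventionally printed.

    ``lr_pos`` is +∞ at specificity 1 (flagged via ``lr_pos_undefined``
    False — infinite is a defined, perfect value); ``lr_neg`` is NaN and
    flagged undefined at specificity 0.
    """

    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    band_pos: str
    band_neg: str
    lr_pos_undefined: bool = False
    lr_neg_undefined: bool = False

    @property
    def sensitivity_pct(self) -> int:
        """Sensitivity in whole percent, as printed."""
        return int(_round_half_away(100.0 * self.sensitivity, 0))

    @property
    def specificity_pct(self) -> int:
        return int(_round_half_away(100.0 * self.specificity, 0))

    @property
    def lr_pos_rounded(self) -> float:
        return _round_half_away(self.lr_pos, 2)

    @property
    def lr_neg_rounded(self) -> float:
        return _round_half_away(self.lr_neg, 2)


def likelihood_ratios(sensitivity: float, specificity: float
                      ) -> tuple[float, float]:
    """LR+ and LR− from sensitivity and specificity.

    LR+ = sens/(1−spec) (+∞ at specificity 1); LR− = (1−sens)/spec
    (NaN at specificity 0).
    """
    lr_pos = math.inf if specificity == 1.0 else \
        sensitivity / (1.0 - specificity)
    lr_neg = math.nan if specificity == 0.0 else \
        (1.0 - sensitivity) / specificity
    return lr_pos, lr_neg


def lr_band(lr_pos: float, lr_neg: float) -> tuple[str, str]:
    """Qualitative band labels for a likelihood-ratio pair.

    LR+: ≥50 excellent, [10, 50) good, [2, 10) fair, else none.
    LR−: <0.05 excellent, [0.05, 0.1) good, [0.1, 0.3] fair, else none.
    """
    if math.isnan(lr_pos):
        band_pos = "none"
    elif lr_pos >= 50:
        band_pos = "excellent"
    elif lr_pos >= 10:
        band_pos = "good"
    elif lr_pos >= 2:
        band_pos = "fair"
    else:
        band_pos = "none"

    if math.isnan(lr_neg):
        band_neg = "none"
    elif lr_neg < 0.05:
        band_neg = "excellent"
    elif lr_neg < 0.1:
        band_neg = "good"
    elif lr_neg <= 0.3:
        band_neg = "fair"
    else:
        band_neg = "none"
    return band_pos, band_neg


def metrics(c: Confusion2x2) -> DiagnosticMetrics:
    """Screening metrics of a confusion table by the standard formulas."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("metrics need tp+fn > 0 and tn+fp > 0")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    lr_pos, lr_neg = likelihood_ratios(sens, spec)
    band_pos, band_neg = lr_band(lr_pos, lr_neg)
    return DiagnosticMetrics(
        sensitivity=sens, specificity=spec, lr_pos=lr_pos, lr_neg=lr_neg,
        band_pos=band_pos, band_neg=band_neg,
        lr_pos_undefined=False,
        lr_neg_undefined=math.isnan(lr_neg))


def rule_to_dict(rule: CombinedRule) -> dict:
    return {"components": [
        {"feature": c.feature, "direction": c.direction,
         "cutoff": c.cutoff, "strict": c.strict} for c in rule.components]}


def rule_from_dict(d: dict) -> CombinedRule:
    return CombinedRule(tuple(ThresholdRule(**c) for c in d["components"]))
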