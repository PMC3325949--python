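"""Group-comparison statistics for retinal parameters.

The study's statistical battery: one-way ANOVA across the five groups,
Dunnett's many-to-one post-hoc test against the control group, Tukey's
HSD across all pairs (α = 0.05 throughout), Spearman rank correlation
(test–retest and clinical-vs-retinal), and a publication-style summary
table of group means ± SEM with Dunnett significance flags.

Dunnett and Tukey p-values come from the multivariate-t and studentized-
range distributions respectively (scipy), which handle the study's
unbalanced group sizes exactly; :func:`dunnett_critical_value` offers an
independent Monte-Carlo route to the Dunnett critical point.

Eye handling is a config switch at the feature-table level: both eyes as
dependent duplicate rows (the study's stated approach) or one eye-mean
row per subject (the convention of its figures and of the diagnostic
rule).  Missing values are excluded per analysis, never imputed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import DERIVED_FEATURES
from .params_table import PANEL_FIELDS


class DegenerateDataError(ValueError):
    """All observations identical: no within-group variance to test against."""


@dataclass
class ComparisonResult:
    """One post-hoc contrast: group means, adjusted p, significance flag."""

    parameter: str
    comparison: str           # e.g. "PSP vs Control"
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    p_adjusted: float         # NaN when non-estimable
    significant: bool
    note: str = ""


def _clean_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for k, v in groups.items():
        a = np.asarray(v, dtype=float)
        out[k] = a[~np.isnan(a)]
    return out


def anova_oneway(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    ``groups`` maps group label → observations (NaNs dropped).  Requires
    ≥ 2 groups with ≥ 2 observations each.  Raises
    :class:`DegenerateDataError` when the data carry no variance at all.
    """
    g = _clean_groups(groups)
    samples = [v for v in g.values() if v.size >= 2]
    if len(samples) < 2:
        raise ValueError("ANOVA needs >= 2 groups with >= 2 observations")
    allv = np.concatenate(samples)
    if np.ptp(allv) == 0:
        raise DegenerateDataError("degenerate data: zero total variance")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def dunnett_vs_control(groups: dict[str, np.ndarray], control: str = "Control",
                       alpha: float = 0.05,
                       parameter: str = "") -> list[ComparisonResult]:
    """Dunnett many-to-one comparisons of every group against the control.

    Family-wise error is controlled at ``alpha`` through the multivariate
    t distribution with the correlation structure implied by the (possibly
    unbalanced) group sizes.  Groups with fewer than 2 observations are
    reported as non-estimable rather than dropped silently.
    """
    g = _clean_groups(groups)
    if control not in g:
        raise ValueError(f"control group {control!r} not present")
    ctrl = g[control]
    if ctrl.size < 2:
        raise ValueError(f"control group {control!r} has < 2 observations")
    others = {k: v for k, v in g.items() if k != control}
    estimable = {k: v for k, v in others.items() if v.size >= 2}

    samples = [ctrl, *estimable.values()]
    within_ss = sum(float(((v - v.mean()) ** 2).sum()) for v in samples)
    scale = max(1.0, *(float((v ** 2).sum()) for v in samples))
    if estimable and within_ss <= 1e-12 * scale:
        raise DegenerateDataError(
            "degenerate data: zero within-group variance")

    pvals: dict[str, float] = {}
    if estimable:
        # fixed rng: the multivariate-t integration is quasi-random and
        # would otherwise jitter run-to-run
        res = stats.dunnett(*estimable.values(), control=ctrl,
                            rng=np.random.default_rng(20120413))
        pvals = dict(zip(estimable.keys(), np.atleast_1d(res.pvalue)))

    out = []
    for k, v in others.items():
        p = pvals.get(k, math.nan)
        note = "" if k in estimable else "non-estimable: < 2 observations"
        out.append(ComparisonResult(
            parameter=parameter, comparison=f"{k} vs {control}",
            mean_a=float(v.mean()) if v.size else math.nan,
            mean_b=float(ctrl.mean()),
            sem_a=float(stats.sem(v)) if v.size >= 2 else math.nan,
            sem_b=float(stats.sem(ctrl)),
            n_a=int(v.size), n_b=int(ctrl.size),
            p_adjusted=float(p), significant=bool(p < alpha) if p == p else False,
            note=note))
    return out


def tukey_all_pairs(groups: dict[str, np.ndarray], alpha: float = 0.05,
                    parameter: str = "") -> list[ComparisonResult]:
    """Tukey HSD across all group pairs (studentized-range distribution)."""
    g = _clean_groups(groups)
    estimable = {k: v for k, v in g.items() if v.size >= 2}
    labels = list(estimable.keys())
    if len(labels) < 2:
        raise ValueError("Tukey needs >= 2 groups with >= 2 observations")
    res = stats.tukey_hsd(*estimable.values())

    out = []
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        p = float(res.pvalue[i, j])
        va, vb = estimable[a], estimable[b]
        out.append(ComparisonResult(
            parameter=parameter, comparison=f"{a} vs {b}",
            mean_a=float(va.mean()), mean_b=float(vb.mean()),
            sem_a=float(stats.sem(va)), sem_b=float(stats.sem(vb)),
            n_a=int(va.size), n_b=int(vb.size),
            p_adjusted=p, significant=bool(p < alpha)))
    for k, v in g.items():
        if k not in estimable:
            for other in labels:
                out.append(ComparisonResult(
                    parameter=parameter, comparison=f"{k} vs {other}",
                    mean_a=float(v.mean()) if v.size else math.nan,
                    mean_b=float(estimable[other].mean()),
                    sem_a=math.nan, sem_b=float(stats.sem(estimable[other])),
                    n_a=int(v.size), n_b=int(estimable[other].size),
                    p_adjusted=math.nan, significant=False,
                    note="non-estimable: < 2 observations"))
    return out


def dunnett_critical_value(alpha: float, k: int, df: int,
                           n_draws: int = 1_000_000,
                           seed: int = 20120413) -> float:
    """Two-sided Dunnett critical value for a balanced design, by Monte Carlo.

    Draws ``n_draws`` realizations of the k correlated t statistics
    (pairwise correlation 1/2 in the balanced case) and returns the
    (1 − alpha) quantile of max|T|.  At 10⁶ draws the quantile is stable
    to about ±0.005; used as an independent check on the p-value route.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    block = 200_000
    maxima = []
    for start in range(0, n_draws, block):
        m = min(block, n_draws - start)
        common = rng.standard_normal((m, 1))
        z = (common + rng.standard_normal((m, k))) / np.sqrt(2.0)
        chi = rng.chisquare(df, size=(m, 1))
        t = z / np.sqrt(chi / df)
        maxima.append(np.abs(t).max(axis=1))
    out = np.concatenate(maxima)
    return float(np.quantile(out, 1.0 - alpha))


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing value in either variable are removed first;
    n ≥ 3 pairs are required.  The p-value is exact (full permutation
    distribution of the ranks) for n ≤ 9 and the standard t-distribution
    approximation for larger n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("spearman needs >= 3 complete pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return math.nan, math.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        p = _exact_perm_pvalue(rx, ry, rho)
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), n - 2)) if abs(rho) < 1 else 0.0
    return rho, p


def _exact_perm_pvalue(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for the rank correlation (n ≤ 9)."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]                      # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry.mean()
    num = ryc @ rxc
    den = math.sqrt((rxc ** 2).sum()) * np.sqrt((ryc ** 2).sum(axis=1))
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


DEFAULT_SUMMARY_PARAMS = tuple(DERIVED_FEATURES) + PANEL_FIELDS


def summary_table(features: pd.DataFrame,
                  parameters: tuple[str, ...] = DEFAULT_SUMMARY_PARAMS,
                  control: str = "Control", alpha: float = 0.05,
                  eye_handling: str = "subject_means") -> pd.DataFrame:
    """Publication-style summary: per-parameter group means ± SEM with flags.

    For every parameter, reports each group's mean and SEM plus a boolean
    ``<group>_sig`` flag marking a Dunnett-adjusted p below ``alpha``
    against the control — the flagging rule of the published table.
    Parameters with no within-group variance are reported unflagged with
    a note instead of erroring (zero variance admits no test).

    ``features`` is the output of
    :func:`~parkoct.features.build_feature_table` (either eye-handling
    mode; the mode used is echoed in the ``eye_handling`` attribute of
    the result for provenance).
    """
    group_labels = [control] + sorted(set(features["group"]) - {control})
    rows = []
    for param in parameters:
        if param not in features.columns:
            continue
        groups = {g: features.loc[features["group"] == g, param].to_numpy()
                  for g in group_labels if (features["group"] == g).any()}
        row: dict = {"parameter": param}
        note = ""
        for g, v in groups.items():
            v = v[~np.isnan(v)]
            row[f"{g}_mean"] = v.mean() if v.size else math.nan
            row[f"{g}_sem"] = stats.sem(v) if v.size >= 2 else math.nan
            row[f"{g}_n"] = v.size
        try:
            if control in groups and len(groups) >= 2:
                comps = dunnett_vs_control(groups, control=control,
                                           alpha=alpha, parameter=param)
                for c in comps:
                    gname = c.comparison.split(" vs ")[0]
                    row[f"{gname}_sig"] = c.significant
                    row[f"{gname}_p"] = c.p_adjusted
            else:
                note = "no comparisons: control-only data"
        except DegenerateDataError:
            note = "zero variance: comparisons skipped"
        except ValueError as e:
            note = str(e)
        if note:
            for g in groups:
                if g != control:
                    row.setdefault(f"{g}_sig", False)
                    row.setdefault(f"{g}_p", math.nan)
        row["note"] = note
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["eye_handling"] = eye_handling
    out.attrs["alpha"] = alpha
    return out
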