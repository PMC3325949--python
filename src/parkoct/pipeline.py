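"""End-to-end pipeline: simulate/read → QC → features → stats → screen → search.

One :class:`RunConfig` drives the whole analysis deterministically from a
single seed and writes a self-contained report bundle:

    subjects.csv, eyes.csv      the (synthetic or provided) cohort
    exclusions.csv              QC exclusion log
    features.csv                per-subject derived features
    summary.csv                 group means ± SEM with significance flags
    comparisons.csv             every Dunnett and Tukey contrast
    metrics.json                PSP-rule screening metrics and LR bands
    ranked_rules.csv            cutoff-search ranking (top rules)
    run.log                     config echo, versions, exclusions
"""

from __future__ import annotations

import dataclasses
import json
import math
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import Cohort, qc_filter, read_cohort, write_cohort
from .features import build_feature_table
from .group_stats import summary_table, tukey_all_pairs, dunnett_vs_control
from .rules import (CombinedRule, confusion, metrics, psp_rule,
                    rule_from_dict, rule_to_dict)
from .search import (SearchSpace, evaluate_named_rule_in_context,
                     ranked_rules_frame, search_rules)
from .simulate import GeneratorParams, default_params, simulate_cohort

PATIENT_GROUPS = ("PD", "MSA", "CBS", "PSP")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``generator_params``: "default" or a path to a JSON parameter file;
    ``rule``: "psp_default" or a path to a JSON rule spec;
    ``eye_handling``: "subject_means" or "duplicates" (for group stats;
    classification always uses subject means).
    """

    seed: int = 0
    generator_params: str = "default"
    eye_handling: str = "subject_means"
    alpha: float = 0.05
    rule: str = "psp_default"
    out_dir: str = "results/run"
    subjects_csv: str | None = None   # analyse provided data instead of simulating
    eyes_csv: str | None = None
    search_top_k: int = 100

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha={self.alpha} outside (0, 1)")
        if self.eye_handling not in ("subject_means", "duplicates"):
            raise ValueError(f"unknown eye_handling={self.eye_handling!r}")
        if (self.subjects_csv is None) != (self.eyes_csv is None):
            raise ValueError("subjects_csv and eyes_csv must be given together")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        cfg = cls(**json.loads(Path(path).read_text()))
        cfg.validate()
        return cfg


def _load_rule(spec: str) -> CombinedRule:
    if spec == "psp_default":
        return psp_rule()
    return rule_from_dict(json.loads(Path(spec).read_text()))


def _load_params(spec: str) -> GeneratorParams:
    if spec == "default":
        return default_params()
    return GeneratorParams.from_json(spec)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the bundle as a dict and writes it to disk.

    Deterministic given the seed: running the same config twice yields
    byte-identical CSV/JSON output.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"parkoct {__version__}  python {sys.version.split()[0]}",
                 f"config: {json.dumps(dataclasses.asdict(config))}"]

    stage = "cohort"
    try:
        if config.subjects_csv:
            cohort = read_cohort(config.subjects_csv, config.eyes_csv)
            log_lines.append(f"read cohort: {cohort!r}")
        else:
            params = _load_params(config.generator_params)
            cohort = simulate_cohort(params, config.seed)
            log_lines.append(f"simulated cohort: {cohort!r} (seed={config.seed})")
        write_cohort(cohort, out / "subjects.csv", out / "eyes.csv")

        stage = "qc"
        cohort, exclusions = qc_filter(cohort)
        pd.DataFrame(exclusions, columns=["kind", "subject_id", "side",
                                          "reason"]).to_csv(
            out / "exclusions.csv", index=False)
        for e in exclusions:
            log_lines.append(f"excluded: {e}")
        log_lines.append(f"after QC: {cohort!r}")

        stage = "features"
        feats_stats = build_feature_table(cohort,
                                          eye_handling=config.eye_handling)
        feats_subject = (feats_stats if config.eye_handling == "subject_means"
                         else build_feature_table(cohort, "subject_means"))
        feats_subject.to_csv(out / "features.csv", index=False,
                             float_format="%.6g")

        stage = "group_stats"
        summary = summary_table(feats_stats, alpha=config.alpha,
                                eye_handling=config.eye_handling)
        summary.insert(1, "eye_handling", config.eye_handling)
        summary.to_csv(out / "summary.csv", index=False, float_format="%.6g")
        comp_rows = []
        for param in summary["parameter"]:
            groups = {g: feats_stats.loc[feats_stats["group"] == g,
                                         param].to_numpy()
                      for g in feats_stats["group"].unique()}
            try:
                for c in dunnett_vs_control(groups, alpha=config.alpha,
                                            parameter=param):
                    comp_rows.append({"test": "dunnett",
                                      **dataclasses.asdict(c)})
                for c in tukey_all_pairs(groups, alpha=config.alpha,
                                         parameter=param):
                    comp_rows.append({"test": "tukey",
                                      **dataclasses.asdict(c)})
            except ValueError as e:   # degenerate/insufficient data
                comp_rows.append({"test": "none", "parameter": param,
                                  "note": str(e)})
        pd.DataFrame(comp_rows).to_csv(out / "comparisons.csv", index=False,
                                       float_format="%.6g")

        stage = "screen"
        rule = _load_rule(config.rule)
        metrics_doc = {"rule": rule_to_dict(rule),
                       "rule_text": rule.describe(),
                       "classification_unit": "subject (eye-averaged)",
                       "evaluation": "in-sample (resubstitution)"}
        present = set(feats_subject["group"])
        contrasts = {}
        if "PSP" in present and "PD" in present:
            contrasts["PSP_vs_PD"] = ("PSP", ["PD"])
        others = [g for g in PATIENT_GROUPS if g != "PSP" and g in present]
        if "PSP" in present and others:
            contrasts["PSP_vs_all_syndromes"] = ("PSP", others)
        for name, (pos, negs) in contrasts.items():
            c, excl = confusion(rule, feats_subject, pos, negs)
            m = metrics(c)
            metrics_doc[name] = {
                "positive_group": pos, "negative_groups": negs,
                "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                "n_excluded_missing": len(excl),
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "sensitivity_pct": m.sensitivity_pct,
                "specificity_pct": m.specificity_pct,
                "lr_pos": None if math.isinf(m.lr_pos) else m.lr_pos,
                "lr_neg": None if math.isnan(m.lr_neg) else m.lr_neg,
                "lr_pos_rounded": None if math.isinf(m.lr_pos)
                else m.lr_pos_rounded,
                "lr_neg_rounded": None if math.isnan(m.lr_neg)
                else m.lr_neg_rounded,
                "band_pos": m.band_pos, "band_neg": m.band_neg,
            }
        (out / "metrics.json").write_text(json.dumps(metrics_doc, indent=1))

        stage = "search"
        if "PSP_vs_PD" in contrasts:
            ranked = search_rules(feats_subject, "PSP", ["PD"],
                                  top_k=config.search_top_k)
            ranked_rules_frame(ranked).to_csv(out / "ranked_rules.csv",
                                              index=False,
                                              float_format="%.6g")
            ctx = evaluate_named_rule_in_context(rule, feats_subject,
                                                 "PSP", ["PD"])
            log_lines.append(
                f"named rule rank {ctx['rank']} of "
                f"{ctx['n_rules_searched']} searched (J="
                f"{ctx['criterion_value']:.3f}, best "
                f"{ctx['best_criterion_value']:.3f})")
        else:
            pd.DataFrame().to_csv(out / "ranked_rules.csv", index=False)
            log_lines.append("search skipped: PSP or PD absent")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {"out_dir": str(out), "config": dataclasses.asdict(config),
            "log": log_lines}


def report(bundle_dir: str | Path) -> str:
    """Render a human-readable markdown report from a bundle directory."""
    out = Path(bundle_dir)
    for req in ("summary.csv", "metrics.json", "ranked_rules.csv"):
        if not (out / req).exists():
            raise FileNotFoundError(f"bundle incomplete: missing {req}")
    summary = pd.read_csv(out / "summary.csv")
    metrics_doc = json.loads((out / "metrics.json").read_text())
    ranked = pd.read_csv(out / "ranked_rules.csv")

    lines = ["# Retinal-layer analysis report", ""]
    if summary.empty or not any(c.endswith("_mean") for c in summary.columns):
        lines.append("*no subjects*")
    else:
        lines.append("## Group summary (mean ± SEM; * = differs from "
                     "controls, Dunnett p < 0.05)")
        lines.append("")
        groups = [c[:-5] for c in summary.columns if c.endswith("_mean")]
        lines.append("| parameter | " + " | ".join(groups) + " |")
        lines.append("|" + "---|" * (len(groups) + 1))
        for _, row in summary.iterrows():
            cells = []
            for g in groups:
                m, s = row.get(f"{g}_mean"), row.get(f"{g}_sem")
                if pd.isna(m):
                    cells.append("—")
                    continue
                star = "*" if row.get(f"{g}_sig") is True else ""
                cells.append(f"{m:.2f} ± {s:.2f}{star}" if pd.notna(s)
                             else f"{m:.2f}{star}")
            lines.append(f"| {row['parameter']} | " + " | ".join(cells) + " |")
        lines.append("")

    lines.append(f"## Screening rule: {metrics_doc.get('rule_text', '?')}")
    lines.append("")
    for name in ("PSP_vs_PD", "PSP_vs_all_syndromes"):
        if name not in metrics_doc:
            continue
        m = metrics_doc[name]
        lr_pos = "inf" if m["lr_pos"] is None else f"{m['lr_pos_rounded']:g}"
        lr_neg = "undefined" if m["lr_neg"] is None else \
            f"{m['lr_neg_rounded']:g}"
        lines.append(
            f"- **{name.replace('_', ' ')}**: sensitivity "
            f"{m['sensitivity_pct']}%, specificity {m['specificity_pct']}%, "
            f"LR+ {lr_pos} ({m['band_pos']}), LR− {lr_neg} "
            f"({m['band_neg']})  [{m['tp']}/{m['fp']}/{m['tn']}/{m['fn']} "
            "tp/fp/tn/fn, in-sample]")
    lines.append("")

    if not ranked.empty:
        lines.append("## Cutoff search — top 10 (in-sample, resubstitution)")
        lines.append("")
        top = ranked.head(10)
        lines.append("| rank | rule | sens | spec | J |")
        lines.append("|---|---|---|---|---|")
        for _, r in top.iterrows():
            lines.append(f"| {int(r['rank'])} | {r['rule']} | "
                         f"{r['sensitivity']:.2f} | {r['specificity']:.2f} | "
                         f"{r['youden_j']:.2f} |")
    return "\n".join(lines) + "\n"
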