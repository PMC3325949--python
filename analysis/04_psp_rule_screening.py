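"""Evaluate the PSP screening rule on the simulated cohort.

The rule: ONL/OPL ratio < 3.1 AND mean INL < 46 µm ⇒ classify PSP.
Evaluated per subject (eye-averaged features) against PD alone and
against all other parkinsonian syndromes, with likelihood-ratio bands.
Also evaluates the single-feature ONL cutoff at 104 µm for comparison
(its published specificity figure is printed as "sensitivity" in the
source — an apparent typo; it is treated as specificity here).
"""

import json
from pathlib import Path

import pandas as pd

from parkoct import (CombinedRule, ThresholdRule, confusion, metrics,
                     psp_rule)

FEATURES = Path("results/features.csv")
OUT = Path("results/metrics.json")

CONTRASTS = {"PSP vs PD": ("PSP", ["PD"]),
             "PSP vs all syndromes": ("PSP", ["PD", "MSA", "CBS"])}

if __name__ == "__main__":
    feats = pd.read_csv(FEATURES)
    doc = {}
    for label, rule in (("combined ONL/OPL + INL", psp_rule()),
                        ("ONL alone < 104 µm",
                         CombinedRule((ThresholdRule("onl", "below",
                                                     104.0),)))):
        for cname, (pos, negs) in CONTRASTS.items():
            c, excl = confusion(rule, feats, pos, negs)
            m = metrics(c)
            doc[f"{label} | {cname}"] = {
                "rule": rule.describe(),
                "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                "sensitivity_pct": m.sensitivity_pct,
                "specificity_pct": m.specificity_pct,
                "lr_pos": None if m.lr_pos == float("inf")
                else m.lr_pos_rounded,
                "lr_neg": m.lr_neg_rounded,
                "band_pos": m.band_pos, "band_neg": m.band_neg,
                "evaluation": "in-sample (resubstitution)",
            }
            print(f"{label:26s} {cname:22s} sens {m.sensitivity_pct:3d}%  "
                  f"spec {m.specificity_pct:3d}%  LR+ {m.lr_pos_rounded:5.2f}"
                  f" ({m.band_pos:9s})  LR- {m.lr_neg_rounded:4.2f} "
                  f"({m.band_neg})")
    OUT.write_text(json.dumps(doc, indent=1))
    print(f"\nwrote {OUT}")
    print("a low LR- means a negative test argues strongly against PSP; "
          "the modest LR+ means a positive test is only a hint toward it")
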