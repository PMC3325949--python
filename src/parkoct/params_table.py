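"""Published per-group OCT and clinical parameters used to drive the simulator.

The study cohort consists of five diagnostic groups — controls and four
parkinsonian syndromes (PD, MSA, CBS, PSP) — for which the source study
reports, per group, the mean and the standard error of the mean (SEM) of
every acquired OCT parameter, together with the group sizes and clinical
covariates. No subject-level data were published, so these group-level
summaries are the canonical parameterization of the synthetic cohorts.

Units: all layer thicknesses and macular thicknesses in µm, macular
volumes in mm³, age in years, disease duration and follow-up in months.

Values are stored as ``(mean, sem)`` pairs; per-subject standard
deviations are reconstructed downstream as ``SEM × sqrt(n_subjects)``.
"""

from __future__ import annotations

GROUPS = ("Control", "PD", "MSA", "CBS", "PSP")

#: Number of subjects per diagnostic group in the source study.
GROUP_SIZES = {"Control": 35, "PD": 40, "MSA": 19, "CBS": 10, "PSP": 15}

#: Ordered OCT parameter names; these are exactly the per-eye panel fields.
PANEL_FIELDS = (
    # peripapillar retinal nerve fibre layer, mean + 4 quadrants (µm)
    "rnfl_mean",
    "rnfl_temporal",
    "rnfl_nasal",
    "rnfl_superior",
    "rnfl_inferior",
    # macular thickness, total/central/peripheral + 8 sectors (µm)
    "mt_total",
    "mt_central",
    "mt_peripheral",
    "mt_superior_peripheral",
    "mt_inferior_peripheral",
    "mt_temporal_peripheral",
    "mt_nasal_peripheral",
    "mt_superior_central",
    "mt_inferior_central",
    "mt_temporal_central",
    "mt_nasal_central",
    # macular volume, same layout (mm³)
    "mv_total",
    "mv_central",
    "mv_peripheral",
    "mv_superior_peripheral",
    "mv_inferior_peripheral",
    "mv_temporal_peripheral",
    "mv_nasal_peripheral",
    "mv_superior_central",
    "mv_inferior_central",
    "mv_temporal_central",
    "mv_nasal_central",
    # manually segmented layers at nasal/temporal thickest points (µm)
    "rgc_ipl_nasal",
    "rgc_ipl_temporal",
    "inl_nasal",
    "inl_temporal",
    "opl_nasal",
    "opl_temporal",
    # outer nuclear layer at its central thickest point (µm)
    "onl_central",
)

#: Volume fields (mm³); everything else in PANEL_FIELDS is a thickness (µm).
VOLUME_FIELDS = tuple(f for f in PANEL_FIELDS if f.startswith("mv_"))

# (mean, SEM) per field, in group order Control, PD, MSA, PSP, CBS below.
_T2 = {
    #                    Control          PD              MSA             PSP             CBS
    "rnfl_mean":              ((99.13, 1.587), (97.33, 1.61), (93.79, 1.92), (93.8, 2.84), (94.17, 3.32)),
    "rnfl_temporal":          ((73.89, 2.017), (73.08, 2.12), (72.37, 3.45), (65.07, 2.35), (69.3, 3.35)),
    "rnfl_nasal":             ((71.99, 2.341), (73.49, 2.40), (68.18, 2.23), (75.4, 4.58), (72.5, 3.84)),
    "rnfl_superior":          ((121.6, 2.782), (117.2, 2.70), (115.9, 3.7), (116.5, 4.77), (123.2, 4.87)),
    "rnfl_inferior":          ((126.7, 3.063), (127.2, 2.53), (118.4, 4.16), (117.1, 3.95), (118.6, 5.65)),
    "mt_total":               ((317.6, 2.691), (317.4, 2.66), (308.2, 4.13), (302.3, 5.02), (311.5, 3.30)),
    "mt_central":             ((340.9, 2.91), (341.6, 2.71), (332.3, 4.52), (322.5, 5.95), (334.9, 3.90)),
    "mt_peripheral":          ((294.3, 2.604), (293.5, 2.53), (283.9, 3.67), (280.0, 4.43), (289.3, 2.92)),
    "mt_superior_peripheral": ((296.0, 2.706), (296.3, 2.43), (284.6, 3.80), (280.3, 4.61), (294.5, 3.54)),
    "mt_inferior_peripheral": ((285.1, 2.75), (284.8, 2.39), (277.4, 3.27), (271.0, 4.44), (280.9, 2.71)),
    "mt_temporal_peripheral": ((283.6, 2.383), (283.8, 2.29), (273.7, 3.53), (273.6, 5.24), (276.0, 2.46)),
    "mt_nasal_peripheral":    ((312.1, 2.941), (310.1, 2.58), (299.4, 4.06), (291.5, 3.86), (306.5, 4.19)),
    "mt_superior_central":    ((343.1, 2.737), (343.6, 2.85), (334.7, 5.00), (326.6, 7.24), (337.0, 4.22)),
    "mt_inferior_central":    ((340.7, 3.119), (342.3, 2.90), (330.5, 4.26), (320.8, 6.32), (334.8, 3.42)),
    "mt_temporal_central":    ((333.8, 2.989), (334.0, 2.68), (327.2, 4.93), (318.5, 7.83), (326.5, 3.16)),
    "mt_nasal_central":       ((346.1, 3.166), (346.6, 2.77), (336.8, 4.50), (324.0, 4.21), (341.2, 5.21)),
    "mv_total":               ((1.01, 0.01), (1.01, 0.01), (0.99, 0.01), (0.95, 0.02), (1.00, 0.01)),
    "mv_central":             ((0.53, 0.01), (0.54, 0.01), (0.52, 0.01), (0.51, 0.01), (0.53, 0.01)),
    "mv_peripheral":          ((1.49, 0.01), (1.49, 0.02), (1.44, 0.02), (1.37, 0.02), (1.46, 0.02)),
    "mv_superior_peripheral": ((1.52, 0.01), (1.51, 0.01), (1.45, 0.02), (1.35, 0.05), (1.49, 0.03)),
    "mv_inferior_peripheral": ((1.44, 0.02), (1.47, 0.02), (1.41, 0.02), (1.28, 0.04), (1.42, 0.02)),
    "mv_temporal_peripheral": ((1.43, 0.02), (1.42, 0.02), (1.39, 0.02), (1.34, 0.04), (1.39, 0.02)),
    "mv_nasal_peripheral":    ((1.58, 0.02), (1.55, 0.02), (1.54, 0.03), (1.47, 0.04), (1.56, 0.03)),
    "mv_superior_central":    ((0.53, 0.01), (0.53, 0.01), (0.53, 0.01), (0.51, 0.01), (0.53, 0.01)),
    "mv_inferior_central":    ((0.53, 0.01), (0.54, 0.01), (0.52, 0.01), (0.53, 0.04), (0.57, 0.04)),
    "mv_temporal_central":    ((0.52, 0.01), (0.53, 0.01), (0.51, 0.01), (0.50, 0.01), (0.51, 0.01)),
    "mv_nasal_central":       ((0.54, 0.01), (0.54, 0.01), (0.53, 0.01), (0.51, 0.01), (0.54, 0.01)),
    "rgc_ipl_nasal":          ((103.1, 1.58), (102.5, 1.50), (97.23, 1.49), (89.96, 2.86), (97.11, 1.87)),
    "rgc_ipl_temporal":       ((94.26, 1.73), (97.06, 1.25), (94.93, 2.79), (84.54, 2.72), (91.72, 2.65)),
    "inl_nasal":              ((44.63, 0.89), (48.19, 1.04), (44.1, 1.483), (40.43, 1.40), (46.28, 3.62)),
    "inl_temporal":           ((40.96, 0.65), (45.4, 1.01), (40.07, 1.84), (38.32, 0.87), (41.0, 3.03)),
    "opl_nasal":              ((36.14, 1.59), (35.21, 0.84), (34.53, 1.56), (43.5, 3.25), (41.17, 4.60)),
    "opl_temporal":           ((33.03, 0.93), (32.26, 0.76), (34.23, 1.61), (32.93, 0.75), (35.56, 1.83)),
    "onl_central":            ((105.1, 1.71), (105.8, 2.46), (104.0, 2.29), (93.92, 2.17), (116.3, 4.49)),
}

_T2_GROUP_ORDER = ("Control", "PD", "MSA", "PSP", "CBS")

#: {group: {field: (mean, sem)}} for all OCT panel fields.
OCT_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    g: {f: _T2[f][i] for f in PANEL_FIELDS} for i, g in enumerate(_T2_GROUP_ORDER)
}

#: Clinical covariates (mean, SEM) per patient group.  Controls have no
#: published clinical table; their age is set to match the patient groups
#: (the study recruited age- and sex-matched controls) — this control entry
#: is a synthetic choice, not a published value.
CLINICAL_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "PD":  {"age": (61.2, 2.0), "duration_months": (8.1, 0.8),
            "followup_months": (30.8, 3.0), "hy": (2.5, 0.2),
            "updrs_on": (18.4, 1.3), "updrs_off": (35.7, 3.3)},
    "MSA": {"age": (63.2, 1.7), "duration_months": (4.3, 0.1),
            "followup_months": (23.2, 3.7), "hy": (3.2, 0.2),
            "updrs_on": (36.4, 3.8), "updrs_off": (33.4, 4.4)},
    "CBS": {"age": (63.2, 2.4), "duration_months": (2.7, 1.5),
            "followup_months": (18.4, 3.7), "hy": (2.3, 0.3),
            "updrs_on": (27.2, 4.5), "updrs_off": (35.0, 5.7)},
    "PSP": {"age": (71.3, 1.5), "duration_months": (4.3, 3.3),
            "followup_months": (16.7, 3.6), "hy": (2.8, 0.3),
            "updrs_on": (29.2, 3.5), "updrs_off": (36.0, 5.6)},
    "Control": {"age": (64.0, 1.5)},
}
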