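"""Synthetic five-group OCT cohort generator.

The study's subject-level data were never deposited; only group means,
SEMs and group sizes are published.  This module turns those summaries
into a generative model so the whole downstream pipeline (features, group
statistics, diagnostic rules, cutoff search) can be exercised end to end.

Model
-----
For each diagnostic group, a subject's latent layer panel is multivariate
normal with the published group mean vector and covariance
``SD_i · SD_j · (rho_layers + (1 − rho_layers)·1[i = j])`` — an
exchangeable between-layer correlation, since the study reports no
covariance structure.  Per-subject SDs are reconstructed from the
published SEMs as ``SEM × sqrt(n_subjects)``.  The two eyes of a subject
share the latent panel through

    eye = mean + SD · (sqrt(rho_eyes)·Z_subject + sqrt(1 − rho_eyes)·Z_eye)

with ``Z_subject`` and the per-eye ``Z_eye`` each carrying the
between-layer correlation, so every eye has exactly the target marginal
mean/SD, the within-eye between-layer correlation is ``rho_layers`` and
the between-eye correlation of the same layer is ``rho_eyes``.

Thicknesses are truncated below at 1 µm by resampling the offending
entries (no point mass at the bound); at the published means/SDs this is
essentially never triggered.  Clinical covariates are drawn independently
of the layers, matching the study's finding of no correlation between
disease duration or UPDRS-III and any retinal layer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, EYE_COLUMNS, SUBJECT_COLUMNS
from .params_table import (CLINICAL_PARAMS, GROUP_SIZES, GROUPS, OCT_PARAMS,
                           PANEL_FIELDS, VOLUME_FIELDS)

CLINICAL_FIELDS = ("age", "duration_months", "followup_months",
                   "hy", "updrs_on", "updrs_off")

# clamp ranges for clinical covariates (lo, hi)
_CLINICAL_RANGE = {
    "age": (18.0, 100.0),
    "duration_months": (0.1, 600.0),
    "followup_months": (0.1, 600.0),
    "hy": (1.0, 5.0),
    "updrs_on": (0.0, 108.0),
    "updrs_off": (0.0, 108.0),
}


class ParameterError(ValueError):
    """Invalid generator parameters (e.g. a non-PSD layer correlation)."""


@dataclass
class GroupParams:
    """Distribution parameters for one diagnostic group.

    ``mean`` and ``sd`` map panel-field name → value (µm or mm³); ``sd``
    is the per-subject standard deviation, already scaled from the SEM.
    ``clinical_mean``/``clinical_sd`` cover the covariates present for
    the group.
    """

    group: str
    n_subjects: int
    mean: dict[str, float]
    sd: dict[str, float]
    clinical_mean: dict[str, float] = field(default_factory=dict)
    clinical_sd: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ParameterError(f"{self.group}: n_subjects must be > 0")
        for f, m in self.mean.items():
            if not m > 0:
                raise ParameterError(f"{self.group}: mean[{f}]={m} must be > 0")
        for f, s in self.sd.items():
            if s < 0:
                raise ParameterError(f"{self.group}: sd[{f}]={s} must be >= 0")


@dataclass
class GeneratorParams:
    """Full parameter bundle for :func:`simulate_cohort`.

    Parameters
    ----------
    groups : dict
        Per-group :class:`GroupParams`.
    rho_layers : float
        Exchangeable between-layer correlation in [0, 1).  Ignored if
        ``layer_corr`` is given.
    rho_eyes : float
        Correlation between the two eyes of one subject, in [0, 1].
    quality_db_mean, quality_db_sd, quality_db_floor : float
        Scan-quality distribution (dB); quality is resampled above the
        floor, which defaults to the study's 20 dB exclusion threshold
        so generated cohorts pass QC unchanged.
    layer_corr : ndarray, optional
        Full between-layer correlation matrix (len(PANEL_FIELDS) square)
        for sensitivity analyses; must be positive semi-definite.
    """

    groups: dict[str, GroupParams]
    rho_layers: float = 0.3
    rho_eyes: float = 0.8
    quality_db_mean: float = 25.0
    quality_db_sd: float = 3.0
    quality_db_floor: float = 20.0
    layer_corr: np.ndarray | None = None

    def validate(self) -> None:
        if not 0.0 <= self.rho_layers < 1.0:
            raise ParameterError(f"rho_layers={self.rho_layers} outside [0, 1)")
        if not 0.0 <= self.rho_eyes <= 1.0:
            raise ParameterError(f"rho_eyes={self.rho_eyes} outside [0, 1]")
        for gp in self.groups.values():
            gp.validate()
        if self.layer_corr is not None:
            C = np.asarray(self.layer_corr, dtype=float)
            k = len(PANEL_FIELDS)
            if C.shape != (k, k):
                raise ParameterError(f"layer_corr must be {k}x{k}")
            if not np.allclose(C, C.T):
                raise ParameterError("layer_corr must be symmetric")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ParameterError("layer_corr is not positive semi-definite")

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.layer_corr is not None:
            d["layer_corr"] = np.asarray(self.layer_corr).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        d = dict(d)
        d["groups"] = {g: GroupParams(**gp) for g, gp in d["groups"].items()}
        if d.get("layer_corr") is not None:
            d["layer_corr"] = np.asarray(d["layer_corr"], dtype=float)
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_params() -> GeneratorParams:
    """Generator parameters matching the published study.

    Group sizes 35/40/19/10/15 (Control/PD/MSA/CBS/PSP); per-group means
    and SEMs for every OCT parameter taken from the published summary
    table, with per-subject SD reconstructed as SEM × sqrt(n_subjects);
    clinical covariates likewise.  Correlations are not published:
    rho_layers = 0.3 and rho_eyes = 0.8 are field-realistic defaults
    (retinal layer thicknesses are moderately correlated across layers
    and strongly between fellow eyes).  Scan quality 25 ± 3 dB with a
    20 dB floor.
    """
    groups = {}
    for g in GROUPS:
        n = GROUP_SIZES[g]
        oct_p = OCT_PARAMS[g]
        clin = CLINICAL_PARAMS[g]
        groups[g] = GroupParams(
            group=g,
            n_subjects=n,
            mean={f: oct_p[f][0] for f in PANEL_FIELDS},
            sd={f: oct_p[f][1] * np.sqrt(n) for f in PANEL_FIELDS},
            clinical_mean={k: v[0] for k, v in clin.items()},
            clinical_sd={k: v[1] * np.sqrt(n) for k, v in clin.items()},
        )
    return GeneratorParams(groups=groups)


# ---------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------

def _correlated_standard(rng: np.random.Generator, n: int, fields: list[str],
                         params: GeneratorParams) -> np.ndarray:
    """n × k standard normals with the configured between-layer correlation."""
    k = len(fields)
    if params.layer_corr is not None:
        idx = [PANEL_FIELDS.index(f) for f in fields]
        C = np.asarray(params.layer_corr, dtype=float)[np.ix_(idx, idx)]
        w, V = np.linalg.eigh(C)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        return rng.standard_normal((n, k)) @ L.T
    rho = params.rho_layers
    common = rng.standard_normal((n, 1))
    indiv = rng.standard_normal((n, k))
    return np.sqrt(rho) * common + np.sqrt(1.0 - rho) * indiv


def _truncate_below(rng: np.random.Generator, values: np.ndarray,
                    mean: np.ndarray, sd: np.ndarray, lo: float) -> np.ndarray:
    """Resample entries below ``lo`` from their marginal normal (rejection)."""
    bad = values < lo
    tries = 0
    while bad.any():
        idx = np.nonzero(bad)
        redraw = mean[idx[1]] + sd[idx[1]] * rng.standard_normal(idx[0].size)
        values[idx] = redraw
        bad = values < lo
        tries += 1
        if tries > 1000:  # pathological params; fall back to clipping
            values = np.clip(values, lo, None)
            break
    return values


def simulate_cohort(params: GeneratorParams, seed: int) -> Cohort:
    """Draw one synthetic cohort; identical seed ⇒ identical cohort.

    All randomness flows from a single :class:`numpy.random.SeedSequence`
    split per group, so adding or reordering groups does not perturb the
    draws of the others.
    """
    params.validate()
    root = np.random.SeedSequence(seed)
    group_seeds = root.spawn(len(params.groups))

    sub_frames, eye_frames = [], []
    counter = 0
    for (gname, gp), gseed in zip(params.groups.items(), group_seeds):
        rng = np.random.default_rng(gseed)
        n = gp.n_subjects
        fields = [f for f in PANEL_FIELDS if f in gp.mean]
        mean = np.array([gp.mean[f] for f in fields])
        sd = np.array([gp.sd.get(f, 0.0) for f in fields])

        re = params.rho_eyes
        z_subj = _correlated_standard(rng, n, fields, params)
        eye_vals = {}
        for side in ("left", "right"):
            z_eye = _correlated_standard(rng, n, fields, params)
            z = np.sqrt(re) * z_subj + np.sqrt(1.0 - re) * z_eye
            vals = mean + sd * z
            # volumes are positive too; 1 µm floor only binds thicknesses,
            # use 0.001 for volumes (mm³ scale)
            lo = np.where([f in VOLUME_FIELDS for f in fields], 1e-3, 1.0)
            bad_possible = (mean - 6 * sd < lo).any()
            if bad_possible or (vals < lo).any():
                for j, f in enumerate(fields):
                    vals[:, j:j + 1] = _truncate_below(
                        rng, vals[:, j:j + 1], mean[j:j + 1], sd[j:j + 1],
                        float(lo[j]))
            eye_vals[side] = vals

        ids = [f"{gname}-{counter + i:06d}" for i in range(n)]
        counter += n

        # clinical covariates, clamped to valid ranges
        clin = {}
        for f in CLINICAL_FIELDS:
            if f in gp.clinical_mean:
                draw = gp.clinical_mean[f] + gp.clinical_sd.get(f, 0.0) * \
                    rng.standard_normal(n)
                lo_c, hi_c = _CLINICAL_RANGE[f]
                clin[f] = np.clip(draw, lo_c, hi_c)
            else:
                clin[f] = np.full(n, np.nan)
        sex = np.where(rng.random(n) < 0.5, "F", "M")

        subs = pd.DataFrame({
            "subject_id": ids, "group": gname, "age": clin["age"], "sex": sex,
            "duration_months": clin["duration_months"],
            "followup_months": clin["followup_months"], "hy": clin["hy"],
            "updrs_on": clin["updrs_on"], "updrs_off": clin["updrs_off"],
            "visual_acuity": np.full(n, np.nan),
        }, columns=list(SUBJECT_COLUMNS))
        sub_frames.append(subs)

        for side in ("left", "right"):
            q = params.quality_db_mean + params.quality_db_sd * \
                rng.standard_normal(n)
            floor = params.quality_db_floor
            bad = q < floor
            while bad.any():
                q[bad] = params.quality_db_mean + params.quality_db_sd * \
                    rng.standard_normal(int(bad.sum()))
                bad = q < floor
            edf = pd.DataFrame({"subject_id": ids, "side": side,
                                "quality_db": q})
            panel = pd.DataFrame(eye_vals[side], columns=fields)
            for f in PANEL_FIELDS:
                edf[f] = panel[f].to_numpy() if f in panel else np.nan
            eye_frames.append(edf.loc[:, list(EYE_COLUMNS)])

    subjects = pd.concat(sub_frames, ignore_index=True)
    eyes = pd.concat(eye_frames, ignore_index=True)
    # interleave left/right per subject for readability
    eyes = eyes.sort_values(["subject_id", "side"], kind="stable",
                            ignore_index=True)
    return Cohort(subjects, eyes)
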