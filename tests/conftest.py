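import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

# property tests must behave identically on every run
settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from parkoct import (Cohort, EyeRecord, LayerPanel, Subject, build_feature_table,
                     default_params, qc_filter, simulate_cohort)
from parkoct.params_table import PANEL_FIELDS


def make_panel(**overrides) -> LayerPanel:
    """A fully populated, physiologically plausible layer panel."""
    base = {f: 100.0 for f in PANEL_FIELDS}
    base.update({f: 1.0 for f in PANEL_FIELDS if f.startswith("mv_")})
    base.update({"inl_nasal": 44.0, "inl_temporal": 41.0,
                 "opl_nasal": 36.0, "opl_temporal": 33.0,
                 "onl_central": 105.0})
    base.update(overrides)
    return LayerPanel(**base)


@pytest.fixture
def tiny_cohort() -> Cohort:
    """5 subjects (one per group), mostly two-eyed, one missing value."""
    subjects = [
        Subject("s1", "Control", age=64, sex="F", visual_acuity=1.0),
        Subject("s2", "PD", age=61, sex="M", duration_months=8.0),
        Subject("s3", "MSA", age=63, sex="F"),
        Subject("s4", "PSP", age=71, sex="M"),
        Subject("s5", "CBS", age=63, sex="F"),
    ]
    eyes = [
        EyeRecord("s1", "left", 28, make_panel(onl_central=100.0)),
        EyeRecord("s1", "right", 27, make_panel(onl_central=110.0)),
        EyeRecord("s2", "left", 25, make_panel(inl_nasal=48.0)),
        EyeRecord("s2", "right", 26, make_panel(inl_nasal=48.4)),
        EyeRecord("s3", "left", 24, make_panel()),
        EyeRecord("s4", "left", 30, make_panel(onl_central=94.0,
                                               opl_nasal=43.0)),
        EyeRecord("s4", "right", 30, make_panel(onl_central=math.nan)),
        EyeRecord("s5", "left", 22, make_panel()),
        EyeRecord("s5", "right", 21, make_panel()),
    ]
    return Cohort.from_records(subjects, eyes)


@pytest.fixture(scope="session")
def degenerate_params():
    """Published group means with all SDs forced to zero."""
    p = default_params()
    for gp in p.groups.values():
        gp.sd = {f: 0.0 for f in gp.sd}
        gp.clinical_sd = {f: 0.0 for f in gp.clinical_sd}
    p.quality_db_sd = 0.0
    return p


@pytest.fixture(scope="session")
def degenerate_cohort(degenerate_params) -> Cohort:
    return simulate_cohort(degenerate_params, seed=0)


@pytest.fixture(scope="session")
def degenerate_features(degenerate_cohort) -> pd.DataFrame:
    cohort, _ = qc_filter(degenerate_cohort)
    return build_feature_table(cohort)


@pytest.fixture(scope="session")
def study_cohort() -> Cohort:
    """One study-sized synthetic cohort at the default parameterization."""
    return simulate_cohort(default_params(), seed=20120413)


@pytest.fixture(scope="session")
def study_features(study_cohort) -> pd.DataFrame:
    cohort, _ = qc_filter(study_cohort)
    return build_feature_table(cohort)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
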