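"""Shared fixtures: frozen hand-computed oracles and small synthetic cohorts."""

from __future__ import annotations

import pytest
from hypothesis import settings

from stagedefw import GeneratorConfig, generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# Stage-representative biometry (cm) used for the hand-evaluated oracles.
STAGE_BIOMETRY = {
    "28_30": {"BPD": 7.5, "HC": 27.0, "AC": 26.0, "FL": 5.5},
    "31_33": {"BPD": 8.1, "HC": 29.4, "AC": 27.1, "FL": 6.0},
    "34_36": {"BPD": 8.6, "HC": 31.0, "AC": 30.0, "FL": 6.6},
    "37_39": {"BPD": 9.2, "HC": 32.9, "AC": 32.1, "FL": 7.1},
    "40_42": {"BPD": 9.4, "HC": 33.6, "AC": 33.5, "FL": 7.4},
}

# Hand evaluation of each printed staged equation on the biometry above,
# computed by direct arithmetic transcription of the equations
# (independent of the declarative engine) and frozen here. Grams.
ORACLE_EFW = {
    "staged_mlr_28_30": 1438.4508,
    "staged_fpr_28_30": 1451.7302,
    "staged_vm_28_30": 1451.8836,
    "staged_mlr_31_33": 1748.5587,
    "staged_fpr_31_33": 1755.5460,
    "staged_vm_31_33": 1754.2037,
    "staged_mlr_34_36": 2369.3373,
    "staged_fpr_34_36": 2374.1743,
    "staged_vm_34_36": 2360.3972,
    "staged_mlr_37_39": 2997.9039,
    "staged_fpr_37_39": 2998.3172,
    "staged_vm_37_39": 3021.4634,
    "staged_mlr_40_42": 3378.9765,
    "staged_fpr_40_42": 3374.3900,
    "staged_vm_40_42": 3393.1777,
}

# Printed aggregate validation-group comparison rows (model ->
# (systematic error %, random error %, RMSE g)); the staged row is the
# reference. Serves as a worked-example fixture for comparison arithmetic.
AGGREGATE_ROWS = {
    "hadlock_abhf": (-1.74, 7.99, 282.13),
    "hadlock_ahf": (-2.61, 7.97, 292.77),
    "hadlock_abf": (-0.92, 8.13, 278.69),
    "hadlock_ah": (-1.54, 8.46, 292.72),
    "hadlock_ab": (1.35, 8.55, 280.58),
    "hadlock_af": (-1.68, 8.34, 292.07),
    "intergrowth21_ah": (-4.83, 8.12, 330.47),
    "woo_abf": (-4.26, 8.00, 319.20),
    "woo_af": (11.93, 9.68, 480.18),
    "woo_ab": (-9.64, 7.70, 437.66),
    "combs_ahf": (-3.60, 8.03, 312.09),
    "warsof_af": (1.29, 8.72, 290.22),
    "warsof_ab": (-4.70, 8.33, 333.15),
    "vintzileos_ab": (5.02, 9.79, 357.17),
    "shepard_ab": (7.38, 9.51, 378.21),
    "jordaan_ab": (0.37, 8.55, 280.39),
    "jordaan_ah": (1.64, 9.44, 304.59),
    "jordaan_abh": (-0.47, 8.87, 292.68),
    "shinozuka_abf": (-0.63, 8.31, 281.17),
    "hsieh_abf": (-0.48, 8.70, 289.84),
    "ott_ahf": (-1.84, 8.09, 287.09),
    "new_staged": (0.31, 7.97, 266.25),
}

# Published diagnostic-accuracy rows for the staged model set at
# n = 1933: (sens %, spec %, PPV %, NPV %, +LR, -LR, overall accuracy %).
DIAGNOSTIC_ROWS = {
    "SGA": (81.97, 98.00, 81.08, 98.11, 40.98, 0.18, 96.48),
    "LGA": (74.91, 95.96, 75.46, 95.84, 18.54, 0.26, 92.96),
    "macrosomia": (78.10, 93.87, 42.27, 98.68, 12.75, 0.23, 93.02),
}


@pytest.fixture(scope="session")
def small_cohort():
    """n=2000 synthetic cohort with centile reference (seed 1)."""
    cohort, ref = generate(GeneratorConfig(n=2000, seed=1))
    return cohort, ref


@pytest.fixture(scope="session")
def midsize_cohort():
    """n=6000 synthetic cohort without centiles, for fitting tests."""
    cohort, _ = generate(GeneratorConfig(n=6000, seed=7), include_centiles=False)
    return cohort
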