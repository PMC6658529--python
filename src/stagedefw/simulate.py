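"""Synthetic delivery-cohort generator.

Emulates the statistical structure the staged-model analysis assumes:
gestational ages at delivery concentrated at term with a sparse preterm
tail, the four biometry variables growing along monotone mean curves
with correlated Gaussian deviations, and birth weight generated from
biometry through a known truth model times multiplicative log-normal
noise. A matching per-week P10/P90 birth-weight centile reference is
derived empirically from a large calibration draw of the same process,
so SGA/LGA prevalences are ~10% by construction.

The defaults encode the study conditions of the target population:
stage weights 0.19 / 0.80 / 4.13 / 60.75 / 34.14 percent for the five
3-week stages, median birth weight ~3.3 kg, weekly weight-gain velocity
peaking at 34 weeks, and 7% multiplicative noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .biometry import CentileReference, Cohort, Stage
from .formulas import FormulaSpec, StagedModelSet, default_staged_models

__all__ = [
    "GeneratorConfig",
    "generate",
    "generate_velocity_profile",
    "BIOMETRY_ANCHOR_WEEKS",
    "DEFAULT_BIOMETRY_ANCHORS",
]

#: Weeks at which the default biometry mean curves are anchored.
BIOMETRY_ANCHOR_WEEKS = tuple(range(28, 43))

#: Weekly mean biometry (cm) anchors, weeks 28..42. Values follow
#: standard third-trimester biometry charts, adjusted so that the staged
#: truth model yields a ~3.3 kg median at the default gestational-age
#: mix and a weekly weight-gain peak at 34 weeks.
DEFAULT_BIOMETRY_ANCHORS: dict[str, tuple[float, ...]] = {
    "BPD": (7.10, 7.34, 7.59, 7.85, 8.11, 8.36, 8.60, 8.81, 8.99, 9.14,
            9.27, 9.38, 9.47, 9.54, 9.60),
    "HC": (26.00, 26.85, 27.73, 28.63, 29.55, 30.45, 31.30, 32.02, 32.62,
           33.10, 33.50, 33.83, 34.10, 34.32, 34.50),
    "AC": (23.50, 24.30, 25.15, 26.10, 27.20, 28.38, 29.63, 30.68, 31.53,
           32.23, 32.83, 33.33, 33.73, 34.08, 34.38),
    "FL": (5.20, 5.40, 5.61, 5.83, 6.06, 6.30, 6.55, 6.77, 6.96, 7.12,
           7.26, 7.38, 7.48, 7.57, 7.65),
}

#: Cross-sectional SD (cm) of each biometry variable around its mean
#: curve; a mixture of biological size variation and measurement error.
DEFAULT_BIOMETRY_SD: dict[str, float] = {
    "BPD": 0.28, "HC": 0.95, "AC": 1.55, "FL": 0.24,
}

#: Stage probabilities for gestational age at delivery (28-30, 31-33,
#: 34-36, 37-39, 40-42 weeks).
DEFAULT_STAGE_WEIGHTS = (0.0019, 0.0080, 0.0413, 0.6075, 0.3414)


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort generator."""

    n: int = 19310
    seed: int = 0
    stage_weights: Sequence[float] = DEFAULT_STAGE_WEIGHTS
    noise_cv: float = 0.07
    biometry_corr: float = 0.6
    biometry_anchors: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_BIOMETRY_ANCHORS)
    )
    biometry_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOMETRY_SD)
    )
    truth: Union[StagedModelSet, FormulaSpec, None] = None  # None -> staged set
    centile_draw_n: int = 50_000

    def __post_init__(self):
        w = np.asarray(self.stage_weights, dtype=float)
        if w.size != len(Stage) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("stage_weights must be 5 non-negative values")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not -1 / 3 < self.biometry_corr < 1:
            raise ValueError("biometry_corr must make a valid 4x4 correlation")
        for var, anchors in self.biometry_anchors.items():
            a = np.asarray(anchors, dtype=float)
            if a.size != len(BIOMETRY_ANCHOR_WEEKS):
                raise ValueError(f"{var}: need {len(BIOMETRY_ANCHOR_WEEKS)} anchors")
            if np.any(np.diff(a) < 0):
                raise ValueError(f"{var}: mean anchors must be non-decreasing")

    @property
    def truth_model(self) -> Union[StagedModelSet, FormulaSpec]:
        return self.truth if self.truth is not None else default_staged_models()

    def normalized_weights(self) -> np.ndarray:
        w = np.asarray(self.stage_weights, dtype=float)
        return w / w.sum()


def _mean_curves(config: GeneratorConfig) -> dict[str, PchipInterpolator]:
    curves = {}
    wk = np.asarray(BIOMETRY_ANCHOR_WEEKS, dtype=float)
    for var, anchors in config.biometry_anchors.items():
        a = np.asarray(anchors, dtype=float)
        if np.all(a == a[0]):  # constant curve: PCHIP degenerates fine, but be explicit
            curves[var] = PchipInterpolator(wk, a, extrapolate=True)
        else:
            curves[var] = PchipInterpolator(wk, a, extrapolate=True)
    return curves


def _draw_ga(rng: np.random.Generator, config: GeneratorConfig, n: int) -> np.ndarray:
    stages = list(Stage)
    idx = rng.choice(len(stages), size=n, p=config.normalized_weights())
    lo = np.array([s.lower_wk for s in stages])[idx]
    hi = np.array([s.upper_wk for s in stages])[idx]
    u = rng.uniform(size=n)
    # uniform within stage, except the post-term stage which tapers
    # linearly to zero towards 43 weeks (deliveries past 42+0 are rare)
    ga = lo + u * (hi - lo)
    last = idx == len(stages) - 1
    if last.any():
        ga[last] = 40.0 + 3.0 * (1.0 - np.sqrt(1.0 - u[last]))
    return ga


def _draw_biometry(
    rng: np.random.Generator, config: GeneratorConfig, ga: np.ndarray
) -> pd.DataFrame:
    curves = _mean_curves(config)
    n = ga.size
    rho = config.biometry_corr
    corr = np.full((4, 4), rho)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate biometry correlation matrix") from exc
    z = rng.standard_normal((n, 4)) @ chol.T
    out = {}
    for j, var in enumerate(("BPD", "HC", "AC", "FL")):
        mean = curves[var](ga)
        sd = config.biometry_sd[var]
        vals = mean + sd * z[:, j]
        out[var.lower() + "_cm"] = np.maximum(vals, 0.3 * np.asarray(mean))
    return pd.DataFrame(out)


def _truth_weights(
    config: GeneratorConfig, df: pd.DataFrame
) -> np.ndarray:
    truth = config.truth_model
    biometry = {
        "BPD": df["bpd_cm"].to_numpy(float),
        "HC": df["hc_cm"].to_numpy(float),
        "AC": df["ac_cm"].to_numpy(float),
        "FL": df["fl_cm"].to_numpy(float),
    }
    if isinstance(truth, StagedModelSet):
        return truth.predict(df).to_numpy(float)
    return np.asarray(truth.predict(biometry), dtype=float)


def _draw_cohort_frame(
    rng: np.random.Generator, config: GeneratorConfig, n: int
) -> pd.DataFrame:
    ga = _draw_ga(rng, config, n)
    biom = _draw_biometry(rng, config, ga)
    df = pd.concat([pd.DataFrame({"ga_weeks": ga}), biom], axis=1)
    mean_w = _truth_weights(config, df)
    if config.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.noise_cv ** 2)))
        noise = np.exp(rng.normal(0.0, sigma, size=n))
    else:
        noise = 1.0
    df["birth_weight_g"] = mean_w * noise
    df["sex"] = np.where(rng.uniform(size=n) < 0.515, "M", "F")
    df["interval_days"] = rng.choice(
        4, size=n, p=(0.2145, 0.4630, 0.2047, 0.1178)
    )
    # inert clinical labels for demographic realism; never used in fitting
    df["gdm"] = rng.uniform(size=n) < 0.0366
    df["preeclampsia"] = rng.uniform(size=n) < 0.0195
    return df


def generate(
    config: GeneratorConfig, include_centiles: bool = True
) -> tuple[Cohort, Optional[CentileReference]]:
    """Generate a synthetic cohort (and its matching centile reference).

    Reproducible: the same config (including seed) yields an identical
    cohort. The centile reference comes from an independent calibration
    draw of ``centile_draw_n`` records from the same process, with
    empirical weekly P10/P90 monotonised across weeks; pass
    ``include_centiles=False`` to skip that draw.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_cohort, rng_calib = (np.random.default_rng(s) for s in ss.spawn(2))
    df = _draw_cohort_frame(rng_cohort, config, config.n)
    cohort = Cohort(
        df,
        provenance=f"synthetic cohort (n={config.n}, seed={config.seed})",
        accounting={"ingested": config.n, "analyzed": config.n},
    )
    if not include_centiles:
        return cohort, None

    calib = _draw_cohort_frame(rng_calib, config, max(config.centile_draw_n, 1000))
    weeks = np.floor(calib["ga_weeks"].to_numpy(float)).astype(int)
    rows = []
    for wk in range(28, 43):
        w = calib.loc[weeks == wk, "birth_weight_g"]
        if len(w) < 20:
            rows.append((wk, np.nan, np.nan))
            continue
        rows.append((wk, float(np.quantile(w, 0.10)), float(np.quantile(w, 0.90))))
    tab = pd.DataFrame(rows, columns=["week", "p10_g", "p90_g"])
    tab = tab.interpolate(limit_direction="both")
    # enforce centiles non-decreasing across weeks (weekly empirical
    # quantiles are noisy where the preterm tail is thin)
    tab["p10_g"] = np.maximum.accumulate(tab["p10_g"])
    tab["p90_g"] = np.maximum.accumulate(np.maximum(tab["p90_g"], tab["p10_g"] + 1.0))
    return cohort, CentileReference(tab)


def generate_velocity_profile(config: GeneratorConfig) -> pd.Series:
    """Weekly mean weight gain implied by the generator's mean curves.

    Evaluates the truth model on the noise-free mean biometry at each
    integer week 28..42 and differences consecutive weeks; the series is
    indexed by the later week (29..42, 14 increments). Under default
    anchors the gain rises to its maximum at week 34 and declines
    after — the inverse-V velocity pattern of third-trimester growth.
    """
    curves = _mean_curves(config)
    weeks = np.arange(28, 43, dtype=float)
    df = pd.DataFrame(
        {
            "ga_weeks": weeks,
            "bpd_cm": curves["BPD"](weeks),
            "hc_cm": curves["HC"](weeks),
            "ac_cm": curves["AC"](weeks),
            "fl_cm": curves["FL"](weeks),
        }
    )
    w = _truth_weights(config, df)
    inc = np.diff(w)
    return pd.Series(inc, index=np.arange(29, 43), name="weekly_gain_g")
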