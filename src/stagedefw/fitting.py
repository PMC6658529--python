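"""Fitting engines for stage-specific birth weight prediction models.

Three model families, each exposed statsmodels-style as a model class
whose ``fit()`` returns a results object:

* :class:`InteractionMLR` — ordinary least squares of log10(birth
  weight) on the four biometry variables and their pairwise products,
  reduced by backward elimination at a significance threshold.
* :class:`FractionalPolynomialModel` — for each positive composite
  predictor (e.g. AC*FL/100), a fractional-polynomial basis search over
  the Royston–Altman power set {-2, -1, -0.5, 0, 0.5, 1, 2, 3} at
  degree <= 2 (8 FP1 + 36 FP2 candidate bases, chosen by Gaussian
  deviance), followed by multivariable backward elimination on the
  log10 scale.
* :class:`VolumeModel` — intercept-free least squares on the gram
  scale, weight = a * head_volume + b * FL*AC^2, selecting the head
  volume basis among {HC^3, BPD^3, BPD*HC^2, BPD^2*HC} by residual sum
  of squares, with both coefficients required positive.

:func:`fit_staged` applies a family (or compares all three) per
3-week gestational-age stage and assembles a dispatchable
:class:`~stagedefw.formulas.StagedModelSet`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .biometry import BIOMETRY_VARS, Cohort, Stage
from .formulas import Factor, FormulaSpec, StagedModelSet, Term

__all__ = [
    "FP_POWERS",
    "FittingError",
    "SampleSizeError",
    "DesignTerm",
    "default_mlr_pool",
    "default_fpr_composites",
    "HEAD_CANDIDATES",
    "InteractionMLR",
    "FractionalPolynomialModel",
    "VolumeModel",
    "fit_mlr",
    "fit_fpr",
    "fit_vm",
    "fit_staged",
]

#: Royston–Altman fractional-polynomial power set (0 denotes log).
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


class FittingError(RuntimeError):
    """Model fitting failed (rank deficiency, no admissible candidate, ...)."""


class SampleSizeError(FittingError):
    """Too few observations for the requested candidate pool."""


@dataclass(frozen=True)
class DesignTerm:
    """A named design column convertible to a declarative formula term."""

    name: str
    factors: tuple[Factor, ...]

    def column(self, biometry: Mapping[str, np.ndarray]) -> np.ndarray:
        out = 1.0
        for f in self.factors:
            out = out * f.value(biometry)
        return np.asarray(out, dtype=float)


def _biometry_dict(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "BPD": df["bpd_cm"].to_numpy(float),
        "HC": df["hc_cm"].to_numpy(float),
        "AC": df["ac_cm"].to_numpy(float),
        "FL": df["fl_cm"].to_numpy(float),
    }


def default_mlr_pool() -> list[DesignTerm]:
    """Main effects BPD, HC, AC, FL plus the six pairwise products."""
    pool = [DesignTerm(v, (Factor((v,)),)) for v in BIOMETRY_VARS]
    for a, b in itertools.combinations(BIOMETRY_VARS, 2):
        pool.append(DesignTerm(f"{a}*{b}", (Factor((a, b)),)))
    return pool


@dataclass(frozen=True)
class Composite:
    """A positive composite predictor, e.g. AC*FL/100."""

    vars: tuple[str, ...]
    divisor: float = 1.0

    @property
    def name(self) -> str:
        base = "*".join(self.vars)
        return f"{base}/{self.divisor:g}" if self.divisor != 1 else base

    def values(self, biometry: Mapping[str, np.ndarray]) -> np.ndarray:
        out = 1.0
        for v in self.vars:
            out = out * biometry[v]
        return np.asarray(out / self.divisor, dtype=float)


def default_fpr_composites() -> list[Composite]:
    """Composite predictors for the FP search.

    The union of scaled composites appearing in the fitted staged FP
    models: pair products of the four biometry variables scaled into
    the order-one range, plus the scaled single circumferences.
    """
    return [
        Composite(("AC", "FL"), 100.0),
        Composite(("AC", "HC"), 1000.0),
        Composite(("BPD", "HC"), 100.0),
        Composite(("FL", "HC"), 100.0),
        Composite(("AC", "BPD"), 1000.0),
        Composite(("FL", "BPD"), 100.0),
        Composite(("AC",), 10.0),
        Composite(("HC",), 10.0),
    ]


#: Head-volume candidate bases for the volume-based model.
HEAD_CANDIDATES: dict[str, tuple[Factor, ...]] = {
    "HC^3": (Factor(("HC",), power=3),),
    "BPD^3": (Factor(("BPD",), power=3),),
    "BPD*HC^2": (Factor(("BPD",)), Factor(("HC",), power=2)),
    "BPD^2*HC": (Factor(("BPD",), power=2), Factor(("HC",))),
}

TRUNK_TERM = DesignTerm("FL*AC^2", (Factor(("FL",)), Factor(("AC",), power=2)))


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

def backward_eliminate(
    y: np.ndarray,
    columns: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> tuple[list[str], sm.regression.linear_model.RegressionResultsWrapper, list]:
    """Iteratively drop the least significant term until all p < alpha.

    Fits OLS with intercept on the named columns; at each step removes
    the term with the largest p-value if it is >= alpha. Ties (equal
    p-values) are broken by removing the later term in declaration
    order. Returns (retained names, final OLS results, removal trace of
    (name, p_at_removal)).
    """
    y = np.asarray(y, dtype=float)
    names = list(columns)
    trace: list[tuple[str, float]] = []
    while True:
        if names:
            X = pd.DataFrame({n: columns[n] for n in names})
            design = sm.add_constant(X, has_constant="add")
        else:
            design = pd.DataFrame({"const": np.ones(y.size)})
        res = sm.OLS(y, design).fit()
        if not names:
            return names, res, trace
        pvals = res.pvalues[names]
        # NaN p-values (degenerate/collinear columns) are treated as
        # least informative and removed first.
        pv = pvals.to_numpy()
        pv = np.where(np.isnan(pv), np.inf, pv)
        worst = pv.max()
        if worst < alpha:
            return names, res, trace
        # argmax with later-declaration tie-break
        idx = max(i for i, p in enumerate(pv) if p == worst)
        trace.append((names[idx], float(pvals.iloc[idx]) if np.isfinite(pv[idx]) else float("nan")))
        names.pop(idx)


def _check_full_rank(design: np.ndarray, context: str) -> None:
    if design.size and np.linalg.matrix_rank(design) < design.shape[1]:
        raise FittingError(f"rank-deficient design matrix in {context}")


# ---------------------------------------------------------------------------
# results objects
# ---------------------------------------------------------------------------

@dataclass
class EFWFitResults:
    """Fit results common to the three families.

    ``resid_sd`` is the residual standard deviation on the model's
    response scale (log10 grams for MLR/FPR, grams for VM).
    """

    formula: FormulaSpec
    family: str
    n_obs: int
    params: pd.Series
    pvalues: pd.Series
    resid_sd: float
    trace: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def formula_spec(self) -> FormulaSpec:
        return self.formula

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.formula.predict(_biometry_dict(df)), dtype=float)

    def summary(self) -> str:
        lines = [
            f"{self.family} birth weight model: {self.formula.name}",
            "=" * 58,
            f"n obs: {self.n_obs}    response: {self.formula.response_scale}"
            f"    resid SD: {self.resid_sd:.6g}",
            f"{'term':<28}{'coef':>14}{'p-value':>12}",
            "-" * 58,
        ]
        for name, coef in self.params.items():
            p = self.pvalues.get(name, float("nan"))
            ptxt = f"{p:>12.3g}" if np.isfinite(p) else f"{'':>12}"
            lines.append(f"{name:<28}{coef:>14.6g}{ptxt}")
        if self.trace:
            removed = ", ".join(f"{n} (p={p:.3g})" for n, p in self.trace)
            lines += ["-" * 58, f"eliminated (in order): {removed}"]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

def _as_frame(data: Union[pd.DataFrame, Cohort]) -> pd.DataFrame:
    df = data.data if isinstance(data, Cohort) else data
    if "birth_weight_g" not in df.columns or df["birth_weight_g"].isna().any():
        raise ValueError("fitting requires birth_weight_g for every record")
    if (df["birth_weight_g"] <= 0).any():
        raise ValueError("birth weights must be positive")
    return df


class InteractionMLR:
    """OLS of log10(birth weight) on biometry mains and pairwise products."""

    def __init__(
        self,
        data: Union[pd.DataFrame, Cohort],
        pool: Optional[Sequence[DesignTerm]] = None,
        name: str = "mlr",
    ):
        self.data = _as_frame(data)
        self.pool = list(pool) if pool is not None else default_mlr_pool()
        self.name = name
        if len(self.data) < 10 * len(self.pool):
            raise SampleSizeError(
                f"need >= {10 * len(self.pool)} observations for "
                f"{len(self.pool)} candidate terms, got {len(self.data)}"
            )

    def fit(self, alpha: float = 0.05) -> EFWFitResults:
        df = self.data
        biometry = _biometry_dict(df)
        y = np.log10(df["birth_weight_g"].to_numpy(float))
        columns = {t.name: t.column(biometry) for t in self.pool}
        retained, res, trace = backward_eliminate(y, columns, alpha)
        _check_full_rank(
            sm.add_constant(
                pd.DataFrame({n: columns[n] for n in retained}), has_constant="add"
            ).to_numpy(),
            "MLR fit after elimination",
        )
        by_name = {t.name: t for t in self.pool}
        terms = tuple(
            Term(coef=float(res.params[n]), factors=by_name[n].factors)
            for n in retained
        )
        spec = FormulaSpec(
            name=self.name,
            family="MLR",
            response_scale="log10_g",
            terms=terms,
            intercept=float(res.params["const"]),
        )
        return EFWFitResults(
            formula=spec,
            family="MLR",
            n_obs=len(df),
            params=res.params.rename(index={"const": "intercept"}),
            pvalues=res.pvalues.rename(index={"const": "intercept"}),
            resid_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
            trace=trace,
        )


def fp_basis(x: np.ndarray, powers: Sequence[float]) -> list[np.ndarray]:
    """Fractional-polynomial basis columns for one predictor.

    Power 0 denotes ln(x); a repeated power (p, p) yields
    {x**p, x**p * ln(x)} (so (0, 0) yields {ln x, (ln x)**2}).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise FittingError("fractional-polynomial basis requires positive inputs")
    cols: list[np.ndarray] = []
    seen: list[float] = []
    for p in powers:
        base = np.log(x) if p == 0 else x ** p
        if p in seen:  # repeated power
            base = (np.log(x) ** 2) if p == 0 else x ** p * np.log(x)
        cols.append(base)
        seen.append(p)
    return cols


def _fp_factors(comp: Composite, powers: Sequence[float]) -> list[tuple[Factor, ...]]:
    """Declarative factors matching :func:`fp_basis` column-for-column."""
    out: list[tuple[Factor, ...]] = []
    seen: list[float] = []
    for p in powers:
        if p in seen:
            f = Factor(comp.vars, power=p, divisor=comp.divisor,
                       log_power=2 if p == 0 else 1)
        else:
            f = Factor(comp.vars, power=p, divisor=comp.divisor,
                       log_power=1 if p == 0 else 0)
        out.append((f,))
        seen.append(p)
    return out


def _fp_label(comp: Composite, powers: Sequence[float], i: int) -> str:
    p = powers[i]
    rep = p in powers[:i]
    base = f"({comp.name})"
    if p == 0:
        return f"log{base}^2" if rep else f"log{base}"
    core = base if p == 1 else f"{base}^{p:g}"
    return f"{core}*log{base}" if rep else core


class FractionalPolynomialModel:
    """Multivariable fractional-polynomial regression of log10 weight.

    For each composite the FP1/FP2 power search (8 + 36 candidate
    models) is run marginally against the response and the
    minimum-deviance basis retained; the union of selected bases then
    passes through backward elimination.
    """

    def __init__(
        self,
        data: Union[pd.DataFrame, Cohort],
        composites: Optional[Sequence[Composite]] = None,
        powers: Sequence[float] = FP_POWERS,
        degree: int = 2,
        name: str = "fpr",
    ):
        self.data = _as_frame(data)
        self.composites = (
            list(composites) if composites is not None else default_fpr_composites()
        )
        self.powers = tuple(powers)
        if degree not in (1, 2):
            raise ValueError("fractional-polynomial degree must be 1 or 2")
        self.degree = degree
        self.name = name

    @staticmethod
    def candidate_power_sets(
        powers: Sequence[float] = FP_POWERS, degree: int = 2
    ) -> list[tuple[float, ...]]:
        """All FP power tuples searched per composite (8 FP1 + 36 FP2)."""
        cands: list[tuple[float, ...]] = [(p,) for p in powers]
        if degree == 2:
            cands += [(p, p) for p in powers]
            cands += [t for t in itertools.combinations(powers, 2)]
        return cands

    def search_composite(
        self, comp: Composite
    ) -> tuple[tuple[float, ...], dict[tuple[float, ...], float]]:
        """Deviance-minimising FP power set for one composite.

        Returns the selected powers and a dict mapping every visited
        power tuple to its Gaussian deviance, n * log(RSS/n).
        """
        df = self.data
        biometry = _biometry_dict(df)
        x = comp.values(biometry)
        if np.any(x <= 0):
            raise FittingError(
                f"composite {comp.name} is non-positive; FP transforms need x > 0"
            )
        y = np.log10(df["birth_weight_g"].to_numpy(float))
        n = len(y)
        deviances = {}
        for powers in self.candidate_power_sets(self.powers, self.degree):
            X = np.column_stack([np.ones(n)] + fp_basis(x, powers))
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            deviances[powers] = n * np.log(max(rss, 1e-300) / n)
        selected = min(deviances, key=deviances.get)
        return selected, deviances

    def fit(self, alpha: float = 0.05) -> EFWFitResults:
        df = self.data
        biometry = _biometry_dict(df)
        y = np.log10(df["birth_weight_g"].to_numpy(float))
        columns: dict[str, np.ndarray] = {}
        factors_by_name: dict[str, tuple[Factor, ...]] = {}
        search_trace = {}
        for comp in self.composites:
            powers, dev = self.search_composite(comp)
            search_trace[comp.name] = {"selected": powers, "n_visited": len(dev)}
            x = comp.values(biometry)
            basis = fp_basis(x, powers)
            facs = _fp_factors(comp, powers)
            for i, col in enumerate(basis):
                label = _fp_label(comp, powers, i)
                columns[label] = col
                factors_by_name[label] = facs[i]
        retained, res, trace = backward_eliminate(y, columns, alpha)
        terms = tuple(
            Term(coef=float(res.params[n]), factors=factors_by_name[n])
            for n in retained
        )
        spec = FormulaSpec(
            name=self.name,
            family="FPR",
            response_scale="log10_g",
            terms=terms,
            intercept=float(res.params["const"]),
        )
        return EFWFitResults(
            formula=spec,
            family="FPR",
            n_obs=len(df),
            params=res.params.rename(index={"const": "intercept"}),
            pvalues=res.pvalues.rename(index={"const": "intercept"}),
            resid_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
            trace=trace,
            extra={"fp_search": search_trace},
        )


class VolumeModel:
    """Intercept-free weight = a*head_volume + b*FL*AC^2 on the gram scale.

    The head basis is chosen among HC^3, BPD^3, BPD*HC^2 and BPD^2*HC by
    exhaustive residual-sum-of-squares comparison; candidates yielding a
    non-positive coefficient for either term are rejected (both terms
    are volumes, so negative proportionality is physically meaningless).
    """

    def __init__(
        self,
        data: Union[pd.DataFrame, Cohort],
        head_candidates: Optional[Mapping[str, tuple[Factor, ...]]] = None,
        name: str = "vm",
    ):
        self.data = _as_frame(data)
        self.head_candidates = dict(head_candidates or HEAD_CANDIDATES)
        self.name = name

    def fit(self, alpha: float = 0.05, weighting: str = "ols") -> EFWFitResults:
        """Fit the volume model.

        ``weighting="ols"`` (default) is unweighted through-origin least
        squares on the gram scale. ``weighting="relative"`` iteratively
        reweights by 1/fitted**2, the efficient choice when the weight
        error is multiplicative (constant coefficient of variation);
        candidate selection then compares relative residual sums of
        squares.
        """
        if weighting not in ("ols", "relative"):
            raise ValueError("weighting must be 'ols' or 'relative'")
        df = self.data
        biometry = _biometry_dict(df)
        w = df["birth_weight_g"].to_numpy(float)
        trunk = TRUNK_TERM.column(biometry)
        attempts = {}
        best = None
        for head_name, factors in self.head_candidates.items():
            head = DesignTerm(head_name, tuple(factors)).column(biometry)
            X = np.column_stack([head, trunk])
            sm_res = sm.OLS(w, X).fit()
            if weighting == "relative":
                for _ in range(3):
                    fitted = np.maximum(X @ np.asarray(sm_res.params), 1.0)
                    sm_res = sm.WLS(w, X, weights=1.0 / fitted ** 2).fit()
                fitted = np.maximum(X @ np.asarray(sm_res.params), 1.0)
                rss = float(np.sum(((w - fitted) / fitted) ** 2))
            else:
                rss = float(np.sum(sm_res.resid ** 2))
            a, b = sm_res.params
            admissible = a > 0 and b > 0
            attempts[head_name] = {"rss": rss, "coefs": (float(a), float(b)),
                                   "admissible": admissible}
            if admissible and (best is None or rss < best[1]):
                best = (head_name, rss, sm_res, tuple(factors))
        if best is None:
            raise FittingError(
                "volume model: every head candidate yielded a non-positive "
                "coefficient"
            )
        head_name, rss, sm_res, head_factors = best
        a, b = (float(v) for v in sm_res.params)
        spec = FormulaSpec(
            name=self.name,
            family="VM",
            response_scale="g",
            terms=(
                Term(coef=a, factors=head_factors),
                Term(coef=b, factors=TRUNK_TERM.factors),
            ),
        )
        params = pd.Series({head_name: a, TRUNK_TERM.name: b})
        pvalues = pd.Series(
            dict(zip([head_name, TRUNK_TERM.name], np.asarray(sm_res.pvalues)))
        )
        n = len(w)
        return EFWFitResults(
            formula=spec,
            family="VM",
            n_obs=n,
            params=params,
            pvalues=pvalues,
            resid_sd=float(np.sqrt(rss / max(n - 2, 1))),
            trace=[],
            extra={"head_selection": attempts, "selected_head": head_name},
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_mlr(
    data: Union[pd.DataFrame, Cohort],
    pool: Optional[Sequence[DesignTerm]] = None,
    alpha: float = 0.05,
    name: str = "mlr",
) -> EFWFitResults:
    return InteractionMLR(data, pool=pool, name=name).fit(alpha=alpha)


def fit_fpr(
    data: Union[pd.DataFrame, Cohort],
    composites: Optional[Sequence[Composite]] = None,
    powers: Sequence[float] = FP_POWERS,
    alpha: float = 0.05,
    name: str = "fpr",
) -> EFWFitResults:
    return FractionalPolynomialModel(
        data, composites=composites, powers=powers, name=name
    ).fit(alpha=alpha)


def fit_vm(
    data: Union[pd.DataFrame, Cohort],
    head_candidates: Optional[Mapping[str, tuple[Factor, ...]]] = None,
    alpha: float = 0.05,
    name: str = "vm",
) -> EFWFitResults:
    return VolumeModel(data, head_candidates=head_candidates, name=name).fit(alpha=alpha)


_FAMILY_FITTERS = {"MLR": fit_mlr, "FPR": fit_fpr, "VM": fit_vm}

#: Per-stage family assignment of the recommended staged model set.
DEFAULT_STAGE_FAMILIES: dict[Stage, str] = {
    Stage.S28_30: "VM",
    Stage.S31_33: "VM",
    Stage.S34_36: "VM",
    Stage.S37_39: "MLR",
    Stage.S40_42: "FPR",
}


def fit_staged(
    cohort: Cohort,
    families: Union[Mapping[Stage, str], str, None] = None,
    alpha: float = 0.05,
    use_training_split: bool = True,
) -> tuple[StagedModelSet, dict[Stage, EFWFitResults]]:
    """Fit one model per gestational-age stage.

    ``families`` maps each stage to "MLR", "FPR" or "VM"; a single
    string applies one family to all stages; None uses the recommended
    assignment (VM for 28–36, MLR for 37–39, FPR for 40–42). With
    ``families="auto"`` all three families are fitted per stage and the
    one with the smallest absolute in-sample systematic error wins; the
    per-family errors are recorded in each result's ``extra``.

    Fits on the training subset when the cohort carries a split.
    """
    if use_training_split and "split" in cohort.data.columns:
        work = cohort.training
    else:
        work = cohort

    auto = families == "auto"
    if families is None:
        fam_map = dict(DEFAULT_STAGE_FAMILIES)
    elif isinstance(families, str) and not auto:
        fam_map = {s: families.upper() for s in Stage}
    elif auto:
        fam_map = {}
    else:
        fam_map = {s: families[s].upper() for s in Stage}

    models: dict[Stage, FormulaSpec] = {}
    results: dict[Stage, EFWFitResults] = {}
    for stage in Stage:
        sl = work.stage_slice(stage)
        if len(sl) == 0:
            raise FittingError(f"no records in stage {stage.name}")
        label = f"fit_{stage.name.lower()}"
        if auto:
            errors = {}
            fits = {}
            for fam, fitter in _FAMILY_FITTERS.items():
                try:
                    r = fitter(sl, alpha=alpha, name=f"{label}_{fam.lower()}")
                except FittingError:
                    continue
                pe = (r.predict(sl) - sl["birth_weight_g"].to_numpy(float)) \
                    / sl["birth_weight_g"].to_numpy(float) * 100.0
                errors[fam] = float(np.mean(pe))
                fits[fam] = r
            if not fits:
                raise FittingError(f"no family could be fitted in stage {stage.name}")
            winner = min(errors, key=lambda k: abs(errors[k]))
            res = fits[winner]
            res.extra["family_systematic_errors_pct"] = errors
            res.extra["selected_family"] = winner
        else:
            fam = fam_map[stage]
            if fam not in _FAMILY_FITTERS:
                raise ValueError(f"unknown family {fam!r} for stage {stage.name}")
            res = _FAMILY_FITTERS[fam](sl, alpha=alpha, name=f"{label}_{fam.lower()}")
        results[stage] = res
        models[stage] = res.formula
    return StagedModelSet(models, name="fitted_staged"), results
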