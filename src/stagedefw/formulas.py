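"""Declarative estimated-fetal-weight (EFW) formula engine.

Every formula — the fifteen newly fitted staged models and the registry
of previously published equations (Hadlock, Shepard, Woo, Jordaan, ...)
— is represented as data, not code: an optional intercept plus a sum of
terms, each term a coefficient times a product of factors of the form

    (product_of_variables / divisor) ** power  [* ln(product / divisor)]

over the biometry variables {BPD, HC, AC, FL}. A power of 0 together
with ``log: true`` denotes a plain natural-log term; a nonzero power
with ``log: true`` denotes the repeated-power fractional-polynomial term
x**p * ln(x). The response scale declares how the linear predictor maps
to grams (identity, *1000 for kg, 10**x for log10 responses, exp for
natural-log responses). Input units are declared per variable (cm or
mm); the engine converts from the canonical centimetre records.

This keeps printed coefficients bit-exact and auditable in the shipped
YAML registry, and makes fitted models round-trippable through the same
file format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .biometry import BIOMETRY_VARS, BiometryRecord, Stage, stage_of

__all__ = [
    "Factor",
    "Term",
    "FormulaSpec",
    "StagedModelSet",
    "FormulaError",
    "RegistryError",
    "evaluate",
    "predict_staged",
    "load_registry",
    "default_registry",
    "default_staged_models",
    "table_staged_models",
]

RESPONSE_SCALES = ("g", "kg", "log10_g", "log10_kg", "ln_g")


class FormulaError(ValueError):
    """Formula cannot be evaluated on the given inputs."""


class RegistryError(ValueError):
    """Malformed registry entry."""


@dataclass(frozen=True)
class Factor:
    """One multiplicative factor: (prod(vars)/divisor)**power * ln(.)**log_power.

    ``log_power`` follows the fractional-polynomial repeated-power
    convention: power 0 with log_power 1 is a plain natural-log term,
    nonzero power with log_power 1 is x**p * ln(x), and the repeated
    power (0, 0) contributes ln(x)**2.
    """

    vars: tuple[str, ...]
    power: float = 1.0
    divisor: float = 1.0
    log_power: int = 0

    def __post_init__(self):
        for v in self.vars:
            if v not in BIOMETRY_VARS:
                raise RegistryError(
                    f"unknown biometry variable {v!r}; expected one of {BIOMETRY_VARS}"
                )
        if self.divisor <= 0:
            raise RegistryError(f"divisor must be positive, got {self.divisor}")
        if self.power == 0 and self.log_power == 0:
            raise RegistryError("a factor with power 0 must carry a log factor")

    @property
    def log(self) -> bool:
        return self.log_power > 0

    def value(self, biometry: Mapping[str, np.ndarray | float]) -> np.ndarray | float:
        base = 1.0
        for v in self.vars:
            base = base * biometry[v]
        base = base / self.divisor
        neg = np.any(np.asarray(base) <= 0)
        if neg and (self.log or self.power != int(self.power) or self.power < 0):
            raise FormulaError(
                f"non-positive input to factor {self!r}; log/fractional powers "
                "require strictly positive biometry"
            )
        out = base ** self.power if self.power != 0 else 1.0
        if self.log_power:
            out = out * np.log(base) ** self.log_power
        return out

    def label(self) -> str:
        """Human-readable form, e.g. ``(AC*FL/100)^-2*log(AC*FL/100)``."""
        base = "*".join(self.vars)
        if self.divisor != 1.0:
            base = f"({base}/{self.divisor:g})"
        elif len(self.vars) > 1 or self.power != 1 or self.log_power:
            base = f"({base})" if len(self.vars) > 1 else base
        parts = []
        if self.power != 0:
            parts.append(base if self.power == 1 else f"{base}^{self.power:g}")
        for _ in range(self.log_power):
            parts.append(f"log{base if base.startswith('(') else '(' + base + ')'}")
        return "*".join(parts)


@dataclass(frozen=True)
class Term:
    coef: float
    factors: tuple[Factor, ...]

    def value(self, biometry) -> np.ndarray | float:
        out = self.coef
        for f in self.factors:
            out = out * f.value(biometry)
        return out


@dataclass(frozen=True)
class FormulaSpec:
    """A named EFW formula: response scale, input units, intercept, terms."""

    name: str
    family: str  # MLR | FPR | VM | published
    response_scale: str  # g | kg | log10_g | log10_kg | ln_g
    terms: tuple[Term, ...]
    intercept: Optional[float] = None
    input_units: Mapping[str, str] = field(default_factory=dict)  # var -> cm|mm
    citation: str = ""

    def __post_init__(self):
        if self.response_scale not in RESPONSE_SCALES:
            raise RegistryError(
                f"{self.name}: unknown response_scale {self.response_scale!r}"
            )
        if self.family == "VM":
            if self.intercept not in (None, 0, 0.0):
                raise RegistryError(f"{self.name}: VM formulas have no intercept")
            if len(self.terms) != 2:
                raise RegistryError(
                    f"{self.name}: VM formulas have exactly two terms "
                    "(head volume + trunk volume)"
                )
        for unit in self.input_units.values():
            if unit not in ("cm", "mm"):
                raise RegistryError(f"{self.name}: input unit must be cm or mm")

    @property
    def variables(self) -> tuple[str, ...]:
        used = []
        for t in self.terms:
            for f in t.factors:
                for v in f.vars:
                    if v not in used:
                        used.append(v)
        return tuple(used)

    def _prepare(self, biometry: Mapping[str, np.ndarray | float]):
        """Convert canonical cm inputs to the formula's declared units."""
        out = {}
        for v in self.variables:
            if v not in biometry or biometry[v] is None:
                raise FormulaError(f"{self.name}: missing required variable {v}")
            x = np.asarray(biometry[v], dtype=float)
            if np.any(x <= 0):
                raise FormulaError(f"{self.name}: non-positive {v}")
            if self.input_units.get(v, "cm") == "mm":
                x = x * 10.0
            out[v] = x
        return out

    def predict(self, biometry: Mapping[str, np.ndarray | float]) -> np.ndarray | float:
        """Estimated weight in grams from biometry given in centimetres."""
        b = self._prepare(biometry)
        lin = 0.0 if self.intercept is None else self.intercept
        for t in self.terms:
            lin = lin + t.value(b)
        if self.response_scale == "g":
            w = lin
        elif self.response_scale == "kg":
            w = lin * 1000.0
        elif self.response_scale == "log10_g":
            w = 10.0 ** lin
        elif self.response_scale == "log10_kg":
            w = (10.0 ** lin) * 1000.0
        else:  # ln_g
            w = np.exp(lin)
        return w

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "family": self.family,
            "citation": self.citation,
            "response_scale": self.response_scale,
            "input_units": dict(self.input_units),
            "terms": [
                {
                    "coef": t.coef,
                    "factors": [
                        {
                            "var": "*".join(f.vars),
                            "power": f.power,
                            "divisor": f.divisor,
                            **(
                                {"log": True}
                                if f.log_power == 1
                                else {"log_power": f.log_power}
                                if f.log_power
                                else {}
                            ),
                        }
                        for f in t.factors
                    ],
                }
                for t in self.terms
            ],
        }
        if self.intercept is not None:
            d["intercept"] = self.intercept
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FormulaSpec":
        try:
            terms = []
            for td in d["terms"]:
                factors = []
                for fd in td["factors"]:
                    log_power = int(
                        fd.get("log_power", 1 if fd.get("log", False) else 0)
                    )
                    factors.append(
                        Factor(
                            vars=tuple(str(fd["var"]).split("*")),
                            power=float(fd.get("power", 1.0)),
                            divisor=float(fd.get("divisor", 1.0)),
                            log_power=log_power,
                        )
                    )
                terms.append(Term(coef=float(td["coef"]), factors=tuple(factors)))
            return cls(
                name=str(d["name"]),
                family=str(d["family"]),
                response_scale=str(d["response_scale"]),
                terms=tuple(terms),
                intercept=(float(d["intercept"]) if "intercept" in d and d["intercept"] is not None else None),
                input_units=dict(d.get("input_units", {})),
                citation=str(d.get("citation", "")),
            )
        except RegistryError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise RegistryError(
                f"malformed registry entry {d.get('name', '<unnamed>')!r}: {exc}"
            ) from exc


def evaluate(formula: FormulaSpec, record: BiometryRecord | Mapping[str, float]) -> float:
    """Evaluate one formula on one record, returning grams."""
    if isinstance(record, BiometryRecord):
        biometry = record.biometry()
    else:
        biometry = record
    return float(formula.predict(biometry))


@dataclass(frozen=True)
class StagedModelSet:
    """One formula per 3-week gestational-age stage, dispatched at predict time."""

    models: Mapping[Stage, FormulaSpec]
    name: str = "staged"

    def __post_init__(self):
        missing = [s.name for s in Stage if s not in self.models]
        if missing:
            raise RegistryError(f"staged model set missing stages: {missing}")

    def __getitem__(self, stage: Stage) -> FormulaSpec:
        return self.models[stage]

    def predict_record(self, record: BiometryRecord | Mapping[str, float]) -> float:
        ga = record.ga_weeks if isinstance(record, BiometryRecord) else record["ga_weeks"]
        return evaluate(self.models[stage_of(ga)], record)

    def predict(self, df: pd.DataFrame) -> pd.Series:
        """Vectorised staged prediction over a cohort DataFrame (grams)."""
        from .biometry import stage_of_array

        stages = stage_of_array(df["ga_weeks"])
        out = np.empty(len(df), dtype=float)
        biometry = {
            "BPD": df["bpd_cm"].to_numpy(float),
            "HC": df["hc_cm"].to_numpy(float),
            "AC": df["ac_cm"].to_numpy(float),
            "FL": df["fl_cm"].to_numpy(float),
        }
        for stage in Stage:
            mask = np.asarray(stages == stage.name)
            if not mask.any():
                continue
            sub = {k: v[mask] for k, v in biometry.items()}
            out[mask] = self.models[stage].predict(sub)
        return pd.Series(out, index=df.index, name="efw_g")


def predict_staged(models: StagedModelSet, record: BiometryRecord | Mapping) -> float:
    """Route a record through its gestational-age stage's formula."""
    return models.predict_record(record)


def load_registry(path: Union[str, Path, None] = None) -> dict[str, FormulaSpec]:
    """Load a formula registry YAML into named FormulaSpec objects.

    Without an argument, loads the packaged registry: the fifteen staged
    models plus the 21 published comparison formulas.
    """
    if path is None:
        text = resources.files("stagedefw.data").joinpath("registry.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    entries = doc["formulas"] if isinstance(doc, Mapping) else doc
    registry: dict[str, FormulaSpec] = {}
    for entry in entries:
        spec = FormulaSpec.from_dict(entry)
        if spec.name in registry:
            raise RegistryError(f"duplicate formula name {spec.name!r}")
        registry[spec.name] = spec
    return registry


def save_registry(specs: Iterable[FormulaSpec], path: Union[str, Path]) -> None:
    doc = {"formulas": [s.to_dict() for s in specs]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


_REGISTRY_CACHE: dict[str, FormulaSpec] | None = None


def default_registry() -> dict[str, FormulaSpec]:
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        _REGISTRY_CACHE = load_registry()
    return _REGISTRY_CACHE


#: Stage -> registry-name of the recommended staged model
#: (volume-based for 28-36 weeks, interaction MLR for 37-39,
#: fractional-polynomial for 40-42).
RECOMMENDED_STAGED = {
    Stage.S28_30: "staged_vm_28_30",
    Stage.S31_33: "staged_vm_31_33",
    Stage.S34_36: "staged_vm_34_36",
    Stage.S37_39: "staged_mlr_37_39",
    Stage.S40_42: "staged_fpr_40_42",
}


def default_staged_models() -> StagedModelSet:
    """The recommended staged model set (VM/VM/VM/MLR/FPR by stage)."""
    reg = default_registry()
    return StagedModelSet(
        {s: reg[name] for s, name in RECOMMENDED_STAGED.items()},
        name="new_staged",
    )


def table_staged_models(family: str) -> StagedModelSet:
    """A single-family staged set (family in MLR/FPR/VM) from the registry."""
    fam = family.upper()
    if fam not in ("MLR", "FPR", "VM"):
        raise RegistryError(f"family must be MLR, FPR or VM, got {family!r}")
    reg = default_registry()
    models = {}
    for s in Stage:
        key = f"staged_{fam.lower()}_{int(s.lower_wk)}_{int(s.upper_wk) - 1}"
        models[s] = reg[key]
    return StagedModelSet(models, name=f"staged_{fam.lower()}")
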