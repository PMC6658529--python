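"""Domain types for fetal biometry cohorts.

Canonical internal units are centimetres for the four standard 2D
ultrasound measurements (biparietal diameter BPD, head circumference HC,
abdominal circumference AC, femur length FL) and grams for weight.
Gestational age is carried as decimal weeks and analysis is restricted to
deliveries in [28, 43) weeks, partitioned into five 3-week stages.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "BIOMETRY_VARS",
    "GA_MIN",
    "GA_MAX",
    "MACROSOMIA_THRESHOLD_G",
    "Stage",
    "StagingError",
    "BiometryRecord",
    "Cohort",
    "CentileReference",
    "OutcomeLabels",
    "stage_of",
    "stage_of_array",
    "label_outcomes",
    "apply_split",
    "read_cohort_csv",
]

#: Ultrasound biometry variables, in conventional reporting order.
BIOMETRY_VARS = ("BPD", "HC", "AC", "FL")

GA_MIN = 28.0
GA_MAX = 43.0  # exclusive; "40-42 weeks" ends the day week 43 begins

MACROSOMIA_THRESHOLD_G = 4000.0


class StagingError(ValueError):
    """Gestational age outside the admitted interval [28, 43) weeks."""


class ReferenceCoverageError(KeyError):
    """Centile reference lacks a row for the requested completed week."""


class Stage(enum.Enum):
    """Half-open 3-week gestational-age bins partitioning [28, 43) weeks.

    The label "37-39 weeks" denotes deliveries with 37.0 <= ga < 40.0
    decimal weeks (completed weeks 37, 38 and 39); the half-open
    convention is the only one under which the five labels partition the
    admitted range.
    """

    S28_30 = (28.0, 31.0)
    S31_33 = (31.0, 34.0)
    S34_36 = (34.0, 37.0)
    S37_39 = (37.0, 40.0)
    S40_42 = (40.0, 43.0)

    def __init__(self, lower_wk: float, upper_wk: float):
        self.lower_wk = lower_wk
        self.upper_wk = upper_wk

    @property
    def label(self) -> str:
        return self.name

    def contains(self, ga_weeks: float) -> bool:
        return self.lower_wk <= ga_weeks < self.upper_wk

    def __str__(self) -> str:  # e.g. "28-30"
        return f"{int(self.lower_wk)}-{int(self.upper_wk) - 1}"


def stage_of(ga_weeks: float) -> Stage:
    """Map a decimal gestational age (weeks) to its 3-week stage.

    Raises
    ------
    StagingError
        If ``ga_weeks`` is outside the admitted interval [28, 43).
    """
    if not (GA_MIN <= ga_weeks < GA_MAX):
        raise StagingError(
            f"gestational age {ga_weeks} weeks outside admitted interval "
            f"[{GA_MIN}, {GA_MAX}) weeks"
        )
    for stage in Stage:
        if stage.contains(ga_weeks):
            return stage
    raise AssertionError("unreachable: stages partition [28, 43)")


def stage_of_array(ga_weeks: np.ndarray | pd.Series) -> pd.Categorical:
    """Vectorised :func:`stage_of` returning a pandas Categorical."""
    ga = np.asarray(ga_weeks, dtype=float)
    if ga.size and ((ga < GA_MIN).any() or (ga >= GA_MAX).any()):
        bad = ga[(ga < GA_MIN) | (ga >= GA_MAX)]
        raise StagingError(
            f"{bad.size} gestational ages outside [{GA_MIN}, {GA_MAX}) weeks "
            f"(e.g. {bad[0]})"
        )
    edges = [s.lower_wk for s in Stage] + [GA_MAX]
    idx = np.digitize(ga, edges[1:-1], right=False)
    labels = [s.name for s in Stage]
    return pd.Categorical.from_codes(idx, categories=labels)


@dataclass(frozen=True)
class BiometryRecord:
    """One pregnancy: delivery gestational age, biometry (cm), weight (g)."""

    ga_weeks: float
    bpd_cm: float
    hc_cm: float
    ac_cm: float
    fl_cm: float
    birth_weight_g: Optional[float] = None
    sex: Optional[str] = None
    ultrasound_to_delivery_days: Optional[int] = None

    def __post_init__(self):
        for name in ("bpd_cm", "hc_cm", "ac_cm", "fl_cm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.birth_weight_g is not None and not self.birth_weight_g > 0:
            raise ValueError(f"birth_weight_g must be positive, got {self.birth_weight_g}")
        d = self.ultrasound_to_delivery_days
        if d is not None and not (0 <= d <= 3):
            raise ValueError(f"ultrasound_to_delivery_days must be 0-3, got {d}")

    @property
    def stage(self) -> Stage:
        return stage_of(self.ga_weeks)

    def biometry(self) -> dict[str, float]:
        """Biometry as a {BPD, HC, AC, FL} -> cm mapping."""
        return {
            "BPD": self.bpd_cm,
            "HC": self.hc_cm,
            "AC": self.ac_cm,
            "FL": self.fl_cm,
        }


#: Canonical cohort column names (biometry in cm, weight in g).
COHORT_COLUMNS = ("ga_weeks", "bpd_cm", "hc_cm", "ac_cm", "fl_cm", "birth_weight_g")


@dataclass
class Cohort:
    """An ordered collection of pregnancy records backed by a DataFrame.

    ``data`` columns follow :data:`COHORT_COLUMNS`, with optional ``sex``,
    ``interval_days`` and ``split`` ({"training", "validation"}) columns.
    """

    data: pd.DataFrame
    provenance: str = ""
    accounting: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COHORT_COLUMNS[:5] if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort missing required columns: {missing}")
        if "split" in self.data.columns:
            bad = set(self.data["split"].dropna().unique()) - {"training", "validation"}
            if bad:
                raise ValueError(f"invalid split labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_split(self) -> bool:
        return "split" in self.data.columns and self.data["split"].notna().all()

    @property
    def stages(self) -> pd.Categorical:
        return stage_of_array(self.data["ga_weeks"])

    def stage_slice(self, stage: Stage) -> pd.DataFrame:
        mask = np.asarray(self.stages == stage.name)
        return self.data.loc[mask]

    def subset(self, split: str) -> "Cohort":
        if "split" not in self.data.columns:
            raise ValueError("cohort has no split assignment; call apply_split first")
        sub = self.data.loc[self.data["split"] == split].reset_index(drop=True)
        return Cohort(sub, provenance=f"{self.provenance} [{split}]")

    @property
    def training(self) -> "Cohort":
        return self.subset("training")

    @property
    def validation(self) -> "Cohort":
        return self.subset("validation")

    def records(self) -> Iterable[BiometryRecord]:
        for row in self.data.itertuples(index=False):
            yield BiometryRecord(
                ga_weeks=row.ga_weeks,
                bpd_cm=row.bpd_cm,
                hc_cm=row.hc_cm,
                ac_cm=row.ac_cm,
                fl_cm=row.fl_cm,
                birth_weight_g=getattr(row, "birth_weight_g", None),
                sex=getattr(row, "sex", None),
            )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "Cohort":
        return read_cohort_csv(path)


def read_cohort_csv(path: Union[str, Path]) -> Cohort:
    """Read a cohort CSV, auto-detecting mm vs cm biometry by header suffix.

    Accepted biometry headers are ``bpd_mm``/``bpd_cm`` etc.; millimetre
    columns are converted to the canonical centimetre columns on ingest.
    Records with missing biometry or gestational age outside [28, 43) are
    excluded, with counts recorded in ``Cohort.accounting``.
    """
    df = pd.read_csv(path)
    if "ga_weeks" not in df.columns:
        raise ValueError("cohort CSV must have a ga_weeks column")
    out = pd.DataFrame({"ga_weeks": df["ga_weeks"].astype(float)})
    for var in ("bpd", "hc", "ac", "fl"):
        if f"{var}_cm" in df.columns:
            out[f"{var}_cm"] = df[f"{var}_cm"].astype(float)
        elif f"{var}_mm" in df.columns:
            out[f"{var}_cm"] = df[f"{var}_mm"].astype(float) / 10.0
        else:
            raise ValueError(f"cohort CSV lacks {var}_cm or {var}_mm column")
    if "birth_weight_g" in df.columns:
        out["birth_weight_g"] = df["birth_weight_g"].astype(float)
    for opt in ("sex", "interval_days", "split"):
        if opt in df.columns:
            out[opt] = df[opt]

    n_ingested = len(out)
    biom_cols = ["bpd_cm", "hc_cm", "ac_cm", "fl_cm"]
    complete = out[biom_cols].notna().all(axis=1) & (out[biom_cols] > 0).all(axis=1)
    in_range = (out["ga_weeks"] >= GA_MIN) & (out["ga_weeks"] < GA_MAX)
    keep = complete & in_range
    accounting = {
        "ingested": n_ingested,
        "excluded_incomplete_biometry": int((~complete).sum()),
        "excluded_ga_out_of_range": int((complete & ~in_range).sum()),
        "analyzed": int(keep.sum()),
    }
    return Cohort(out.loc[keep].reset_index(drop=True),
                  provenance=str(path), accounting=accounting)


@dataclass(frozen=True)
class OutcomeLabels:
    """Birth-outcome flags for one record.

    SGA/LGA are defined against a population centile reference at the
    completed gestational week (strict inequalities); macrosomia is
    birth weight >= 4000 g regardless of gestational age.
    """

    is_sga: bool
    is_lga: bool
    is_macrosomia: bool

    def __post_init__(self):
        if self.is_sga and self.is_lga:
            raise ValueError("SGA and LGA are mutually exclusive")


class CentileReference:
    """Per-completed-week 10th and 90th birth-weight centiles (grams)."""

    def __init__(self, table: pd.DataFrame):
        required = {"week", "p10_g", "p90_g"}
        if not required.issubset(table.columns):
            raise ValueError(f"centile table needs columns {sorted(required)}")
        t = table[["week", "p10_g", "p90_g"]].astype(
            {"week": int, "p10_g": float, "p90_g": float}
        )
        t = t.sort_values("week").reset_index(drop=True)
        if (t["p10_g"] >= t["p90_g"]).any():
            raise ValueError("p10 must be below p90 at every week")
        self.table = t
        self._p10 = dict(zip(t["week"], t["p10_g"]))
        self._p90 = dict(zip(t["week"], t["p90_g"]))

    @property
    def weeks(self) -> list[int]:
        return list(self.table["week"])

    def p10(self, week: int) -> float:
        try:
            return self._p10[int(week)]
        except KeyError:
            raise ReferenceCoverageError(
                f"no centile row for completed week {week}"
            ) from None

    def p90(self, week: int) -> float:
        try:
            return self._p90[int(week)]
        except KeyError:
            raise ReferenceCoverageError(
                f"no centile row for completed week {week}"
            ) from None

    def thresholds(self, ga_weeks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised (p10, p90) thresholds for decimal gestational ages."""
        weeks = np.floor(np.asarray(ga_weeks, dtype=float)).astype(int)
        missing = sorted(set(weeks) - set(self._p10))
        if missing:
            raise ReferenceCoverageError(f"no centile rows for weeks {missing}")
        p10 = np.array([self._p10[w] for w in weeks])
        p90 = np.array([self._p90[w] for w in weeks])
        return p10, p90

    def to_csv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "CentileReference":
        return cls(pd.read_csv(path))


def label_outcomes(
    record: BiometryRecord | Mapping[str, float], ref: CentileReference
) -> OutcomeLabels:
    """Label one delivery as SGA / LGA / macrosomic.

    SGA iff birth weight < 10th centile at the completed week; LGA iff
    > 90th centile; macrosomia iff weight >= 4000 g (boundary inclusive).
    """
    if isinstance(record, BiometryRecord):
        bw, ga = record.birth_weight_g, record.ga_weeks
    else:
        bw, ga = record["birth_weight_g"], record["ga_weeks"]
    if bw is None or not bw > 0:
        raise ValueError("birth_weight_g must be present and positive")
    week = int(math.floor(ga))
    return OutcomeLabels(
        is_sga=bw < ref.p10(week),
        is_lga=bw > ref.p90(week),
        is_macrosomia=bw >= MACROSOMIA_THRESHOLD_G,
    )


def apply_split(
    cohort: Cohort,
    validation_fraction: float = 1933 / 19310,
    seed: int = 0,
) -> Cohort:
    """Randomly assign records to training / validation groups.

    Simple random sampling without replacement; the validation group size
    is ``round(n * validation_fraction)``. Reproducible under a fixed
    seed. The default fraction reproduces a ~9:1 split.
    """
    if not 0 < validation_fraction < 1:
        raise ValueError(
            f"validation_fraction must be in (0, 1), got {validation_fraction}"
        )
    n = len(cohort)
    n_val = int(round(n * validation_fraction))
    rng = np.random.default_rng(seed)
    val_idx = rng.choice(n, size=n_val, replace=False)
    split = np.full(n, "training", dtype=object)
    split[val_idx] = "validation"
    data = cohort.data.copy()
    data["split"] = split
    return Cohort(data, provenance=cohort.provenance, accounting=cohort.accounting)
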