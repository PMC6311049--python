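"""eGFR equations, rounding policies, age computation, and CKD staging.

Implements the IDMS-traceable MDRD study equation and the 2009 CKD-EPI
creatinine equation. Both estimate glomerular filtration rate (mL/min per
1.73 m2 body surface area) from serum creatinine (Scr, mg/dL), age (years),
gender, and binary black / non-black race.

MDRD (IDMS):  175 * Scr^-1.154 * Age^-0.203 * 0.742[female] * 1.212[black]
CKD-EPI:      141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^Age
              * 1.018[female] * 1.159[black]
with gender-specific knot k (0.7 female / 0.9 male) and low-Scr exponent a
(-0.329 female / -0.411 male).
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "EquationConstants",
    "PatientSnapshot",
    "ComparisonPolicy",
    "StageScheme",
    "RoundingMode",
    "Gender",
    "RaceDetail",
    "DEFAULT_STAGES",
    "mdrd_egfr",
    "ckdepi_egfr",
    "round_to_precision",
    "assign_stage",
    "age_at_date",
]


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class RaceDetail(str, enum.Enum):
    WHITE = "white"
    BLACK = "black"
    ASIAN = "asian"
    AMERICAN_INDIAN = "american_indian"
    OTHER = "other"


class RoundingMode(str, enum.Enum):
    #: commercial rounding: 0.5 rounds away from zero (62.75 -> 62.8)
    HALF_AWAY_FROM_ZERO = "half_away_from_zero"
    #: banker's rounding: 0.5 rounds to the even neighbour
    HALF_EVEN = "half_even"


@dataclass(frozen=True)
class EquationConstants:
    """Coefficients of the MDRD and CKD-EPI equations.

    Shipped as a frozen dataclass so alternative equation variants can be
    injected; :meth:`from_json` / :meth:`to_json` round-trip a versioned
    config file.
    """

    mdrd_scale: float = 175.0
    mdrd_scr_exp: float = -1.154
    mdrd_age_exp: float = -0.203
    mdrd_female_factor: float = 0.742
    mdrd_black_factor: float = 1.212
    ckdepi_scale: float = 141.0
    ckdepi_high_exp: float = -1.209
    ckdepi_age_base: float = 0.993
    ckdepi_female_factor: float = 1.018
    ckdepi_black_factor: float = 1.159
    ckdepi_kappa_female: float = 0.7
    ckdepi_kappa_male: float = 0.9
    ckdepi_alpha_female: float = -0.329
    ckdepi_alpha_male: float = -0.411

    def __post_init__(self) -> None:
        if not (
            self.mdrd_scale > 0
            and self.mdrd_female_factor > 0
            and self.mdrd_black_factor > 0
            and self.ckdepi_scale > 0
            and self.ckdepi_kappa_female > 0
            and self.ckdepi_kappa_male > 0
        ):
            raise ValueError("equation factors must be strictly positive")
        if self.mdrd_scr_exp >= 0 or self.mdrd_age_exp >= 0:
            raise ValueError("MDRD Scr and age exponents must be negative")

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "EquationConstants":
        return cls(**json.loads(Path(path).read_text()))


DEFAULT_CONSTANTS = EquationConstants()


@dataclass(frozen=True)
class PatientSnapshot:
    """One patient's equation parameters as recorded at a given time."""

    patient_id: str
    dob: _dt.date
    gender: Gender
    race_detail: RaceDetail
    scr: float
    lab_date: _dt.date

    def __post_init__(self) -> None:
        if self.scr <= 0:
            raise ValueError(f"scr must be positive, got {self.scr}")
        if self.lab_date < self.dob:
            raise ValueError("lab_date precedes dob")

    @property
    def race_black(self) -> bool:
        return self.race_detail == RaceDetail.BLACK

    @property
    def female(self) -> bool:
        return self.gender == Gender.FEMALE

    @property
    def age(self) -> int:
        """Completed years at lab_date."""
        return age_at_date(self.dob, self.lab_date)


@dataclass(frozen=True)
class ComparisonPolicy:
    """Rounding precisions used at the three places eGFR values are rounded.

    ``screen_precision`` is the coarse unit for the concordance screen
    (whole numbers by default: a conservative screen that never flags a
    pair a finer screen would pass), ``inversion_precision`` the unit at
    which the inverse index keys generated eGFR values, and
    ``report_precision`` the unit at which eGFR values are stored.
    """

    screen_precision: float = 1.0
    inversion_precision: float = 0.1
    report_precision: float = 0.1
    rounding_mode: RoundingMode = RoundingMode.HALF_AWAY_FROM_ZERO

    def __post_init__(self) -> None:
        for name in ("screen_precision", "inversion_precision", "report_precision"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_POLICY = ComparisonPolicy()


@dataclass(frozen=True)
class StageScheme:
    """Ordered half-open eGFR intervals partitioning (0, inf).

    Entries are ``(label, lower_inclusive, upper_exclusive)`` in descending
    eGFR order. The half-open convention assigns boundary values (e.g. 60.0)
    to the higher-eGFR interval, matching the inclusive integer bounds of
    clinical stage tables (Stage 3a = 59-45 etc.) while classifying every
    positive tenth.
    """

    bands: tuple = (
        ("eGFR 90+", 90.0, math.inf),
        ("eGFR 60-89", 60.0, 90.0),
        ("Stage 3a", 45.0, 60.0),
        ("Stage 3b", 30.0, 45.0),
        ("Stage 4", 15.0, 30.0),
        ("Stage 5", 0.0, 15.0),
    )

    def __post_init__(self) -> None:
        labels = [b[0] for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ValueError("stage labels must be unique")
        for (_, lo, hi), (_, lo2, hi2) in zip(self.bands, self.bands[1:]):
            if lo != hi2:
                raise ValueError("stage bands must tile (0, inf) contiguously")
            if lo >= hi or lo2 >= hi2:
                raise ValueError("stage bands must be non-empty")
        if self.bands[-1][1] != 0.0 or not math.isinf(self.bands[0][2]):
            raise ValueError("stage bands must span (0, inf)")

    @property
    def labels(self) -> list:
        return [b[0] for b in self.bands]


DEFAULT_STAGES = StageScheme()


def mdrd_egfr(age, scr, female, black, constants: EquationConstants = DEFAULT_CONSTANTS):
    """Unrounded IDMS MDRD eGFR. Accepts scalars or numpy arrays.

    Strictly decreasing in both ``scr`` and ``age``; the female (0.742) and
    black (1.212) factors multiply exactly once.
    """
    age = np.asarray(age, dtype=float)
    scr = np.asarray(scr, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("age and scr must be positive")
    v = (
        constants.mdrd_scale
        * scr**constants.mdrd_scr_exp
        * age**constants.mdrd_age_exp
    )
    v = v * np.where(np.asarray(female, dtype=bool), constants.mdrd_female_factor, 1.0)
    v = v * np.where(np.asarray(black, dtype=bool), constants.mdrd_black_factor, 1.0)
    return v if v.ndim else float(v)


def ckdepi_egfr(age, scr, female, black, constants: EquationConstants = DEFAULT_CONSTANTS):
    """Unrounded 2009 CKD-EPI creatinine eGFR. Accepts scalars or arrays.

    Piecewise in Scr around the gender-specific knot kappa; the two branch
    factors both equal 1 at Scr = kappa, so the function is continuous there.
    """
    age = np.asarray(age, dtype=float)
    scr = np.asarray(scr, dtype=float)
    female = np.asarray(female, dtype=bool)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("age and scr must be positive")
    kappa = np.where(female, constants.ckdepi_kappa_female, constants.ckdepi_kappa_male)
    alpha = np.where(female, constants.ckdepi_alpha_female, constants.ckdepi_alpha_male)
    ratio = scr / kappa
    v = (
        constants.ckdepi_scale
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** constants.ckdepi_high_exp
        * constants.ckdepi_age_base**age
    )
    v = v * np.where(female, constants.ckdepi_female_factor, 1.0)
    v = v * np.where(np.asarray(black, dtype=bool), constants.ckdepi_black_factor, 1.0)
    return v if v.ndim else float(v)


def round_to_precision(
    value,
    precision: float,
    mode: RoundingMode = RoundingMode.HALF_AWAY_FROM_ZERO,
):
    """Round to the nearest multiple of ``precision``.

    Works on scalars and arrays. ``half_away_from_zero`` reproduces the
    commercial rounding of clinical systems (62.75 -> 62.8, 62.7 -> 63 at
    whole-number precision); ``half_even`` is IEEE round-half-to-even.
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    x = np.asarray(value, dtype=float) / precision
    if mode == RoundingMode.HALF_AWAY_FROM_ZERO:
        r = np.sign(x) * np.floor(np.abs(x) + 0.5)
    else:
        r = np.round(x)
    out = r * precision
    return out if out.ndim else float(out)


def assign_stage(egfr: float, scheme: StageScheme = DEFAULT_STAGES) -> str:
    """CKD stage label for a (rounded) eGFR under half-open band boundaries."""
    if egfr <= 0:
        raise ValueError(f"egfr must be positive, got {egfr}")
    for label, lo, hi in scheme.bands:
        if lo <= egfr < hi:
            return label
    raise AssertionError("stage bands do not cover value")  # pragma: no cover


def assign_stage_array(egfr: np.ndarray, scheme: StageScheme = DEFAULT_STAGES) -> np.ndarray:
    """Vectorised staging: integer band index (0 = highest eGFR band)."""
    egfr = np.asarray(egfr, dtype=float)
    if np.any(egfr <= 0):
        raise ValueError("egfr must be positive")
    # descending lower bounds: 90, 60, 45, 30, 15, 0
    lowers = np.array([b[1] for b in scheme.bands])
    idx = np.argmax(egfr[:, None] >= lowers[None, :], axis=1)
    return idx


def age_at_date(dob: _dt.date, on: _dt.date) -> int:
    """Age in completed years on a given date (increments on the anniversary)."""
    if on < dob:
        raise ValueError("date precedes dob")
    years = on.year - dob.year
    if (on.month, on.day) < (dob.month, dob.day):
        years -= 1
    return years
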