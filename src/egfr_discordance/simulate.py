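"""Synthetic EHR-drift cohort generator with ground truth.

Emulates a large VA-like primary-care cohort (about 90% male, about 18%
black, mean age near 55, serum creatinine log-normal with median near
0.95 mg/dL and SD near 0.5) in which an automated eGFR was computed and
stored at lab time ("then" record), after which the stored demographics or
creatinine may have been destructively overwritten ("now" record). Injected
changes are labelled, so attribution of automated-vs-retrospective
discordance can be validated against known causes.

Scr values are quantised to the attribution grid step, so every true
parameter combination lies on the enumeration grid and single-parameter
recovery is exact up to rounding coincidences.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, write_cohort
from .egfr import (
    DEFAULT_CONSTANTS,
    DEFAULT_POLICY,
    ComparisonPolicy,
    EquationConstants,
    Gender,
    PatientSnapshot,
    RaceDetail,
    age_at_date,
    mdrd_egfr,
    round_to_precision,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_truth",
    "apply_ehr_drift",
    "emit_cohort",
    "simulate_cohort",
]

_RACES = ("white", "black", "asian", "american_indian", "other")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort marginals, drift probabilities, and drift magnitude models.

    Drift probabilities are interpreted as mutually exclusive by default
    (at most one parameter changes per patient, mirroring the dominance of
    single-parameter explanations in real drift); ``independent_drift=True``
    lets several parameters change in one record.
    """

    n_patients: int = 1000
    seed: int = 0
    fraction_male: float = 0.90
    race_probs: Tuple[float, ...] = (0.76, 0.18, 0.01, 0.01, 0.04)
    age_mean: float = 55.0
    age_sd: float = 18.0
    age_bounds: Tuple[int, int] = (18, 120)
    scr_log_median: float = 0.95
    scr_log_sigma: float = 0.426
    scr_bounds: Tuple[float, float] = (0.10, 30.0)
    scr_step: float = 0.01
    p_age: float = 0.0
    p_race: float = 0.0
    p_gender: float = 0.0
    p_scr: float = 0.0
    independent_drift: bool = False
    dob_shift_years: Tuple[int, int] = (1, 30)
    scr_shift_range: Tuple[float, float] = (0.05, 0.50)
    lab_window: Tuple[_dt.date, _dt.date] = (_dt.date(2013, 1, 1), _dt.date(2013, 12, 31))

    def __post_init__(self) -> None:
        ps = (self.p_age, self.p_race, self.p_gender, self.p_scr)
        if any(not 0 <= p <= 1 for p in ps):
            raise ValueError("drift probabilities must lie in [0, 1]")
        if not self.independent_drift and sum(ps) > 1 + 1e-12:
            raise ValueError("mutually exclusive drift probabilities exceed 1")
        if abs(sum(self.race_probs) - 1) > 1e-9:
            raise ValueError("race probabilities must sum to 1")
        if not (self.scr_bounds[0] > 0 and self.scr_step > 0):
            raise ValueError("infeasible Scr bounds or step")
        if self.age_bounds[0] < 1 or self.age_bounds[0] > self.age_bounds[1]:
            raise ValueError("infeasible age bounds")


@dataclass(frozen=True)
class GroundTruth:
    """What was changed in one patient's record, with before/after values."""

    patient_id: str
    changed_parameters: frozenset
    before: Dict[str, object] = field(default_factory=dict)
    after: Dict[str, object] = field(default_factory=dict)


def _quantize(values: np.ndarray, step: float) -> np.ndarray:
    return np.round(np.floor(values / step + 0.5) * step, 10)


def _shift_dob_years(dob: _dt.date, years: int) -> _dt.date:
    try:
        return dob.replace(year=dob.year + years)
    except ValueError:  # Feb 29 -> Feb 28
        return dob.replace(year=dob.year + years, day=28)


def simulate_truth(
    config: SimulationConfig,
    constants: EquationConstants = DEFAULT_CONSTANTS,
    policy: ComparisonPolicy = DEFAULT_POLICY,
) -> Tuple[List[PatientSnapshot], np.ndarray]:
    """Draw "then" records and forward-compute their automated eGFR.

    The automated value mimics the laboratory software: the MDRD equation
    applied to the record as it stood at lab time, rounded at the reporting
    precision. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    male = rng.random(n) < config.fraction_male
    race_idx = rng.choice(len(_RACES), size=n, p=np.asarray(config.race_probs))
    lo_a, hi_a = config.age_bounds
    age = np.rint(rng.normal(config.age_mean, config.age_sd, size=n))
    age = np.clip(age, lo_a, hi_a).astype(int)
    scr = rng.lognormal(np.log(config.scr_log_median), config.scr_log_sigma, size=n)
    scr = _quantize(np.clip(scr, *config.scr_bounds), config.scr_step)
    start, end = config.lab_window
    lab_offsets = rng.integers(0, (end - start).days + 1, size=n)
    dob_backoff = rng.integers(0, 365, size=n)  # keeps completed age exact

    snapshots: List[PatientSnapshot] = []
    for i in range(n):
        lab_date = start + _dt.timedelta(days=int(lab_offsets[i]))
        anniversary = _shift_dob_years(lab_date, -int(age[i]))
        dob = anniversary - _dt.timedelta(days=int(dob_backoff[i]))
        snapshots.append(PatientSnapshot(
            patient_id=f"P{i:06d}",
            dob=dob,
            gender=Gender.MALE if male[i] else Gender.FEMALE,
            race_detail=RaceDetail(_RACES[race_idx[i]]),
            scr=float(scr[i]),
            lab_date=lab_date,
        ))
    egfr = mdrd_egfr(age, scr, ~male, race_idx == _RACES.index("black"), constants)
    automated = np.asarray(round_to_precision(
        egfr, policy.report_precision, policy.rounding_mode))
    return snapshots, automated


_MAX_REDRAWS = 100


def apply_ehr_drift(
    then_records: List[PatientSnapshot],
    config: SimulationConfig,
) -> Tuple[List[PatientSnapshot], List[GroundTruth]]:
    """Overwrite parameters in a copy of the records, per the drift model.

    DOB shifts are whole years (uniform 1-30, either sign), so the integer
    age at lab date changes by exactly the shift; race flips black <->
    non-black; gender flips; Scr gets an additive shift of 0.05-0.50 mg/dL
    in grid-step multiples, either sign. Shifts that would leave the grid
    are redrawn (bounded retries) and skipped with empty truth if infeasible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ps = np.array([config.p_age, config.p_race, config.p_gender, config.p_scr])
    now_records: List[PatientSnapshot] = []
    truths: List[GroundTruth] = []
    for snap in then_records:
        if config.independent_drift:
            chosen = [PARAM for PARAM, p in zip(("age", "race", "gender", "scr"), ps)
                      if rng.random() < p]
        else:
            u = rng.random()
            cum = np.cumsum(ps)
            k = int(np.searchsorted(cum, u, side="right"))
            chosen = [("age", "race", "gender", "scr")[k]] if k < 4 else []
        new = {"dob": snap.dob, "gender": snap.gender,
               "race_detail": snap.race_detail, "scr": snap.scr}
        before: Dict[str, object] = {}
        after: Dict[str, object] = {}
        applied = []
        for param in chosen:
            if param == "age":
                lo, hi = config.dob_shift_years
                ok = False
                for _ in range(_MAX_REDRAWS):
                    shift = int(rng.integers(lo, hi + 1)) * (1 if rng.random() < 0.5 else -1)
                    cand = _shift_dob_years(new["dob"], -shift)  # earlier DOB -> older
                    if cand <= snap.lab_date and (
                        config.age_bounds[0]
                        <= age_at_date(cand, snap.lab_date)
                        <= config.age_bounds[1]
                    ):
                        before["age"], after["age"] = new["dob"].isoformat(), cand.isoformat()
                        new["dob"] = cand
                        ok = True
                        break
                if ok:
                    applied.append("age")
            elif param == "race":
                before["race"] = new["race_detail"].value
                if new["race_detail"] == RaceDetail.BLACK:
                    new["race_detail"] = RaceDetail.WHITE
                else:
                    new["race_detail"] = RaceDetail.BLACK
                after["race"] = new["race_detail"].value
                applied.append("race")
            elif param == "gender":
                before["gender"] = new["gender"].value
                new["gender"] = (Gender.FEMALE if new["gender"] == Gender.MALE
                                 else Gender.MALE)
                after["gender"] = new["gender"].value
                applied.append("gender")
            else:  # scr
                lo_s, hi_s = config.scr_shift_range
                steps_lo = int(round(lo_s / config.scr_step))
                steps_hi = int(round(hi_s / config.scr_step))
                ok = False
                for _ in range(_MAX_REDRAWS):
                    k = int(rng.integers(steps_lo, steps_hi + 1))
                    shift = k * config.scr_step * (1 if rng.random() < 0.5 else -1)
                    cand = round(new["scr"] + shift, 10)
                    if config.scr_bounds[0] - 1e-9 <= cand <= config.scr_bounds[1] + 1e-9:
                        before["scr"], after["scr"] = new["scr"], cand
                        new["scr"] = cand
                        ok = True
                        break
                if ok:
                    applied.append("scr")
        now_records.append(PatientSnapshot(
            patient_id=snap.patient_id, dob=new["dob"], gender=new["gender"],
            race_detail=new["race_detail"], scr=new["scr"], lab_date=snap.lab_date,
        ))
        truths.append(GroundTruth(
            patient_id=snap.patient_id,
            changed_parameters=frozenset(applied),
            before=before, after=after,
        ))
    return now_records, truths


def cohort_frame(now_records: List[PatientSnapshot],
                 automated: np.ndarray) -> pd.DataFrame:
    """Assemble the cohort table the pipeline consumes: as-stored ("now")
    demographics alongside the automated eGFR computed at lab time."""
    if len(now_records) != len(automated):
        raise ValueError("records and automated values misaligned")
    return pd.DataFrame({
        "patient_id": [s.patient_id for s in now_records],
        "dob": [s.dob for s in now_records],
        "gender": [s.gender.value for s in now_records],
        "race": [s.race_detail.value for s in now_records],
        "scr": [s.scr for s in now_records],
        "automated_egfr": np.asarray(automated, dtype=float),
        "lab_date": [s.lab_date for s in now_records],
    }, columns=list(COHORT_COLUMNS))


def truth_frame(truths: List[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": [t.patient_id for t in truths],
        "changed_parameters": ["|".join(sorted(t.changed_parameters)) for t in truths],
        "before": [json.dumps(t.before, sort_keys=True) for t in truths],
        "after": [json.dumps(t.after, sort_keys=True) for t in truths],
    })


def emit_cohort(
    now_records: List[PatientSnapshot],
    automated: np.ndarray,
    path: Union[str, Path],
    truths: Optional[List[GroundTruth]] = None,
    config: Optional[SimulationConfig] = None,
) -> None:
    """Write the cohort CSV (and, alongside, ground truth + provenance JSON).

    The ground-truth file is never read by the analysis pipeline; it exists
    only so recovery of injected causes can be scored afterwards.
    """
    path = Path(path)
    write_cohort(cohort_frame(now_records, automated), path)
    if truths is not None:
        truth_frame(truths).to_csv(path.with_name(path.stem + "_truth.csv"), index=False)
    if config is not None:
        prov = {k: (v.isoformat() if isinstance(v, _dt.date) else v)
                for k, v in _config_dict(config).items()}
        path.with_name(path.stem + "_provenance.json").write_text(
            json.dumps(prov, indent=2, sort_keys=True) + "\n")


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["lab_window"] = [config.lab_window[0].isoformat(), config.lab_window[1].isoformat()]
    return d


def simulate_cohort(
    config: SimulationConfig,
    constants: EquationConstants = DEFAULT_CONSTANTS,
    policy: ComparisonPolicy = DEFAULT_POLICY,
):
    """Convenience: then-records, automated values, now-records, ground truth."""
    then, automated = simulate_truth(config, constants, policy)
    now, truths = apply_ehr_drift(then, config)
    return then, automated, now, truths
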