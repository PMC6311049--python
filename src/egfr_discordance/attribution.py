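"""Inverse enumeration of MDRD parameters and discordance attribution.

Given an automated eGFR that disagrees with the value recomputed from the
record as currently stored, this module answers: *which equation parameters,
changed since the lab was run, could explain the disagreement?*

The procedure:

1. (screen — see :mod:`.concordance`) keep only pairs unequal after
   conservative whole-number rounding;
2. enumerate the MDRD equation over every grid combination of integer age
   18–120, gender, binary black/non-black race, and Scr 0.10–30.0 mg/dL,
   round each generated eGFR to the nearest tenth, and index combinations
   by rounded value (generated values span 1.0–251.0 after clipping);
3. among the combinations reproducing the automated value, keep those
   agreeing with the current record on the most parameters;
4. the parameters on which those best candidates still disagree are the
   candidate explanations; a single distinct mismatch set is definitive,
   several distinct sets yield a disjunctive ("Race or age") explanation.

The index keys rounded eGFR as an integer number of tenths to avoid
floating-point key instability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .concordance import EgfrPair
from .egfr import (
    DEFAULT_CONSTANTS,
    DEFAULT_POLICY,
    ComparisonPolicy,
    EquationConstants,
    PatientSnapshot,
    RoundingMode,
    mdrd_egfr,
)

__all__ = [
    "ParameterGrid",
    "CandidateCombo",
    "InverseIndex",
    "AttributionResult",
    "build_inverse_index",
    "candidates_for_value",
    "match_count",
    "attribute_pair",
    "attribute_pair_bruteforce",
    "categorize_explanation",
    "explanation_super_category",
    "PARAMETERS",
]

#: the four MDRD equation parameters, in canonical order
PARAMETERS = ("age", "gender", "race", "scr")


@dataclass(frozen=True)
class ParameterGrid:
    """The enumeration grid: integer ages, both genders, binary race, and a
    fine Scr lattice; generated eGFR values are clipped to [1.0, 251.0]."""

    age_min: int = 18
    age_max: int = 120
    scr_min: float = 0.10
    scr_max: float = 30.0
    scr_step: float = 0.01
    egfr_clip: Tuple[float, float] = (1.0, 251.0)

    def __post_init__(self) -> None:
        if self.age_min > self.age_max or self.scr_min > self.scr_max:
            raise ValueError("empty grid range")
        if self.scr_step <= 0:
            raise ValueError("scr_step must be positive")
        n = (self.scr_max - self.scr_min) / self.scr_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("scr_step must divide the Scr range evenly")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max + 1, dtype=np.int64)

    @property
    def scr_values(self) -> np.ndarray:
        n = int(round((self.scr_max - self.scr_min) / self.scr_step)) + 1
        return np.round(self.scr_min + self.scr_step * np.arange(n), 10)

    @property
    def size(self) -> int:
        return len(self.ages) * 2 * 2 * len(self.scr_values)

    def scr_on_grid(self, scr: float) -> bool:
        k = (scr - self.scr_min) / self.scr_step
        return (self.scr_min - 1e-9 <= scr <= self.scr_max + 1e-9
                and abs(k - round(k)) < 1e-6)

    def snapshot_on_grid(self, snap: PatientSnapshot) -> bool:
        return self.age_min <= snap.age <= self.age_max and self.scr_on_grid(snap.scr)


DEFAULT_GRID = ParameterGrid()


@dataclass(frozen=True)
class CandidateCombo:
    """A grid point together with its rounded generated eGFR."""

    age: int
    female: bool
    black: bool
    scr: float
    egfr_rounded: float


def _scale_key(values, precision: float, mode: RoundingMode) -> np.ndarray:
    """Integer key = rounded value / precision (e.g. tenths for 0.1)."""
    x = np.asarray(values, dtype=float) / precision
    if mode == RoundingMode.HALF_AWAY_FROM_ZERO:
        k = np.floor(x + 0.5)  # eGFR is positive
    else:
        k = np.round(x)
    return k.astype(np.int64)


def _enumerate(grid: ParameterGrid, constants: EquationConstants,
               policy: ComparisonPolicy):
    """Flat arrays (age, female, black, scr, key) over the full grid."""
    ages = grid.ages
    scrs = grid.scr_values
    genders = np.array([False, True])  # female flag
    races = np.array([False, True])  # black flag
    A, G, R, S = np.meshgrid(ages, genders, races, scrs, indexing="ij")
    age = A.ravel()
    female = G.ravel()
    black = R.ravel()
    scr = S.ravel()
    egfr = mdrd_egfr(age, scr, female, black, constants)
    key = _scale_key(egfr, policy.inversion_precision, policy.rounding_mode)
    return age, female, black, scr, key


@dataclass
class InverseIndex:
    """Mapping from rounded eGFR (integer-scaled key) to grid combinations.

    Stored as flat arrays sorted by key with binary-search lookup; combos
    whose rounded value falls outside the clip range live in a separate
    bucket unless ``drop_out_of_clip`` was set at build time.
    """

    grid: ParameterGrid
    constants: EquationConstants
    policy: ComparisonPolicy
    drop_out_of_clip: bool
    # sorted-by-key flat arrays for in-clip combos
    keys: np.ndarray
    age: np.ndarray
    female: np.ndarray
    black: np.ndarray
    scr: np.ndarray
    # out-of-clip bucket (same layout), empty when dropped
    oc_keys: np.ndarray
    oc_age: np.ndarray
    oc_female: np.ndarray
    oc_black: np.ndarray
    oc_scr: np.ndarray

    @property
    def n_in_clip(self) -> int:
        return len(self.keys)

    @property
    def n_out_of_clip(self) -> int:
        return len(self.oc_keys)

    def key_for(self, egfr_value: float) -> int:
        return int(_scale_key(egfr_value, self.policy.inversion_precision,
                              self.policy.rounding_mode))

    def _slice(self, key: int, keys: np.ndarray) -> slice:
        lo = int(np.searchsorted(keys, key, side="left"))
        hi = int(np.searchsorted(keys, key, side="right"))
        return slice(lo, hi)

    def lookup_arrays(self, egfr_value: float):
        """Candidate arrays (age, female, black, scr) for a query value,
        searching the in-clip index and, when kept, the out-of-clip bucket."""
        key = self.key_for(egfr_value)
        lo_key = self.key_for(self.grid.egfr_clip[0])
        hi_key = self.key_for(self.grid.egfr_clip[1])
        if lo_key <= key <= hi_key:
            s = self._slice(key, self.keys)
            return self.age[s], self.female[s], self.black[s], self.scr[s]
        if self.drop_out_of_clip:
            e = np.empty(0)
            return e.astype(int), e.astype(bool), e.astype(bool), e
        s = self._slice(key, self.oc_keys)
        return self.oc_age[s], self.oc_female[s], self.oc_black[s], self.oc_scr[s]


def build_inverse_index(
    grid: ParameterGrid = DEFAULT_GRID,
    constants: EquationConstants = DEFAULT_CONSTANTS,
    policy: ComparisonPolicy = DEFAULT_POLICY,
    drop_out_of_clip: bool = False,
) -> InverseIndex:
    """Enumerate the grid and build the rounded-eGFR -> combinations index."""
    if grid.size == 0:
        raise ValueError("empty grid")
    age, female, black, scr, key = _enumerate(grid, constants, policy)
    lo = int(_scale_key(grid.egfr_clip[0], policy.inversion_precision, policy.rounding_mode))
    hi = int(_scale_key(grid.egfr_clip[1], policy.inversion_precision, policy.rounding_mode))
    in_clip = (key >= lo) & (key <= hi)
    order = np.argsort(key[in_clip], kind="stable")

    def _take(mask, order_):
        return (key[mask][order_], age[mask][order_], female[mask][order_],
                black[mask][order_], scr[mask][order_])

    k_in, a_in, f_in, b_in, s_in = _take(in_clip, order)
    if drop_out_of_clip:
        empty = np.empty(0)
        oc = (empty.astype(np.int64), empty.astype(np.int64),
              empty.astype(bool), empty.astype(bool), empty)
    else:
        out = ~in_clip
        order_oc = np.argsort(key[out], kind="stable")
        oc = _take(out, order_oc)
    return InverseIndex(
        grid=grid, constants=constants, policy=policy,
        drop_out_of_clip=drop_out_of_clip,
        keys=k_in, age=a_in, female=f_in, black=b_in, scr=s_in,
        oc_keys=oc[0], oc_age=oc[1], oc_female=oc[2], oc_black=oc[3], oc_scr=oc[4],
    )


def candidates_for_value(index: InverseIndex, egfr_value: float) -> List[CandidateCombo]:
    """All grid combinations whose rounded MDRD eGFR equals the query value."""
    age, female, black, scr, = index.lookup_arrays(egfr_value)
    prec = index.policy.inversion_precision
    key = index.key_for(egfr_value)
    rounded = key * prec
    return [
        CandidateCombo(age=int(a), female=bool(f), black=bool(b),
                       scr=float(s), egfr_rounded=float(rounded))
        for a, f, b, s in zip(age, female, black, scr)
    ]


def match_count(candidate: CandidateCombo, current: PatientSnapshot,
                scr_tolerance: float = DEFAULT_GRID.scr_step / 2) -> int:
    """How many of the four parameters the candidate shares with the record."""
    n = 0
    n += candidate.age == current.age
    n += candidate.female == current.female
    n += candidate.black == current.race_black
    n += abs(candidate.scr - current.scr) <= scr_tolerance
    return int(n)


@dataclass(frozen=True)
class AttributionResult:
    """Outcome of steps 2–4 for one screened pair.

    ``mismatch_sets`` holds, for each best-matching candidate, the set of
    parameters on which it disagrees with the current record; ``definitive``
    means a single distinct set remained. ``abs_parameter_difference`` is
    populated for definitive single-parameter explanations over a numeric
    parameter (years for age, mg/dL for Scr), taking the smallest absolute
    difference among best candidates.
    """

    pair_id: str
    status: str  # "match" | "explained" | "unexplained"
    max_match_count: int
    mismatch_sets: FrozenSet[FrozenSet[str]]
    definitive: bool
    category_label: Optional[str]
    abs_value_difference: float
    abs_parameter_difference: Dict[str, float] = field(default_factory=dict)
    reason: Optional[str] = None


def _finish_attribution(
    pair: EgfrPair,
    current: PatientSnapshot,
    cand_age: np.ndarray,
    cand_female: np.ndarray,
    cand_black: np.ndarray,
    cand_scr: np.ndarray,
    scr_tolerance: float,
    tie_strategy: str,
) -> AttributionResult:
    """Steps 3–4 given the candidate arrays for the automated value."""
    abs_diff = abs(pair.automated_report - pair.retro_report)
    if len(cand_age) == 0:
        return AttributionResult(
            pair_id=pair.patient_id, status="unexplained", max_match_count=0,
            mismatch_sets=frozenset(), definitive=False, category_label=None,
            abs_value_difference=abs_diff, reason="no_candidates",
        )
    m_age = cand_age == current.age
    m_gender = cand_female == current.female
    m_race = cand_black == current.race_black
    m_scr = np.abs(cand_scr - current.scr) <= scr_tolerance
    counts = (m_age.astype(np.int8) + m_gender.astype(np.int8)
              + m_race.astype(np.int8) + m_scr.astype(np.int8))
    m_star = int(counts.max())
    if m_star == 4:
        # the current record itself reproduces the automated value: the
        # screen-level disagreement is a rounding artifact, not drift
        return AttributionResult(
            pair_id=pair.patient_id, status="match", max_match_count=4,
            mismatch_sets=frozenset(), definitive=False, category_label=None,
            abs_value_difference=abs_diff,
        )
    best = counts == m_star
    sets = set()
    best_idx = np.nonzero(best)[0]
    for i in best_idx:
        s = []
        if not m_age[i]:
            s.append("age")
        if not m_gender[i]:
            s.append("gender")
        if not m_race[i]:
            s.append("race")
        if not m_scr[i]:
            s.append("scr")
        sets.add(frozenset(s))
    if tie_strategy == "prefer-demographic":
        demo_only = {s for s in sets if "scr" not in s}
        if demo_only:
            sets = demo_only
    mismatch_sets = frozenset(sets)
    definitive = len(sets) == 1
    param_diff: Dict[str, float] = {}
    if definitive:
        (only,) = sets
        if only == frozenset({"age"}):
            diffs = np.abs(cand_age[best_idx] - current.age)
            param_diff["age"] = float(diffs.min())
        elif only == frozenset({"scr"}):
            diffs = np.abs(cand_scr[best_idx] - current.scr)
            param_diff["scr"] = float(diffs.min())
    result = AttributionResult(
        pair_id=pair.patient_id, status="explained", max_match_count=m_star,
        mismatch_sets=mismatch_sets, definitive=definitive, category_label=None,
        abs_value_difference=abs_diff, abs_parameter_difference=param_diff,
    )
    label = categorize_explanation(result)
    return AttributionResult(
        pair_id=result.pair_id, status=result.status,
        max_match_count=result.max_match_count, mismatch_sets=result.mismatch_sets,
        definitive=result.definitive, category_label=label,
        abs_value_difference=result.abs_value_difference,
        abs_parameter_difference=result.abs_parameter_difference,
    )


def _match_result(pair: EgfrPair) -> AttributionResult:
    return AttributionResult(
        pair_id=pair.patient_id, status="match", max_match_count=4,
        mismatch_sets=frozenset(), definitive=False, category_label=None,
        abs_value_difference=abs(pair.automated_report - pair.retro_report),
    )


def _off_grid_result(pair: EgfrPair, reason: str) -> AttributionResult:
    return AttributionResult(
        pair_id=pair.patient_id, status="unexplained", max_match_count=0,
        mismatch_sets=frozenset(), definitive=False, category_label=None,
        abs_value_difference=abs(pair.automated_report - pair.retro_report),
        reason=reason,
    )


def attribute_pair(
    pair: EgfrPair,
    current: PatientSnapshot,
    index: InverseIndex,
    scr_tolerance: Optional[float] = None,
    tie_strategy: str = "disjunction",
) -> AttributionResult:
    """Attribute a screened pair's discordance to changed parameters.

    A concordant pair returns status ``match``. Otherwise the automated
    value is looked up in the inverse index, the candidates agreeing with
    the current record on the most parameters are kept, and the distinct
    sets of still-disagreeing parameters are reported. ``tie_strategy``
    ``"disjunction"`` reports every tied set; ``"prefer-demographic"``
    discards Scr-involving sets when an all-demographic set ties.
    """
    if pair.concordant_value:
        return _match_result(pair)
    if not index.grid.snapshot_on_grid(current):
        return _off_grid_result(pair, "off_grid")
    if scr_tolerance is None:
        scr_tolerance = index.grid.scr_step / 2
    cand = index.lookup_arrays(pair.automated_report)
    return _finish_attribution(pair, current, *cand, scr_tolerance, tie_strategy)


def attribute_pair_bruteforce(
    pair: EgfrPair,
    current: PatientSnapshot,
    grid: ParameterGrid = DEFAULT_GRID,
    constants: EquationConstants = DEFAULT_CONSTANTS,
    policy: ComparisonPolicy = DEFAULT_POLICY,
    scr_tolerance: Optional[float] = None,
    tie_strategy: str = "disjunction",
    drop_out_of_clip: bool = False,
) -> AttributionResult:
    """Independent oracle: identical contract to :func:`attribute_pair`, but
    scans the whole grid directly with no prebuilt index."""
    if pair.concordant_value:
        return _match_result(pair)
    if not grid.snapshot_on_grid(current):
        return _off_grid_result(pair, "off_grid")
    if scr_tolerance is None:
        scr_tolerance = grid.scr_step / 2
    age, female, black, scr, key = _enumerate(grid, constants, policy)
    lo = int(_scale_key(grid.egfr_clip[0], policy.inversion_precision, policy.rounding_mode))
    hi = int(_scale_key(grid.egfr_clip[1], policy.inversion_precision, policy.rounding_mode))
    q = int(_scale_key(pair.automated_report, policy.inversion_precision,
                       policy.rounding_mode))
    hit = key == q
    if drop_out_of_clip:
        hit &= (key >= lo) & (key <= hi)
    return _finish_attribution(
        pair, current, age[hit], female[hit], black[hit], scr[hit],
        scr_tolerance, tie_strategy,
    )


_DEMO_ORDER = ("race", "gender", "age")


def categorize_explanation(result: AttributionResult) -> str:
    """Explanation-taxonomy label for a non-match attribution.

    Definitive singletons map to "Age" / "Race" / "Gender" / "1 clinical";
    definitive multi-parameter sets to counts ("2 demographics",
    "1 demographic 1 clinical"); non-definitive unions of demographic
    singletons to disjunctions in canonical race/gender/age order
    ("Race or age"); unions involving Scr get an extended "Scr or ..." label.
    """
    if result.status == "match":
        raise ValueError("cannot categorize a matched pair")
    if result.status == "unexplained":
        return "Unexplained"
    sets = result.mismatch_sets
    if not sets or any(not s for s in sets):
        raise ValueError("explained result carries an empty mismatch set")
    if len(sets) == 1:
        (only,) = sets
        if len(only) == 1:
            (p,) = only
            return {"age": "Age", "gender": "Gender", "race": "Race",
                    "scr": "1 clinical"}[p]
        n_demo = len(only - {"scr"})
        n_clin = len(only & {"scr"})
        parts = []
        if n_demo:
            parts.append(f"{n_demo} demographic" + ("s" if n_demo > 1 else ""))
        if n_clin:
            parts.append("1 clinical")
        return " ".join(parts)
    # non-definitive: a disjunction of tied explanations
    if all(len(s) == 1 for s in sets):
        params = {next(iter(s)) for s in sets}
        demo = [p for p in _DEMO_ORDER if p in params]
        words = [p.capitalize() for p in demo]
        if "scr" in params:
            words = ["Scr"] + [w.lower() for w in words]
        else:
            words = [words[0]] + [w.lower() for w in words[1:]]
        if len(words) == 2:
            return f"{words[0]} or {words[1]}"
        return ", ".join(words[:-1]) + f", or {words[-1]}"
    # mixed-cardinality ties: serialize canonically
    def ser(s):
        return "+".join(p for p in PARAMETERS if p in s)
    return " or ".join(sorted(ser(s) for s in sets))


def explanation_super_category(result: AttributionResult) -> Optional[str]:
    """Table-style super-category ("1 demographic", "1 clinical",
    "2 demographics", "1 demographic 1 clinical") for an attribution."""
    if result.status != "explained":
        return None
    sets = result.mismatch_sets
    if all(len(s) == 1 and "scr" not in s for s in sets):
        return "1 demographic"
    if len(sets) == 1:
        (only,) = sets
        n_demo = len(only - {"scr"})
        n_clin = len(only & {"scr"})
        if n_clin and not n_demo:
            return "1 clinical"
        if n_demo == 1 and n_clin == 1:
            return "1 demographic 1 clinical"
        if n_demo == 2 and not n_clin:
            return "2 demographics"
    return "other"
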