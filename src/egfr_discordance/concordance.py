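"""Pairing automated with retrospectively calculated eGFR and the
method-comparison statistics: the conservative discordance screen,
Bland–Altman limits of agreement, the CKD stage agreement matrix,
percent agreement, and Cohen's kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .cohort import CohortRow
from .egfr import (
    DEFAULT_CONSTANTS,
    DEFAULT_POLICY,
    DEFAULT_STAGES,
    ComparisonPolicy,
    EquationConstants,
    StageScheme,
    assign_stage,
    mdrd_egfr,
    round_to_precision,
)

__all__ = [
    "EgfrPair",
    "BlandAltmanSummary",
    "StageAgreementMatrix",
    "KappaResult",
    "build_pair",
    "build_pairs",
    "bland_altman",
    "stage_agreement",
    "cohen_kappa",
]


@dataclass(frozen=True)
class EgfrPair:
    """An automated and a retrospectively calculated eGFR for one patient/date.

    ``difference`` is automated minus retrospective throughout;
    ``concordant_value`` reflects equality after rounding both sides at the
    screen precision (whole numbers by default).
    """

    patient_id: str
    automated_raw: float
    retro_raw: float
    automated_screen: float
    retro_screen: float
    automated_report: float
    retro_report: float
    concordant_value: bool
    stage_automated: str
    stage_retro: str
    concordant_stage: bool
    difference: float


def build_pair(
    row: CohortRow,
    policy: ComparisonPolicy = DEFAULT_POLICY,
    constants: EquationConstants = DEFAULT_CONSTANTS,
    scheme: StageScheme = DEFAULT_STAGES,
) -> EgfrPair:
    """Compute the retrospective eGFR from the as-stored record and screen it
    against the automated value.

    The retrospective value applies the MDRD equation to the *current*
    demographics (age in completed years at lab date from the current DOB)
    and current Scr. Stages are assigned from report-precision values.
    """
    snap = row.snapshot
    retro_raw = mdrd_egfr(snap.age, snap.scr, snap.female, snap.race_black, constants)
    auto_raw = row.automated_egfr
    mode = policy.rounding_mode
    # values are stored at report precision; the screen rounds the *stored*
    # values (58.9 -> 59, 62.7 -> 63), not the unrounded ones, so a pair
    # identical as stored can never screen discordant
    a_report = round_to_precision(auto_raw, policy.report_precision, mode)
    r_report = round_to_precision(retro_raw, policy.report_precision, mode)
    a_screen = round_to_precision(a_report, policy.screen_precision, mode)
    r_screen = round_to_precision(r_report, policy.screen_precision, mode)
    st_a = assign_stage(a_report, scheme)
    st_r = assign_stage(r_report, scheme)
    return EgfrPair(
        patient_id=snap.patient_id,
        automated_raw=auto_raw,
        retro_raw=retro_raw,
        automated_screen=a_screen,
        retro_screen=r_screen,
        automated_report=a_report,
        retro_report=r_report,
        concordant_value=(a_screen == r_screen),
        stage_automated=st_a,
        stage_retro=st_r,
        concordant_stage=(st_a == st_r),
        difference=auto_raw - retro_raw,
    )


def build_pairs(rows, policy=DEFAULT_POLICY, constants=DEFAULT_CONSTANTS,
                scheme=DEFAULT_STAGES) -> List[EgfrPair]:
    return [build_pair(r, policy, constants, scheme) for r in rows]


@dataclass(frozen=True)
class BlandAltmanSummary:
    n: int
    mean_difference: float
    sd_difference: float
    loa_multiplier: float
    loa_lower: float
    loa_upper: float
    mean_automated: float
    mean_retro: float
    #: plot-ready (mean of pair, difference) tuples
    points: Tuple[Tuple[float, float], ...]


def bland_altman(pairs: Sequence[EgfrPair], multiplier: float = 2.0) -> BlandAltmanSummary:
    """Bland–Altman summary of automated minus retrospective differences.

    Limits of agreement are mean +/- ``multiplier`` x SD, with the sample SD
    (n-1 denominator). The default multiplier is 2.
    """
    if len(pairs) < 2:
        raise ValueError("Bland–Altman requires at least two pairs")
    auto = np.array([p.automated_raw for p in pairs])
    retro = np.array([p.retro_raw for p in pairs])
    diff = auto - retro
    mean_d = float(diff.mean())
    sd_d = float(diff.std(ddof=1))
    return BlandAltmanSummary(
        n=len(pairs),
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_multiplier=multiplier,
        loa_lower=mean_d - multiplier * sd_d,
        loa_upper=mean_d + multiplier * sd_d,
        mean_automated=float(auto.mean()),
        mean_retro=float(retro.mean()),
        points=tuple(zip(((auto + retro) / 2).tolist(), diff.tolist())),
    )


@dataclass(frozen=True)
class StageAgreementMatrix:
    """Counts indexed (automated stage, retrospective stage)."""

    labels: Tuple[str, ...]
    counts: np.ndarray  # shape (k, k)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def stage_agreement(
    pairs: Sequence[EgfrPair],
    scheme: StageScheme = DEFAULT_STAGES,
) -> Tuple[StageAgreementMatrix, float]:
    """Stage agreement matrix and percent agreement (100 x trace / total)."""
    if not pairs:
        raise ValueError("stage agreement requires at least one pair")
    labels = tuple(scheme.labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for p in pairs:
        counts[idx[p.stage_automated], idx[p.stage_retro]] += 1
    pct = 100.0 * float(np.trace(counts)) / float(counts.sum())
    return StageAgreementMatrix(labels=labels, counts=counts), pct


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci_lower: float
    ci_upper: float
    percent_agreement: float

    @property
    def kappa_x100(self) -> float:
        """Kappa on the 0-100 scale used in clinical agreement tables."""
        return 100.0 * self.kappa

    @property
    def ci_x100(self) -> Tuple[float, float]:
        return (100.0 * self.ci_lower, 100.0 * self.ci_upper)


def cohen_kappa(matrix: StageAgreementMatrix) -> Optional[KappaResult]:
    """Unweighted Cohen's kappa with a large-sample (Fleiss–Cohen) SE and
    95% normal confidence interval.

    Returns ``None`` when kappa is undefined (expected agreement is 1, i.e.
    both raters are constant on the same category).
    """
    c = matrix.counts.astype(float)
    n = c.sum()
    if n <= 0:
        raise ValueError("empty agreement matrix")
    p = c / n
    po = float(np.trace(p))
    pi = p.sum(axis=1)  # automated margins
    pj = p.sum(axis=0)  # retrospective margins
    pe = float(pi @ pj)
    if math.isclose(pe, 1.0, abs_tol=1e-15):
        return None
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss, Cohen & Everitt large-sample variance of kappa-hat
    diag = np.diag(p)
    a = float(np.sum(diag * (1.0 - (pi + pj) * (1.0 - kappa)) ** 2))
    off = p * (pj[None, :] + pi[:, None]) ** 2
    np.fill_diagonal(off, 0.0)
    b = float((1.0 - kappa) ** 2 * off.sum())
    cterm = (kappa - pe * (1.0 - kappa)) ** 2
    var = (a + b - cterm) / (n * (1.0 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    z = 1.959963984540054
    return KappaResult(
        kappa=kappa,
        se=se,
        ci_lower=kappa - z * se,
        ci_upper=kappa + z * se,
        percent_agreement=100.0 * po,
    )
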