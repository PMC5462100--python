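"""Single-trial engine for overdose-controlled dose escalation.

A trial of N patients proceeds as:

1. Dose patient 1 at the lowest dose.  If a DLT occurs, stop the trial for
   safety re-evaluation (the trial is flagged ``stopped_early`` and yields
   no MTD estimate).
2. For each subsequent patient n+1: set the feasibility bound α_{n+1} from
   the schedule and the outcomes of patients 1..n, update the MTD posterior
   H_n with all accrued data, and assign

       x(n+1) = arg min_{l ∈ L} | H_n^{-1}(α_{n+1}) − l |,

   i.e. the administrable dose closest to the posterior α-quantile
   (continuous doses are rounded to the nearest integer mg/m²; equidistant
   discrete ties go to the lower level).
3. After patient N, report the posterior-median MTD estimate γ̂ and the
   next-dose estimate γ̃ = H_N^{-1}(α_{N+1}) (projected onto the space).

A *coherence violation* is an escalation immediately after a DLT:
x(n+1) > x(n) with y_n = 1.  Schedules whose bound never rises after a DLT
never produce one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose import DoseSpace
from .feasibility import FeasibilitySchedule
from .posterior import GridPosterior, PosteriorMTD, PriorSpec, TrialData, mtd_quantile

__all__ = [
    "TrialRecord",
    "Violation",
    "TrialResult",
    "select_dose",
    "run_trial",
    "detect_violations",
    "estimate_mtd",
]


@dataclass(frozen=True)
class TrialRecord:
    patient: int
    alpha: float | None  # None for patient 1 (no posterior is consulted)
    dose: float
    dlt: int


@dataclass(frozen=True)
class Violation:
    patient: int          # index of the incoherently dosed patient (n+1)
    previous_dose: float  # x(n), at which the DLT was observed
    new_dose: float       # x(n+1) > x(n)

    @property
    def magnitude(self) -> float:
        return self.new_dose - self.previous_dose


@dataclass(frozen=True)
class TrialResult:
    records: tuple[TrialRecord, ...]
    stopped_early: bool
    mtd_median: float | None
    mtd_next_dose: float | None
    alpha_final: float | None  # α_{N+1}, the bound behind γ̃
    violations: tuple[Violation, ...]

    @property
    def doses(self) -> np.ndarray:
        return np.array([r.dose for r in self.records])

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([r.dlt for r in self.records])

    @property
    def n_dlts(self) -> int:
        return int(sum(r.dlt for r in self.records))


def select_dose(posterior: PosteriorMTD, alpha: float,
                space: DoseSpace) -> float:
    """Administrable dose nearest the posterior α-quantile of the MTD."""
    return space.project(mtd_quantile(posterior, alpha, space))


def estimate_mtd(posterior: PosteriorMTD, method: str, space: DoseSpace,
                 alpha_next: float | None = None) -> float:
    """End-of-trial MTD estimate.

    ``method="median"`` returns H_N^{-1}(0.50); ``method="next_dose"``
    returns the dose a further patient would receive, H_N^{-1}(α_{N+1}).
    Both are projected onto the dose space (integer rounding or nearest
    discrete level).
    """
    if method == "median":
        return space.project(mtd_quantile(posterior, 0.5, space))
    if method == "next_dose":
        if alpha_next is None:
            raise ValueError("next_dose estimator needs alpha_next")
        return select_dose(posterior, alpha_next, space)
    raise ValueError(f"unknown MTD estimator {method!r}")


def detect_violations(result: TrialResult | tuple[TrialRecord, ...]) -> tuple[Violation, ...]:
    """All escalations immediately following a DLT."""
    records = result.records if isinstance(result, TrialResult) else tuple(result)
    out = []
    for prev, cur in zip(records, records[1:]):
        if prev.dlt == 1 and cur.dose > prev.dose:
            out.append(Violation(cur.patient, prev.dose, cur.dose))
    return tuple(out)


def run_trial(scenario, schedule: FeasibilitySchedule, prior: PriorSpec,
              space: DoseSpace, N: int, seed=None,
              theta: float = 1.0 / 3.0, resolution: int = 400,
              engine: GridPosterior | None = None,
              rng: np.random.Generator | None = None) -> TrialResult:
    """Simulate one trial of ``N`` patients.

    ``scenario`` is any object with a ``prob(dose)`` method giving the true
    DLT probability.  Outcomes are Bernoulli draws from a dedicated
    generator (``seed`` or an explicit ``rng``), so a given seed is
    bit-reproducible.  Pass a shared ``engine`` when batching trials so the
    quadrature nodes and per-dose likelihood caches are built once.
    """
    if N < 2:
        raise ValueError("need N >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    if engine is None:
        engine = GridPosterior(prior, space, theta=theta,
                               resolution=resolution)

    first = space.lowest
    y1 = int(rng.random() < float(scenario.prob(first)))
    records = [TrialRecord(1, None, first, y1)]
    if y1 == 1:
        return TrialResult(tuple(records), True, None, None, None, ())

    loglik = engine.zero_loglik()
    loglik += engine.loglik_terms(first)[y1]
    outcomes = [y1]

    posterior = None
    for m in range(2, N + 1):
        alpha_m = schedule.alpha(m, outcomes)
        posterior = engine.assemble(loglik)
        dose = select_dose(posterior, alpha_m, space)
        y = int(rng.random() < float(scenario.prob(dose)))
        records.append(TrialRecord(m, alpha_m, dose, y))
        outcomes.append(y)
        loglik += engine.loglik_terms(dose)[y]

    final_posterior = engine.assemble(loglik)
    alpha_next = schedule.alpha(N + 1, outcomes)
    mtd_median = estimate_mtd(final_posterior, "median", space)
    mtd_next = estimate_mtd(final_posterior, "next_dose", space,
                            alpha_next=alpha_next)
    result = TrialResult(tuple(records), False, mtd_median, mtd_next,
                         alpha_next, ())
    return TrialResult(result.records, False, mtd_median, mtd_next,
                       alpha_next, detect_violations(result))
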