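"""Feasibility-bound schedules for overdose-controlled dose escalation.

The feasibility bound α is the posterior probability that the assigned dose
exceeds the true MTD; dosing at the α-quantile of the MTD posterior makes
overdosing by any amount (1 − α)/α times as costly as underdosing by the
same amount.  Five schedules are provided:

* ``fixed`` — α constant (originally 0.25) throughout the trial.
* ``tr``    — α = 0.25 for patients 2–9, then +0.05 per patient up to 0.50
  at patient 14 (a stepwise ramp used in practice).
* ``hybrid``— α starts at αmin and climbs in N/2 − 1 equal increments to
  0.50 at patient N/2 + 1.
* ``eat``   — escalation in the absence of toxicity: α starts at αmin and
  gains a fixed increment (default 0.05) only after a non-DLT outcome.
* ``tdfb``  — toxicity-dependent feasibility bound,

      α_{n+1} = min(0.50, αmin + (0.50 − αmin)(n − 1 − Σ_{i≤n} y_i)/S),

  where n − 1 − Σ y_i counts non-DLT responses after patient 1 and S is the
  number of such responses required before dosing at the posterior median.
  Choosing S = (N/2 − 1)(1 − θ) makes E[α] reach 0.50 when half the trial
  has been dosed.

Schedules that only increase after a non-DLT (``fixed`` trivially, ``eat``,
``tdfb``) guarantee coherent dose escalation; ``tr`` and ``hybrid`` do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "fixed_alpha",
    "tr_alpha",
    "hybrid_alpha",
    "eat_alpha",
    "tdfb_alpha",
    "choose_S",
    "expected_alpha",
    "loss_ratio",
    "FeasibilitySchedule",
    "FixedSchedule",
    "TRSchedule",
    "HybridSchedule",
    "EATSchedule",
    "TDFBSchedule",
    "make_schedule",
]

CAP = 0.50


def fixed_alpha(alpha_fixed: float = 0.25) -> float:
    """Constant feasibility bound (the original overdose-control choice)."""
    if not 0.0 < alpha_fixed <= CAP:
        raise ValueError("alpha_fixed must lie in (0, 0.50]")
    return alpha_fixed


def tr_alpha(n: int) -> float:
    """Stepwise ramp: 0.25 for patients 2–9, +0.05 per patient for 10–14,
    0.50 thereafter.  Patient 1 is dosed at xmin, so n ≥ 2."""
    if n < 2:
        raise ValueError("patient 1 is always dosed at xmin; need n >= 2")
    if n <= 9:
        return 0.25
    if n <= 14:
        return 0.25 + 0.05 * (n - 9)
    return CAP


def hybrid_alpha(n: int, alpha_min: float, N: int) -> float:
    """Linear ramp reaching 0.50 at patient N/2 + 1: α_2 = αmin and
    α_n = αmin + (0.50 − αmin)(n − 2)/(N/2 − 1), capped at 0.50."""
    if n < 2:
        raise ValueError("need n >= 2")
    if N < 4 or N % 2:
        raise ValueError("need even N >= 4")
    increments = N // 2 - 1
    return min(CAP, alpha_min + (CAP - alpha_min) * (n - 2) / increments)


def eat_alpha(alpha_min: float, non_dlt_count: int,
              increment: float = 0.05, cap: float = CAP) -> float:
    """Escalation in the absence of toxicity: one increment per non-DLT."""
    if non_dlt_count < 0:
        raise ValueError("non_dlt_count must be nonnegative")
    return min(cap, alpha_min + increment * non_dlt_count)


def tdfb_alpha(n: int, total_dlts: int, alpha_min: float, S: float,
               cap: float = CAP) -> float:
    """Toxicity-dependent bound α_{n+1} for the patient after patient n.

    ``total_dlts`` is Σ_{i=1}^{n} y_i; the numerator n − 1 − Σ y_i counts
    non-DLT responses excluding patient 1 (whose outcome must be 0 for the
    trial to continue).  Equals αmin at n = 1 and never exceeds the cap.
    """
    if S <= 0:
        raise ValueError("S must be strictly positive")
    if n < 1:
        raise ValueError("need n >= 1")
    if total_dlts > max(n - 1, 0):
        raise ValueError("total_dlts cannot exceed n - 1")
    return min(cap, alpha_min + (cap - alpha_min) * (n - 1 - total_dlts) / S)


def choose_S(N: int, theta: float) -> float:
    """S = (N/2 − 1)(1 − θ): E[α] first reaches 0.50 halfway through the
    trial when DLTs arrive at rate θ."""
    if N < 4:
        raise ValueError("need N >= 4")
    if not 0.0 <= theta < 1.0:
        raise ValueError("theta must lie in [0, 1)")
    return (N / 2 - 1) * (1 - theta)


def expected_alpha(n: int, alpha_min: float, S: float, theta: float) -> float:
    """Uncapped E[α_{n+1}] = αmin + (0.50 − αmin)(n − 1)(1 − θ)/S when DLT
    outcomes are i.i.d. Bernoulli(θ)."""
    if S <= 0:
        raise ValueError("S must be strictly positive")
    return alpha_min + (CAP - alpha_min) * (n - 1) * (1 - theta) / S


def loss_ratio(alpha: float) -> float:
    """Overdose-to-underdose loss ratio (1 − α)/α implied by dosing at the
    α-quantile of the MTD posterior."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return (1.0 - alpha) / alpha


# ---------------------------------------------------------------------------
# Stateful-schedule interface used by the trial engine.  A schedule maps the
# index of the next patient and the outcomes observed so far to α; all state
# is derived from the outcome sequence, so schedules are trivially replayable.
# ---------------------------------------------------------------------------


class FeasibilitySchedule:
    """Base class; subclasses implement :meth:`alpha`.

    ``ramp_opportunities`` is the per-trial count of α-increase
    opportunities used as the coherence-violation denominator (``None``
    when the schedule guarantees coherence); ``coherent`` says whether the
    bound can ever rise immediately after a DLT.
    """

    ramp_opportunities: int | None = None
    coherent: bool = True

    def alpha(self, n_next: int, outcomes: Sequence[int]) -> float:
        """Feasibility bound for patient ``n_next`` given outcomes of
        patients 1..n_next−1."""
        raise NotImplementedError


@dataclass(frozen=True)
class FixedSchedule(FeasibilitySchedule):
    alpha_fixed: float = 0.25

    def alpha(self, n_next: int, outcomes: Sequence[int]) -> float:
        return fixed_alpha(self.alpha_fixed)


@dataclass(frozen=True)
class TRSchedule(FeasibilitySchedule):
    ramp_opportunities = 5  # five ramp steps: patients 10..14
    coherent = False

    def alpha(self, n_next: int, outcomes: Sequence[int]) -> float:
        return tr_alpha(n_next)


@dataclass(frozen=True)
class HybridSchedule(FeasibilitySchedule):
    alpha_min: float = 0.25
    N: int = 40
    # α-increase opportunities during the ramp: N/2 − 1 equal increments
    # (19 for N = 40); pass the alternative convention counting dose
    # decisions (20) explicitly if wanted
    opportunities: int | None = None

    coherent = False

    @property
    def ramp_opportunities(self) -> int:
        return self.N // 2 - 1 if self.opportunities is None else self.opportunities

    def alpha(self, n_next: int, outcomes: Sequence[int]) -> float:
        return hybrid_alpha(n_next, self.alpha_min, self.N)


@dataclass(frozen=True)
class EATSchedule(FeasibilitySchedule):
    alpha_min: float = 0.10
    increment: float = 0.05
    cap: float = CAP

    def alpha(self, n_next: int, outcomes: Sequence[int]) -> float:
        # increments accrue from non-DLT outcomes of patients 2..n_next−1,
        # so that α_2 = αmin
        non_dlt = sum(1 for y in outcomes[1:] if y == 0)
        return eat_alpha(self.alpha_min, non_dlt, self.increment, self.cap)


@dataclass(frozen=True)
class TDFBSchedule(FeasibilitySchedule):
    alpha_min: float = 0.25
    S: float = 38.0 / 3.0
    cap: float = CAP

    @classmethod
    def with_auto_S(cls, alpha_min: float, N: int,
                    theta: float) -> "TDFBSchedule":
        return cls(alpha_min=alpha_min, S=choose_S(N, theta))

    def alpha(self, n_next: int, outcomes: Sequence[int]) -> float:
        n = n_next - 1
        if n < 1:
            raise ValueError("need n_next >= 2")
        return tdfb_alpha(n, int(sum(outcomes)), self.alpha_min, self.S,
                          self.cap)


def make_schedule(config: dict, N: int | None = None,
                  theta: float | None = None) -> FeasibilitySchedule:
    """Build a schedule from a flat config dict.

    Keys: ``scheme`` in {fixed, tr, hybrid, eat, tdfb}; plus
    ``alpha_fixed`` (fixed), ``alpha_min`` and ``N`` (hybrid),
    ``alpha_min``/``increment``/``cap`` (eat), ``alpha_min`` and ``S``
    (tdfb; ``S="auto"`` resolves via ``choose_S(N, theta)``).
    """
    scheme = config["scheme"]
    if scheme == "fixed":
        return FixedSchedule(alpha_fixed=config.get("alpha_fixed", 0.25))
    if scheme == "tr":
        return TRSchedule()
    if scheme == "hybrid":
        return HybridSchedule(alpha_min=config.get("alpha_min", 0.25),
                              N=config.get("N", N if N is not None else 40))
    if scheme == "eat":
        return EATSchedule(alpha_min=config.get("alpha_min", 0.10),
                           increment=config.get("increment", 0.05),
                           cap=config.get("cap", CAP))
    if scheme == "tdfb":
        S = config.get("S", "auto")
        if S == "auto":
            if N is None or theta is None:
                raise ValueError("S='auto' needs N and theta")
            S = choose_S(N, theta)
        return TDFBSchedule(alpha_min=config.get("alpha_min", 0.25),
                            S=float(S), cap=config.get("cap", CAP))
    raise ValueError(f"unknown feasibility scheme {scheme!r}")
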