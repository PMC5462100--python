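"""True dose–toxicity scenarios for trial simulation.

The working model throughout is the two-parameter logistic

    π(x; β0, β1) = expit(β0 + β1 x),       β1 > 0,

reparameterized through two clinically interpretable quantities: the maximum
tolerated dose γ (the dose with DLT probability equal to the target toxicity
level θ) and ρ0, the DLT probability at the lowest dose xmin:

    γ  = (logit θ − β0) / β1,
    ρ0 = expit(β0 + β1 xmin).

Given (γ, ρ0, θ, xmin) the logistic parameters follow in closed form:

    β1 = (logit θ − logit ρ0) / (γ − xmin),
    β0 = logit ρ0 − β1 xmin.

This module also provides the power and hyperbolic-tangent data-generating
models used for misspecification sensitivity analyses.  Those models are
never fitted: the working model is always the logistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .dose import DoseSpace

__all__ = [
    "DegenerateScenarioError",
    "LogisticScenario",
    "AltScenario",
    "solve_logistic_from_mtd",
    "dlt_probability",
    "make_discrete_scenario",
    "calibrate_alt_model",
    "alt_dlt_probability",
    "study_scenarios",
    "scenario_table",
]

# Clamp probabilities away from {0, 1} so logit never returns ±inf on
# degenerate inputs (e.g. ρ0 printed as 0.001 evaluated at extreme doses).
_EPS = 1e-15


def clamped_logit(p) -> np.ndarray | float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return np.log(p) - np.log1p(-p)


class DegenerateScenarioError(ValueError):
    """Raised when (γ, ρ0, θ, xmin) do not define a proper increasing curve."""


def solve_logistic_from_mtd(gamma: float, rho0: float, theta: float,
                            xmin: float) -> tuple[float, float]:
    """Solve (β0, β1) from the clinical parameterization (γ, ρ0, θ, xmin).

    Requires ``0 < rho0 < theta < 1`` and ``gamma > xmin``; otherwise the
    implied slope would be non-positive or infinite.
    """
    if not (0.0 < rho0 < 1.0 and 0.0 < theta < 1.0):
        raise DegenerateScenarioError("rho0 and theta must lie in (0, 1)")
    if rho0 >= theta:
        raise DegenerateScenarioError(
            f"rho0={rho0} >= theta={theta}: the MTD would lie below xmin")
    if gamma <= xmin:
        raise DegenerateScenarioError(
            f"gamma={gamma} <= xmin={xmin}: slope would be non-positive")
    beta1 = (clamped_logit(theta) - clamped_logit(rho0)) / (gamma - xmin)
    beta0 = clamped_logit(rho0) - beta1 * xmin
    return float(beta0), float(beta1)


@dataclass(frozen=True)
class LogisticScenario:
    """A true two-parameter logistic dose–toxicity curve.

    Attributes
    ----------
    beta0, beta1:
        Intercept and slope (per mg/m²) of the logistic model; ``beta1 > 0``.
    theta:
        Target toxicity level defining the MTD.
    xmin:
        Lowest dose of the trial range (anchors ρ0).
    """

    beta0: float
    beta1: float
    theta: float = 1.0 / 3.0
    xmin: float = 140.0
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.beta1 > 0:
            raise DegenerateScenarioError("beta1 must be positive")
        if not 0.0 < self.theta < 1.0:
            raise DegenerateScenarioError("theta must lie in (0, 1)")

    @classmethod
    def from_mtd(cls, gamma: float, rho0: float, theta: float = 1.0 / 3.0,
                 xmin: float = 140.0, id: str | None = None) -> "LogisticScenario":
        b0, b1 = solve_logistic_from_mtd(gamma, rho0, theta, xmin)
        return cls(b0, b1, theta, xmin, id=id)

    @property
    def gamma(self) -> float:
        """Maximum tolerated dose: π(γ) = θ."""
        return (clamped_logit(self.theta) - self.beta0) / self.beta1

    @property
    def rho0(self) -> float:
        """DLT probability at the lowest dose xmin."""
        return float(expit(self.beta0 + self.beta1 * self.xmin))

    def prob(self, x) -> np.ndarray | float:
        """True DLT probability at dose ``x`` (vectorized)."""
        out = expit(self.beta0 + self.beta1 * np.asarray(x, dtype=float))
        return float(out) if out.ndim == 0 else out

    def true_mtd(self, space: DoseSpace, theta: float | None = None) -> float:
        """The scenario's MTD within a dose space: γ itself for continuous
        spaces, or the level whose DLT probability is closest to θ."""
        if space.kind == "continuous":
            return float(np.clip(self.gamma, space.xmin, space.xmax))
        probs = self.prob(np.asarray(space.levels))
        return float(space.levels[int(np.argmin(np.abs(probs - self.theta)))])


def dlt_probability(scenario: LogisticScenario, x) -> np.ndarray | float:
    """π(x; β0, β1) under a logistic scenario."""
    return scenario.prob(x)


def make_discrete_scenario(scenario: LogisticScenario,
                           levels: Sequence[float]) -> np.ndarray:
    """Evaluate a logistic scenario on an ordered set of discrete levels."""
    return scenario.prob(np.asarray(levels, dtype=float))


@dataclass(frozen=True)
class AltScenario:
    """Power or hyperbolic-tangent data-generating dose–toxicity curve.

    Both operate on the standardised dose x* = (x − xmin)/(xmax − xmin):

        power: π(x*) = (x*)^{exp(β)}
        tanh:  π(x*) = ((tanh(x*) + 1)/2)^{exp(β)}

    Used only to generate outcomes for model-misspecification studies.
    """

    model: str
    beta: float
    xmin: float = 140.0
    xmax: float = 425.0
    id: str | None = None

    def __post_init__(self) -> None:
        if self.model not in ("power", "tanh"):
            raise ValueError(f"unknown alternative model {self.model!r}")
        if not self.xmin < self.xmax:
            raise ValueError("xmin must be below xmax")

    def prob(self, x) -> np.ndarray | float:
        xs = (np.asarray(x, dtype=float) - self.xmin) / (self.xmax - self.xmin)
        xs = np.clip(xs, 0.0, 1.0)
        if self.model == "power":
            base = xs
        else:
            base = (np.tanh(xs) + 1.0) / 2.0
        out = base ** np.exp(self.beta)
        return float(out) if out.ndim == 0 else out

    def true_mtd(self, space: DoseSpace, theta: float = 1.0 / 3.0) -> float:
        """Dose with DLT probability θ (root-found for continuous spaces;
        nearest-probability level for discrete spaces)."""
        from scipy.optimize import brentq

        if space.kind == "discrete":
            probs = self.prob(np.asarray(space.levels))
            return float(space.levels[int(np.argmin(np.abs(probs - theta)))])
        return float(brentq(lambda x: self.prob(x) - theta,
                            self.xmin + 1e-9, self.xmax))


class CalibrationError(ValueError):
    """Raised when an alternative model cannot attain θ at the requested MTD."""


def calibrate_alt_model(model: str, mtd: float, theta: float,
                        space: DoseSpace) -> AltScenario:
    """Choose β so the power/tanh model has DLT probability θ at ``mtd``.

    Solving base^{exp(β)} = θ for the standardised base at the MTD gives
    exp(β) = ln θ / ln base, which requires the MTD to lie strictly inside
    the dose range (base in (0, 1)).
    """
    if not (space.xmin < mtd < space.xmax):
        raise CalibrationError("MTD must lie strictly inside (xmin, xmax)")
    xs = (mtd - space.xmin) / (space.xmax - space.xmin)
    base = xs if model == "power" else (np.tanh(xs) + 1.0) / 2.0
    if not 0.0 < base < 1.0:
        raise CalibrationError(f"standardised base {base} outside (0, 1)")
    exp_beta = np.log(theta) / np.log(base)
    if exp_beta <= 0:
        raise CalibrationError("calibration requires theta in (0, 1)")
    return AltScenario(model=model, beta=float(np.log(exp_beta)),
                       xmin=space.xmin, xmax=space.xmax,
                       id=f"{model}_mtd{mtd:g}")


def alt_dlt_probability(alt: AltScenario, x) -> np.ndarray | float:
    """DLT probability under a power/tanh scenario (nondecreasing in x)."""
    return alt.prob(x)


# The ten (γ, ρ0) study scenarios spanning steep, shallow and plateauing
# curves, with θ = 1/3 and xmin = 140 mg/m².  Two rows use ρ0 = 0.001.
STUDY_PARAMS: tuple[tuple[str, float, float], ...] = (
    ("1", 165.0, 0.25),
    ("2", 175.0, 0.30),
    ("3", 200.0, 0.03),
    ("4", 250.0, 0.05),
    ("5", 300.0, 0.001),
    ("6", 300.0, 0.02),
    ("7", 350.0, 0.01),
    ("8", 350.0, 0.05),
    ("9", 400.0, 0.001),
    ("10", 400.0, 0.03),
)


def study_scenarios(theta: float = 1.0 / 3.0,
                    xmin: float = 140.0) -> dict[str, LogisticScenario]:
    """The ten logistic study scenarios, keyed by scenario id."""
    return {sid: LogisticScenario.from_mtd(g, r, theta, xmin, id=sid)
            for sid, g, r in STUDY_PARAMS}


def scenario_table(scenarios: Iterable[LogisticScenario] | None = None,
                   levels: Sequence[float] | None = None,
                   xmax: float = 425.0) -> pd.DataFrame:
    """Tabulate scenarios: (γ, ρ0, β0, β1, P(DLT) at xmax and at each level).

    Parameters default to the ten study scenarios on the standard discrete
    levels.  Probabilities are exact (unrounded); round for display.
    """
    if scenarios is None:
        scenarios = study_scenarios().values()
    if levels is None:
        levels = DoseSpace.discrete().levels
    rows = []
    for sc in scenarios:
        row = {
            "scenario": sc.id,
            "gamma": sc.gamma,
            "rho0": sc.rho0,
            "beta0": sc.beta0,
            "beta1": sc.beta1,
            "p_dlt_xmax": sc.prob(xmax),
        }
        for j, d in enumerate(levels, start=1):
            row[f"p_dlt_d{j}"] = sc.prob(d)
        rows.append(row)
    return pd.DataFrame(rows)
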