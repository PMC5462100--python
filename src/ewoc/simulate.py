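"""Batch simulation and operating-characteristic metrics.

For each (dose–toxicity scenario, design) pair this module simulates many
independent trials and reduces them to the operating characteristics used
to compare dose-escalation designs:

* mean bias and RMSE of the MTD recommendations,
      bias = mean(γ̄_k − γ),   RMSE = sqrt(mean((γ̄_k − γ)²));
* an accuracy index over the J candidate MTD labels,
      A = 1 − J · Σ_j (π(d_j) − θ)² p_j / Σ_j (π(d_j) − θ)²,
  where p_j is the fraction of trials recommending label j — A = 1 when
  every recommendation has true toxicity θ, A = 0 for a uniform
  recommendation distribution;
* experimentation: the fraction of dosed patients whose dose has true DLT
  probability in each band (default bands make [0.30, 0.35) available);
* mean DLTs per trial and the coherence-violation rate per α-increase
  opportunity, with its binomial standard error.

Recommendations on continuous dose ranges are mapped to toxicity-probability
bands before the accuracy index is applied (band midpoints stand in for
π(d_j)); discrete recommendations use the levels directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose import DoseSpace
from .feasibility import (EATSchedule, FeasibilitySchedule, FixedSchedule,
                          HybridSchedule, TDFBSchedule, TRSchedule)
from .posterior import GridPosterior, PriorSpec
from .trial import TrialResult, run_trial

__all__ = [
    "DEFAULT_BAND_EDGES",
    "EstimatorMetrics",
    "SimulationSummary",
    "bias_rmse",
    "accuracy_index",
    "experimentation_bands",
    "violation_rate",
    "default_designs",
    "simulate_batch",
    "summaries_to_long",
    "violation_table",
]

#: Default toxicity-probability band edges; half-open bands except the last.
DEFAULT_BAND_EDGES = (0.0, 0.20, 0.25, 0.30, 0.35, 0.40, 1.0)

ESTIMATORS = ("median", "next_dose")


def bias_rmse(recommendations: Sequence[float],
              true_mtd: float) -> tuple[float, float]:
    """Mean bias and RMSE of MTD recommendations around the true MTD."""
    recs = np.asarray(recommendations, dtype=float)
    if recs.size == 0:
        raise ValueError("no recommendations to summarise")
    diff = recs - true_mtd
    return float(diff.mean()), float(np.sqrt(np.mean(diff ** 2)))


def accuracy_index(dlt_probs: Sequence[float], theta: float,
                   rec_freq: Sequence[float]) -> float:
    """Accuracy A of a recommendation distribution over dose labels."""
    p = np.asarray(dlt_probs, dtype=float)
    f = np.asarray(rec_freq, dtype=float)
    if p.shape != f.shape or p.size < 2:
        raise ValueError("need matching lists of at least two dose labels")
    if not math.isclose(float(f.sum()), 1.0, abs_tol=1e-8):
        raise ValueError("recommendation frequencies must sum to 1")
    sq = (p - theta) ** 2
    denom = sq.sum()
    if denom == 0:
        raise ValueError("accuracy undefined: every label sits at theta")
    return float(1.0 - p.size * (sq * f).sum() / denom)


def _band_labels(edges: Sequence[float]) -> list[str]:
    lab = [f"[{a:.2f},{b:.2f})" for a, b in zip(edges[:-2], edges[1:-1])]
    lab.append(f"[{edges[-2]:.2f},{edges[-1]:.2f}]")
    return lab


def _band_fractions(probs: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    counts, _ = np.histogram(probs, bins=np.asarray(edges, dtype=float))
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def experimentation_bands(results: Sequence[TrialResult], scenario,
                          band_edges: Sequence[float] = DEFAULT_BAND_EDGES,
                          ) -> dict[str, float]:
    """Fraction of all dosed patients per true-DLT-probability band."""
    doses = np.concatenate([r.doses for r in results]) if results else np.array([])
    probs = np.asarray(scenario.prob(doses), dtype=float)
    frac = _band_fractions(probs, band_edges)
    return dict(zip(_band_labels(band_edges), frac.tolist()))


def violation_rate(results: Sequence[TrialResult],
                   opportunities_per_trial: int) -> tuple[float, float]:
    """Coherence-violation percentage per α-increase opportunity, with its
    binomial standard error (both in percent)."""
    if opportunities_per_trial < 1:
        raise ValueError("need at least one opportunity per trial")
    n_opp = len(results) * opportunities_per_trial
    if n_opp == 0:
        return 0.0, 0.0
    total = sum(len(r.violations) for r in results)
    p_hat = total / n_opp
    se = math.sqrt(p_hat * (1.0 - p_hat) / n_opp)
    return 100.0 * p_hat, 100.0 * se


@dataclass(frozen=True)
class EstimatorMetrics:
    """MTD-recommendation metrics; ``None`` when every trial stopped early."""

    mean_bias: float | None
    rmse: float | None
    accuracy: float | None
    recommendation: dict[str, float]


@dataclass(frozen=True)
class SimulationSummary:
    """Operating characteristics of one (scenario, design) cell."""

    scenario_id: str
    design_id: str
    trials: int
    completed: int
    stopped_early: int
    experimentation: dict[str, float]
    by_estimator: dict[str, EstimatorMetrics]
    mean_dlts: float | None
    violation_pct: float
    violation_se: float
    mean_violation_magnitude: float | None  # None when no violations occurred
    opportunities_per_trial: int | None


def default_designs(N: int = 40, theta: float = 1.0 / 3.0,
                    ) -> dict[str, FeasibilitySchedule]:
    """The seven study designs: fixed-α overdose control, the stepwise TR
    ramp, the Hybrid linear ramp and the toxicity-dependent bound (each at
    αmin 0.10 and 0.25), and escalation in the absence of toxicity."""
    return {
        "ewoc": FixedSchedule(alpha_fixed=0.25),
        "tr": TRSchedule(),
        "hybrid_a10": HybridSchedule(alpha_min=0.10, N=N),
        "hybrid_a25": HybridSchedule(alpha_min=0.25, N=N),
        "eat": EATSchedule(alpha_min=0.10),
        "tdfb_a10": TDFBSchedule.with_auto_S(0.10, N, theta),
        "tdfb_a25": TDFBSchedule.with_auto_S(0.25, N, theta),
    }


def _summarise(scenario_id: str, design_id: str, results: list[TrialResult],
               scenario, schedule: FeasibilitySchedule, space: DoseSpace,
               theta: float, band_edges: Sequence[float]) -> SimulationSummary:
    completed = [r for r in results if not r.stopped_early]
    stopped = len(results) - len(completed)
    true_mtd = scenario.true_mtd(space, theta)

    by_est: dict[str, EstimatorMetrics] = {}
    for est in ESTIMATORS:
        recs = np.array([r.mtd_median if est == "median" else r.mtd_next_dose
                         for r in completed], dtype=float)
        if recs.size == 0:
            by_est[est] = EstimatorMetrics(None, None, None, {})
            continue
        bias, rmse = bias_rmse(recs, true_mtd)
        if space.kind == "discrete":
            levels = np.asarray(space.levels)
            freq = np.array([(recs == l).mean() for l in levels])
            probs = np.asarray(scenario.prob(levels), dtype=float)
            labels = [f"{l:g}" for l in levels]
        else:
            rec_probs = np.asarray(scenario.prob(recs), dtype=float)
            freq = _band_fractions(rec_probs, band_edges)
            edges = np.asarray(band_edges)
            probs = 0.5 * (edges[:-1] + edges[1:])  # band midpoints
            labels = _band_labels(band_edges)
        by_est[est] = EstimatorMetrics(
            bias, rmse, accuracy_index(probs, theta, freq),
            dict(zip(labels, freq.tolist())))

    opp = schedule.ramp_opportunities
    if opp is None:
        pct, se = violation_rate(results, 1)  # coherent designs: report 0/0
    else:
        pct, se = violation_rate(results, opp)
    mags = [v.magnitude for r in results for v in r.violations]
    mean_mag = float(np.mean(mags)) if mags else None
    mean_dlts = (float(np.mean([r.n_dlts for r in completed]))
                 if completed else None)

    return SimulationSummary(
        scenario_id=scenario_id, design_id=design_id, trials=len(results),
        completed=len(completed), stopped_early=stopped,
        experimentation=experimentation_bands(results, scenario, band_edges),
        by_estimator=by_est, mean_dlts=mean_dlts, violation_pct=pct,
        violation_se=se, mean_violation_magnitude=mean_mag,
        opportunities_per_trial=opp)


def simulate_batch(scenarios: Mapping[str, object],
                   designs: Mapping[str, FeasibilitySchedule],
                   trials: int, N: int, base_seed: int,
                   space: DoseSpace | None = None,
                   prior: PriorSpec | None = None,
                   theta: float = 1.0 / 3.0, resolution: int = 201,
                   band_edges: Sequence[float] = DEFAULT_BAND_EDGES,
                   ) -> list[SimulationSummary]:
    """Simulate ``trials`` trials per (scenario, design) pair.

    Each trial draws outcomes from a dedicated generator keyed by
    (base_seed, scenario index, design index, trial index), so batches are
    reproducible and order-independent.  One quadrature engine is shared
    across the whole batch.
    """
    if trials < 1:
        raise ValueError("need at least one trial")
    if space is None:
        space = DoseSpace.continuous()
    if prior is None:
        prior = PriorSpec.bivariate_normal()
    engine = GridPosterior(prior, space, theta=theta, resolution=resolution)

    summaries = []
    for si, (sid, scenario) in enumerate(scenarios.items()):
        for di, (did, schedule) in enumerate(designs.items()):
            results = []
            for t in range(trials):
                rng = np.random.default_rng([base_seed, si, di, t])
                results.append(run_trial(scenario, schedule, prior, space,
                                         N, theta=theta, engine=engine,
                                         rng=rng))
            summaries.append(_summarise(sid, did, results, scenario,
                                        schedule, space, theta, band_edges))
    return summaries


def summaries_to_long(summaries: Sequence[SimulationSummary]) -> pd.DataFrame:
    """Long-format (scenario, design, metric, value) table of a batch."""
    rows = []

    def add(s, metric, value):
        rows.append({"scenario": s.scenario_id, "design": s.design_id,
                     "metric": metric, "value": value})

    for s in summaries:
        add(s, "trials", s.trials)
        add(s, "completed", s.completed)
        add(s, "stopped_early", s.stopped_early)
        add(s, "mean_dlts", s.mean_dlts)
        add(s, "violation_pct", s.violation_pct)
        add(s, "violation_se", s.violation_se)
        add(s, "mean_violation_magnitude", s.mean_violation_magnitude)
        for est, m in s.by_estimator.items():
            add(s, f"mean_bias_{est}", m.mean_bias)
            add(s, f"rmse_{est}", m.rmse)
            add(s, f"accuracy_{est}", m.accuracy)
            for label, frac in m.recommendation.items():
                add(s, f"recommendation_{est} {label}", frac)
        for label, frac in s.experimentation.items():
            add(s, f"experimentation {label}", frac)
    return pd.DataFrame(rows)


def violation_table(summaries: Sequence[SimulationSummary]) -> pd.DataFrame:
    """Wide coherence-violation table (scenario × design: %, SE) for the
    designs that do not guarantee coherence."""
    rows = [{"scenario": s.scenario_id, "design": s.design_id,
             "violation_pct": s.violation_pct, "violation_se": s.violation_se}
            for s in summaries if s.opportunities_per_trial is not None]
    if not rows:
        return pd.DataFrame(columns=["scenario", "design", "violation_pct",
                                     "violation_se"])
    return (pd.DataFrame(rows)
            .pivot(index="scenario", columns="design",
                   values=["violation_pct", "violation_se"]))
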