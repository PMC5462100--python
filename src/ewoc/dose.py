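"""Dose spaces for phase I dose-finding trials.

A trial either titrates over a continuous dose interval (with doses rounded
to the nearest integer mg/m²) or selects from a small ordered set of discrete
dose levels.  The defaults reproduce the 5-FU combination trial setting:
a continuous range of [140, 425] mg/m² and six discrete levels
{150, 200, 250, 300, 350, 400} mg/m².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["DoseSpace"]

DEFAULT_XMIN = 140.0
DEFAULT_XMAX = 425.0
DEFAULT_LEVELS = (150.0, 200.0, 250.0, 300.0, 350.0, 400.0)


@dataclass(frozen=True)
class DoseSpace:
    """A continuous dose interval or an ordered discrete dose set.

    Parameters
    ----------
    kind:
        ``"continuous"`` or ``"discrete"``.
    xmin, xmax:
        Bounds of the dose range in mg/m²; ``xmin < xmax``.
    levels:
        Strictly increasing dose levels, all inside ``[xmin, xmax]``
        (discrete spaces only).
    continuous_rounding:
        Round continuous dose selections to the nearest integer mg/m²
        (half-up).  On by default, matching clinical dispensing practice.
    """

    kind: str
    xmin: float = DEFAULT_XMIN
    xmax: float = DEFAULT_XMAX
    levels: tuple[float, ...] | None = None
    continuous_rounding: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "discrete"):
            raise ValueError(f"unknown dose-space kind {self.kind!r}")
        if not self.xmin < self.xmax:
            raise ValueError("xmin must be strictly less than xmax")
        if self.kind == "discrete":
            if not self.levels:
                raise ValueError("discrete dose space requires levels")
            lv = tuple(float(l) for l in self.levels)
            if any(b <= a for a, b in zip(lv, lv[1:])):
                raise ValueError("dose levels must be strictly increasing")
            if lv[0] < self.xmin or lv[-1] > self.xmax:
                raise ValueError("dose levels must lie within [xmin, xmax]")
            object.__setattr__(self, "levels", lv)
        elif self.levels is not None:
            raise ValueError("continuous dose space takes no levels")

    @classmethod
    def continuous(cls, xmin: float = DEFAULT_XMIN, xmax: float = DEFAULT_XMAX,
                   rounding: bool = True) -> "DoseSpace":
        return cls("continuous", xmin, xmax, continuous_rounding=rounding)

    @classmethod
    def discrete(cls, levels: tuple[float, ...] = DEFAULT_LEVELS,
                 xmin: float = DEFAULT_XMIN, xmax: float = DEFAULT_XMAX) -> "DoseSpace":
        return cls("discrete", xmin, xmax, levels=tuple(levels))

    @property
    def lowest(self) -> float:
        """Dose given to the first patient: xmin, or the lowest level."""
        return self.levels[0] if self.kind == "discrete" else self.xmin

    def project(self, dose: float) -> float:
        """Map an unconstrained dose to an administrable one.

        Continuous spaces clip to ``[xmin, xmax]`` and (by default) round
        half-up to the nearest integer.  Discrete spaces return the nearest
        level, breaking equidistant ties toward the lower (safer) dose.
        """
        if self.kind == "discrete":
            best = self.levels[0]
            best_d = abs(dose - best)
            for l in self.levels[1:]:
                d = abs(dose - l)
                if d < best_d:  # strict: ties stay at the lower level
                    best, best_d = l, d
            return best
        x = min(max(dose, self.xmin), self.xmax)
        if self.continuous_rounding:
            x = float(math.floor(x + 0.5))
        return x
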