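"""Simulation-based tuning of the (lambda, gamma) threshold hyperparameters.

The adaptive threshold ``C_n = 1 - lambda (n/N)^gamma`` trades early
stopping against final-analysis stringency.  Calibration runs the trial
engine under the null and alternative planning scenarios on a grid of
``(lambda, gamma)`` pairs with common random numbers, keeps the pairs whose
estimated type I error respects the cap, and returns the admissible pair
with the greatest estimated power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .designs import DesignSpec, make_design
from .engine import operating_characteristics
from .scenarios import HypothesisPair, planning_hypotheses

__all__ = [
    "CalibrationGrid",
    "CalibrationResult",
    "ErrorRates",
    "CalibrationError",
    "estimate_error_rates",
    "calibrate_lambda_gamma",
]


class CalibrationError(RuntimeError):
    """No grid point satisfied the type I error constraint."""


@dataclass(frozen=True)
class CalibrationGrid:
    """Grid of candidate threshold hyperparameters plus Monte Carlo settings.

    The default resolution is 0.005 over ``lambda in [0.5, 1]`` and
    ``gamma in [0.5, 2]``; the full default grid is large, so routine use
    passes a coarser one.
    """

    lambda_values: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.5, 1.0001, 0.005), 3)))
    gamma_values: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.5, 2.0001, 0.005), 3)))
    reps: int = 2_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.lambda_values or not self.gamma_values:
            raise ValueError("grids must be non-empty")
        if any(not 0 < l <= 1 for l in self.lambda_values):
            raise ValueError("lambda values must lie in (0, 1]")
        if any(g <= 0 for g in self.gamma_values):
            raise ValueError("gamma values must be positive")


@dataclass(frozen=True)
class ErrorRates:
    """Estimated (type I error, power) with Monte Carlo standard errors."""

    type1: float
    type1_se: float
    power: float
    power_se: float
    reps: int


@dataclass(frozen=True)
class CalibrationResult:
    lam: float
    gam: float
    rates: ErrorRates
    table: pd.DataFrame


def estimate_error_rates(design: DesignSpec,
                         hypotheses: HypothesisPair | None = None,
                         reps: int = 2_000,
                         seed: int | None = None,
                         **oc_kwargs) -> ErrorRates:
    """Positive-conclusion frequencies under the null and the alternative.

    Uses the same root seed for both scenarios (common random numbers), so
    paired comparisons between hyperparameter settings are low-variance.
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates for stable estimates")
    hypotheses = hypotheses or planning_hypotheses()
    oc0 = operating_characteristics(design, hypotheses.h0, reps=reps,
                                    seed=seed, **oc_kwargs)
    oc1 = operating_characteristics(design, hypotheses.h1, reps=reps,
                                    seed=seed, **oc_kwargs)
    return ErrorRates(type1=oc0.prob_positive, type1_se=oc0.se_positive,
                      power=oc1.prob_positive, power_se=oc1.se_positive,
                      reps=reps)


def calibrate_lambda_gamma(kind: str,
                           grid: CalibrationGrid,
                           hypotheses: HypothesisPair | None = None,
                           alpha_max: float = 0.05,
                           **design_kwargs) -> CalibrationResult:
    """Grid search for the threshold hyperparameters of a design kind.

    Among grid points with estimated type I error at most ``alpha_max``,
    returns the point with the greatest estimated power; ties break toward
    larger lambda, then larger gamma.  ``alpha_max`` defaults to 0.05 for a
    complete design (use 0.10 when calibrating a stand-alone futility rule).

    Raises
    ------
    CalibrationError
        If no grid point is admissible; the message reports the frontier
        (smallest estimated type I error and its power).
    """
    hypotheses = hypotheses or planning_hypotheses()
    rows = []
    best = None
    for lam in grid.lambda_values:
        for gam in grid.gamma_values:
            design = make_design(kind, lam=lam, gamma=gam,
                                 hypotheses=hypotheses, **design_kwargs)
            rates = estimate_error_rates(design, hypotheses,
                                         reps=grid.reps, seed=grid.seed)
            admissible = rates.type1 <= alpha_max
            rows.append({"lambda": lam, "gamma": gam,
                         "type1": rates.type1, "type1_se": rates.type1_se,
                         "power": rates.power, "power_se": rates.power_se,
                         "admissible": admissible})
            if admissible:
                key = (rates.power, lam, gam)
                if best is None or key > best[0]:
                    best = (key, lam, gam, rates)
    table = pd.DataFrame(rows)
    if best is None:
        frontier = table.sort_values("type1").iloc[0]
        raise CalibrationError(
            f"no grid point has type I error <= {alpha_max}; frontier: "
            f"lambda={frontier['lambda']}, gamma={frontier['gamma']} with "
            f"type1={frontier['type1']:.4f}, power={frontier['power']:.4f}")
    _, lam, gam, rates = best
    return CalibrationResult(lam=lam, gam=gam, rates=rates, table=table)
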