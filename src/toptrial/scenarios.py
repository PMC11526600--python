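"""True-outcome scenarios for correlated binary efficacy/toxicity endpoints.

A scenario is a pair of Bernoulli marginals -- the true objective-response
probability ``p_eff`` (ascertained within a 180-day window) and the true
unacceptable-toxicity probability ``p_tox`` (42-day window) -- together with
a Pearson correlation ``R`` between the two indicators.  Because the
endpoints are binary, ``R`` is only feasible inside a range
``[R_min, R_max]`` determined by the marginals (Frechet bounds on the joint
cell ``Pr(Eff and Tox)``).  A scenario expands to the four multinomial cell
probabilities that drive patient-level simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeScenario",
    "JointCellProbs",
    "HypothesisPair",
    "correlation_bounds",
    "joint_cell_probs",
    "correlation_grid",
    "r_positive_third",
    "SCENARIO_TABLE",
    "reference_scenarios",
    "scenario_table_frame",
    "planning_hypotheses",
]

_EPS = 1e-12


def _check_probability(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0 or not math.isfinite(value):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")
    return value


def correlation_bounds(p_eff: float, p_tox: float) -> tuple[float, float]:
    """Feasible Pearson-correlation range for two Bernoulli indicators.

    The extremes correspond to the Frechet bounds on the joint probability
    ``pi_11 = Pr(Eff and Tox)``: the minimum ``max(0, p_eff + p_tox - 1)``
    and the maximum ``min(p_eff, p_tox)``.  Each extreme joint probability
    converts to a correlation through

        R = (pi_11 - p_eff p_tox) / sqrt(p_eff(1-p_eff) p_tox(1-p_tox)).

    Both marginals must be strictly inside (0, 1); a degenerate marginal
    leaves the correlation undefined.

    Returns
    -------
    (r_min, r_max) : tuple of float
        Full-precision bounds; ``r_min < 0 <= r_max <= 1``.
    """
    p_eff = _check_probability(p_eff, "p_eff")
    p_tox = _check_probability(p_tox, "p_tox")
    if p_eff in (0.0, 1.0) or p_tox in (0.0, 1.0):
        raise ValueError(
            "correlation is undefined for a degenerate marginal "
            f"(p_eff={p_eff}, p_tox={p_tox})"
        )
    denom = math.sqrt(p_eff * (1.0 - p_eff) * p_tox * (1.0 - p_tox))
    pi_lo = max(0.0, p_eff + p_tox - 1.0)
    pi_hi = min(p_eff, p_tox)
    r_min = (pi_lo - p_eff * p_tox) / denom
    r_max = (pi_hi - p_eff * p_tox) / denom
    return r_min, r_max


def r_positive_third(p_eff: float, p_tox: float) -> float:
    """The named positive correlation preset ``R_max / 3``.

    Computed from the exact (unrounded) upper bound; rounding is applied
    only at display time.
    """
    return correlation_bounds(p_eff, p_tox)[1] / 3.0


def correlation_grid(p_eff: float, p_tox: float, k: int = 6) -> np.ndarray:
    """Evenly spaced grid of ``k`` feasible correlations from R_min to R_max."""
    if k < 2:
        raise ValueError("grid needs at least 2 points")
    r_min, r_max = correlation_bounds(p_eff, p_tox)
    return np.linspace(r_min, r_max, k)


@dataclass(frozen=True)
class OutcomeScenario:
    """True marginal efficacy/toxicity probabilities plus their correlation.

    Parameters
    ----------
    p_eff, p_tox : float
        True response and unacceptable-toxicity probabilities.
    r : float
        Pearson correlation between the two indicators; must lie within the
        feasible range implied by the marginals.  Degenerate marginals
        (probability 0 or 1) force ``r = 0``.
    label : str
        Optional display name.
    """

    p_eff: float
    p_tox: float
    r: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        _check_probability(self.p_eff, "p_eff")
        _check_probability(self.p_tox, "p_tox")
        if self.p_eff in (0.0, 1.0) or self.p_tox in (0.0, 1.0):
            if self.r != 0.0:
                raise ValueError("degenerate marginals force r = 0")
            return
        r_min, r_max = correlation_bounds(self.p_eff, self.p_tox)
        if not (r_min - _EPS <= self.r <= r_max + _EPS):
            raise ValueError(
                f"r={self.r} outside feasible range [{r_min:.6f}, {r_max:.6f}] "
                f"for marginals ({self.p_eff}, {self.p_tox})"
            )

    def feasible_bounds(self) -> tuple[float, float]:
        return correlation_bounds(self.p_eff, self.p_tox)

    def cells(self) -> "JointCellProbs":
        return joint_cell_probs(self)

    def to_dict(self) -> dict:
        return {
            "p_eff": self.p_eff,
            "p_tox": self.p_tox,
            "r": self.r,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "OutcomeScenario":
        """Build a scenario from a mapping; ``r`` may be a named preset.

        Recognised presets: ``"pos1"`` (= R_max/3), ``"r_min"``, ``"r_max"``,
        ``"independent"`` (= 0).
        """
        p_eff = data["p_eff"]
        p_tox = data["p_tox"]
        r = data.get("r", 0.0)
        if isinstance(r, str):
            key = r.lower()
            if key in ("pos1", "r_pos1", "r_max/3"):
                r = r_positive_third(p_eff, p_tox)
            elif key == "r_min":
                r = correlation_bounds(p_eff, p_tox)[0]
            elif key == "r_max":
                r = correlation_bounds(p_eff, p_tox)[1]
            elif key in ("independent", "zero"):
                r = 0.0
            else:
                raise ValueError(f"unknown correlation preset {r!r}")
        return cls(p_eff=float(p_eff), p_tox=float(p_tox), r=float(r),
                   label=str(data.get("label", "")))


@dataclass(frozen=True)
class JointCellProbs:
    """Four-cell joint distribution of (efficacy, toxicity) indicators.

    Cells are ordered ``(Eff&Tox, Eff&~Tox, ~Eff&Tox, ~Eff&~Tox)``.
    """

    pi_11: float
    pi_10: float
    pi_01: float
    pi_00: float

    def __post_init__(self) -> None:
        cells = self.as_array()
        if np.any(cells < -_EPS) or np.any(cells > 1.0 + _EPS):
            raise ValueError(f"cells outside [0, 1]: {cells}")
        if abs(cells.sum() - 1.0) > 1e-9:
            raise ValueError(f"cells must sum to 1, got {cells.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pi_11, self.pi_10, self.pi_01, self.pi_00])

    @property
    def p_eff(self) -> float:
        return self.pi_11 + self.pi_10

    @property
    def p_tox(self) -> float:
        return self.pi_11 + self.pi_01

    @property
    def r(self) -> float:
        """Pearson correlation recovered from the cells."""
        pe, pt = self.p_eff, self.p_tox
        denom = math.sqrt(pe * (1.0 - pe) * pt * (1.0 - pt))
        if denom == 0.0:
            return 0.0
        return (self.pi_11 - pe * pt) / denom


def joint_cell_probs(scenario: OutcomeScenario) -> JointCellProbs:
    """Expand ``(p_eff, p_tox, R)`` to the four multinomial cells.

    Inverts the Bernoulli-correlation relation:
    ``pi_11 = p_eff p_tox + R sqrt(p_eff(1-p_eff) p_tox(1-p_tox))``; the
    remaining cells follow by marginal subtraction.
    """
    pe, pt, r = scenario.p_eff, scenario.p_tox, scenario.r
    denom = math.sqrt(pe * (1.0 - pe) * pt * (1.0 - pt))
    pi_11 = pe * pt + r * denom
    pi_10 = pe - pi_11
    pi_01 = pt - pi_11
    pi_00 = 1.0 - pi_11 - pi_10 - pi_01
    cells = np.array([pi_11, pi_10, pi_01, pi_00])
    if np.any(cells < -1e-10):
        raise ValueError(
            f"correlation {r} leaves the unit simplex for marginals ({pe}, {pt})"
        )
    cells = np.clip(cells, 0.0, 1.0)
    return JointCellProbs(*cells)


#: The ten (label, p_eff, p_tox) simulation scenarios of the comparative study.
SCENARIO_TABLE: tuple[tuple[str, float, float], ...] = (
    ("H0", 0.15, 0.30),
    ("H1", 0.30, 0.20),
    ("Intermediate", 0.20, 0.25),
    ("Intermediate (2)", 0.25, 0.25),
    ("Inefficacious", 0.15, 0.20),
    ("Inefficacious (2)", 0.10, 0.15),
    ("Intermediate efficacy", 0.20, 0.20),
    ("Intermediate efficacy (2)", 0.20, 0.30),
    ("Toxic", 0.30, 0.30),
    ("Toxic (2)", 0.40, 0.35),
)


def reference_scenarios(r: float | str = "pos1") -> list[OutcomeScenario]:
    """The ten study scenarios, with the correlation supplied by the caller.

    ``r`` may be a number (applied to every scenario, must be feasible for
    each) or a named preset as accepted by :meth:`OutcomeScenario.from_dict`
    (preset values are recomputed per scenario from its own marginals).
    """
    out = []
    for i, (label, pe, pt) in enumerate(SCENARIO_TABLE, start=1):
        out.append(OutcomeScenario.from_dict(
            {"p_eff": pe, "p_tox": pt, "r": r, "label": f"{i}: {label}"}
        ))
    return out


def scenario_table_frame() -> pd.DataFrame:
    """Scenario table with feasible correlation bounds, one row per scenario."""
    rows = []
    for i, (label, pe, pt) in enumerate(SCENARIO_TABLE, start=1):
        r_min, r_max = correlation_bounds(pe, pt)
        rows.append(
            {"scenario": i, "description": label, "p_eff": pe, "p_tox": pt,
             "r_min": r_min, "r_max": r_max}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HypothesisPair:
    """Null and alternative planning scenarios used for design calibration."""

    h0: OutcomeScenario
    h1: OutcomeScenario

    def __post_init__(self) -> None:
        if not self.h1.p_eff > self.h0.p_eff:
            raise ValueError("H1 efficacy must exceed H0 efficacy")


def planning_hypotheses() -> HypothesisPair:
    """The working hypotheses of the motivating trial.

    H0: 15% response, 30% toxicity, R = 0.21 (a slight positive correlation,
    one third of the feasible maximum rounded to 2 decimals); H1: 30%
    response, 20% toxicity, R = 0.26.
    """
    return HypothesisPair(
        h0=OutcomeScenario(0.15, 0.30, 0.21, label="H0"),
        h1=OutcomeScenario(0.30, 0.20, 0.26, label="H1"),
    )
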