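"""Conjugate posterior machinery for sequential monitoring.

Beta-binomial and Dirichlet-multinomial updates, posterior tail
probabilities, and the fractional follow-up weighting that lets interim
analyses use pending patients: a patient whose observation window is
incomplete and whose event has not occurred contributes a fractional
"evaluated" count ``w = follow-up / window`` (the expected information
under a uniform event-time assumption).  Fractional pseudo-counts plug
directly into the conjugate updates, which is the closed-form approximated
posterior the time-to-event monitoring rule relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import betainc

from .cohort import CohortStream, ObservationWindows, PatientRecord
from .scenarios import OutcomeScenario, joint_cell_probs

__all__ = [
    "BetaParams",
    "DirichletParams",
    "EffectiveCounts",
    "beta_tail",
    "beta_lower",
    "effective_counts",
    "dirichlet_marginal_tails",
]


@dataclass(frozen=True)
class BetaParams:
    """Beta(a, b) pseudo-counts; ``a`` successes, ``b`` failures."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and np.isfinite(self.a)
                and np.isfinite(self.b)):
            raise ValueError("Beta parameters must be finite and positive")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def updated(self, x: float, m: float) -> "BetaParams":
        """Posterior after ``x`` events among ``m`` (possibly weighted) trials."""
        return BetaParams(self.a + x, self.b + m - x)


def _check_counts(x: float, m: float) -> None:
    if not (0 <= x <= m + 1e-9):
        raise ValueError(f"need 0 <= x <= m, got x={x}, m={m}")


def beta_lower(prior: BetaParams, x: float, m: float, cutoff: float) -> float:
    """``Pr(p <= cutoff | Beta(a + x, b + m - x))`` -- the futility tail."""
    _check_counts(x, m)
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    return float(betainc(prior.a + x, prior.b + max(m - x, 0.0), cutoff))


def beta_tail(prior: BetaParams, x: float, m: float, cutoff: float) -> float:
    """``Pr(p > cutoff | Beta(a + x, b + m - x))`` -- the toxicity tail.

    Weighted (non-integer) ``x`` and ``m`` are allowed; conjugacy holds for
    fractional pseudo-counts.
    """
    return 1.0 - beta_lower(prior, x, m, cutoff)


@dataclass(frozen=True)
class DirichletParams:
    """Dirichlet concentration over the four (eff, tox) cells.

    Cell order matches :class:`~toptrial.scenarios.JointCellProbs`:
    ``(Eff&Tox, Eff&~Tox, ~Eff&Tox, ~Eff&~Tox)``.
    """

    alpha: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.alpha) != 4 or any(a <= 0 for a in self.alpha):
            raise ValueError("alpha must be 4 positive values")

    @classmethod
    def from_scenario(cls, scenario: OutcomeScenario,
                      ess: float = 1.0) -> "DirichletParams":
        """Prior matching a scenario's cell probabilities at total mass ``ess``.

        With ``ess = 1`` this is the published convention for the Bayesian
        optimal phase II family: a weakly informative prior centred on the
        null hypothesis cells.
        """
        cells = joint_cell_probs(scenario).as_array()
        alpha = np.maximum(cells * ess, 1e-12)
        return cls(tuple(float(a) for a in alpha))

    def eff_marginal(self) -> BetaParams:
        """Aggregated Beta marginal for the efficacy probability."""
        a = self.alpha
        return BetaParams(a[0] + a[1], a[2] + a[3])

    def tox_marginal(self) -> BetaParams:
        """Aggregated Beta marginal for the toxicity probability."""
        a = self.alpha
        return BetaParams(a[0] + a[2], a[1] + a[3])


@dataclass(frozen=True)
class EffectiveCounts:
    """Data available at an interim analysis, ``D_n``.

    Efficacy counts may be fractional (pending-patient weighting); toxicity
    counts are integers under the binary posterior-probability convention
    (complete windows or observed events only).
    """

    x_eff: float
    m_eff: float
    x_tox: float
    m_tox: float
    n_enrolled: int

    def __post_init__(self) -> None:
        tol = 1e-9
        if not (0 <= self.x_eff <= self.m_eff + tol
                and self.m_eff <= self.n_enrolled + tol):
            raise ValueError("need 0 <= x_eff <= m_eff <= n_enrolled")
        if not (0 <= self.x_tox <= self.m_tox + tol
                and self.m_tox <= self.n_enrolled + tol):
            raise ValueError("need 0 <= x_tox <= m_tox <= n_enrolled")


def _as_arrays(patients) -> tuple[np.ndarray, ...]:
    if isinstance(patients, CohortStream):
        return (patients.arrivals, patients.eff, patients.tox,
                patients.t_eff, patients.t_tox)
    records = list(patients)
    arrival = np.array([p.arrival for p in records], dtype=float)
    eff = np.array([p.eff for p in records], dtype=bool)
    tox = np.array([p.tox for p in records], dtype=bool)
    t_eff = np.array([np.inf if p.t_eff is None else p.t_eff for p in records])
    t_tox = np.array([np.inf if p.t_tox is None else p.t_tox for p in records])
    return arrival, eff, tox, t_eff, t_tox


def weighted_endpoint_counts(arrival: np.ndarray, t_event: np.ndarray,
                             analysis_day: float,
                             window: float) -> tuple[float, float]:
    """Fractionally weighted (events, evaluated) counts for one endpoint.

    Patients with an observed event contribute ``(1, 1)``; patients with a
    complete window and no event contribute ``(0, 1)``; pending patients
    contribute ``(0, w)`` with ``w = follow-up / window``.  ``t_event`` uses
    ``+inf`` for "no event".
    """
    followup = analysis_day - arrival
    if np.any(followup < -1e-9):
        raise ValueError("analysis_day precedes an arrival")
    observed = (arrival + t_event) <= analysis_day
    w = np.clip(followup / window, 0.0, 1.0)
    x = float(np.count_nonzero(observed))
    m = x + float(w[~observed].sum())
    return x, m


def binary_endpoint_counts(arrival: np.ndarray, t_event: np.ndarray,
                           analysis_day: float,
                           window: float) -> tuple[int, int]:
    """Integer (events, evaluated) counts over complete observations only.

    The binary posterior-probability convention evaluates a patient once
    their observation window has elapsed; patients still inside their
    window are excluded entirely.  Counting not-yet-complete patients whose
    event has already occurred -- while their event-free contemporaries
    remain invisible -- would bias the interim event rate upward, so it is
    deliberately not done.
    """
    followup = analysis_day - arrival
    if np.any(followup < -1e-9):
        raise ValueError("analysis_day precedes an arrival")
    complete = followup >= window
    events = complete & ((arrival + t_event) <= analysis_day)
    return int(np.count_nonzero(events)), int(np.count_nonzero(complete))


def effective_counts(patients, analysis_day: float,
                     windows: ObservationWindows,
                     weight_toxicity: bool = False) -> EffectiveCounts:
    """Interim data ``D_n`` for a set of enrolled patients.

    Efficacy uses pending-patient weighting; toxicity uses complete binary
    observations unless ``weight_toxicity`` is set (the joint co-primary
    designs weight toxicity the same way as efficacy).
    """
    arrival, eff, tox, t_eff, t_tox = _as_arrays(patients)
    x_e, m_e = weighted_endpoint_counts(arrival, t_eff, analysis_day,
                                        windows.t_eff)
    if weight_toxicity:
        x_t, m_t = weighted_endpoint_counts(arrival, t_tox, analysis_day,
                                            windows.t_tox)
    else:
        x_t, m_t = binary_endpoint_counts(arrival, t_tox, analysis_day,
                                          windows.t_tox)
    return EffectiveCounts(x_eff=x_e, m_eff=m_e, x_tox=float(x_t),
                           m_tox=float(m_t), n_enrolled=len(arrival))


def dirichlet_marginal_tails(prior: DirichletParams,
                             counts: Sequence[float],
                             phi_eff: float,
                             phi_tox: float) -> tuple[float, float]:
    """Marginal posterior tails of a Dirichlet-multinomial joint model.

    ``counts`` are the four (possibly weighted) cell counts in the order of
    :class:`DirichletParams`.  By the aggregation property the marginal of
    a Dirichlet over a group of cells is Beta, so each tail reduces to a
    Beta tail on the aggregated pseudo-counts.

    Returns ``(Pr(p_eff <= phi_eff | D), Pr(p_tox > phi_tox | D))``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (4,) or np.any(counts < 0):
        raise ValueError("counts must be 4 non-negative values")
    x_eff = counts[0] + counts[1]
    x_tox = counts[0] + counts[2]
    total = float(counts.sum())
    eff_lower = beta_lower(prior.eff_marginal(), x_eff, total, phi_eff)
    tox_upper = beta_tail(prior.tox_marginal(), x_tox, total, phi_tox)
    return eff_lower, tox_upper
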