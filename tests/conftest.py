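"""Shared fixtures: planning scenarios and an exhaustively enumerable toy trial.

The toy trial shrinks the design to 6 patients with near-instant observation
windows and deterministic accrual, so every analysis sees complete data and
a trial's outcome is a pure function of the 4-cell outcome sequence.  The
positive-conclusion probability can then be computed exactly by enumerating
all 4^6 sequences with an independent implementation of the posterior rules
(scipy.stats.beta, explicit loops) and compared against the Monte Carlo
engine.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import beta as beta_dist

import toptrial as tt

TINY = 1e-9  # observation window that closes before the next arrival


@pytest.fixture(scope="session")
def hypotheses() -> tt.HypothesisPair:
    return tt.planning_hypotheses()


@pytest.fixture(scope="session")
def scenario2() -> tt.OutcomeScenario:
    """The alternative-hypothesis scenario at the R_max/3 preset."""
    return tt.OutcomeScenario(0.30, 0.20, tt.r_positive_third(0.30, 0.20),
                              label="2: H1")


def make_toy_design(lam: float = 0.9, gam: float = 1.0) -> tt.DesignSpec:
    """Six-patient futility+toxicity design with complete data at every look."""
    return tt.DesignSpec(
        kind="top_pp", lam=lam, gam=gam,
        schedule=tt.LookSchedule(eff_looks=(3, 6), tox_looks=(2, 4, 6),
                                 n_eff=6, n_tox=6),
        eff_prior=tt.BetaParams(1.0, 1.0),
        tox_prior=tt.BetaParams(1.0, 1.0),
        phi_eff=0.15, phi_tox=0.25, pp_threshold=0.95,
        max_enroll=6, p_met_positive=0.0,
    )


def toy_positive_probability(scenario: tt.OutcomeScenario,
                             lam: float = 0.9, gam: float = 1.0) -> float:
    """Exact positive-conclusion probability of the toy trial.

    Enumerates all 4^6 outcome sequences.  With near-instant windows and a
    6-day accrual grid, at the look fired by patient k's enrollment the
    first k-1 patients are fully observed and patient k contributes nothing
    (zero follow-up), so decisions depend only on the outcome sequence.
    Rules are re-implemented here from their definitions.
    """
    cells = scenario.cells().as_array()
    # cell code: 0 = Eff&Tox, 1 = Eff&~Tox, 2 = ~Eff&Tox, 3 = ~Eff&~Tox
    eff_of = np.array([1, 1, 0, 0])
    tox_of = np.array([1, 0, 1, 0])

    def pp_stops(x: int, m: int) -> bool:
        return beta_dist.sf(0.25, 1 + x, 1 + m - x) > 0.95

    def futility(x: int, m: int, c_n: float) -> bool:
        return beta_dist.cdf(0.15, 1 + x, 1 + m - x) > c_n

    total = 0.0
    for seq in itertools.product(range(4), repeat=6):
        prob = float(np.prod(cells[list(seq)]))
        eff = eff_of[list(seq)]
        tox = tox_of[list(seq)]
        positive = True
        for k in range(1, 7):  # patient k enrolls; complete data = 1..k-1
            x_t = int(tox[:k - 1].sum())
            m_t = k - 1
            if k in (2, 4, 6) and pp_stops(x_t, m_t):
                positive = False
                break
            if k == 3:
                m_e = k - 1
                c_n = 1.0 - lam * (min(m_e, k) / 6.0) ** gam
                if futility(int(eff[:k - 1].sum()), m_e, c_n):
                    positive = False
                    break
        else:
            x_final = int(eff.sum())
            if futility(x_final, 6, 1.0 - lam):
                positive = False
            elif pp_stops(int(tox.sum()), 6):
                positive = False
        total += prob * positive
    return total


def toy_mc_positive_probability(scenario: tt.OutcomeScenario, reps: int,
                                seed: int, lam: float = 0.9,
                                gam: float = 1.0) -> float:
    """Monte Carlo estimate of the same quantity through the trial engine."""
    design = make_toy_design(lam, gam)
    windows = tt.ObservationWindows(t_eff=TINY, t_tox=TINY)
    accrual = tt.AccrualModel(mode="fixed")
    rng = np.random.default_rng(seed)
    positive = 0
    for _ in range(reps):
        cohort = tt.generate_cohort(6, scenario, p_met_positive=0.0,
                                    accrual=accrual, windows=windows, rng=rng)
        res = tt.run_trial(design, cohort)
        positive += res.decision == "positive"
    return positive / reps
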