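"""Single-trial simulation and Monte Carlo operating characteristics.

Chronology of a simulated trial
-------------------------------
Patients enroll continuously (first arrival at day 0).  A look fires the
moment its patient count is reached: efficacy looks count evaluable
(MET-negative) patients, PP toxicity looks count all enrolled patients and
joint-design toxicity looks count evaluable patients.  At a time-to-event
look the analysis day is the enrollment day of the look's index patient and
pending patients enter with fractional weights; at a complete-data look
(binary designs) accrual is suspended and the analysis is deferred until
every enrolled patient's observation windows are complete.  Binding stops
end the trial at the triggering look's analysis day.

A trial that enrolls to its cap performs the final analysis once the last
required observation window closes, on complete data: the futility rule
must not fire (Simon: the responder count must exceed ``r``) and, for
designs with a toxicity rule, the toxicity rule must not fire on the full
complete data.  Only then is the trial positive.  Trial duration runs from
the first enrollment to the decision day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import (AccrualModel, CohortStream, ObservationWindows,
                     generate_cohort)
from .designs import DesignSpec, cn_threshold, pp_stop_counts
from .posteriors import (BetaParams, beta_lower, beta_tail,
                         binary_endpoint_counts, weighted_endpoint_counts)
from .scenarios import OutcomeScenario

__all__ = [
    "TrialResult",
    "OperatingCharacteristics",
    "run_trial",
    "operating_characteristics",
    "scenario_sweep",
]

DECISIONS = ("positive", "stopped_futility", "stopped_toxicity",
             "negative_final")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated trial."""

    decision: str
    n_enrolled: int
    duration: float
    stop_look: int | None = None

    def __post_init__(self) -> None:
        if self.decision not in DECISIONS:
            raise ValueError(f"unknown decision {self.decision!r}")
        if self.decision.startswith("stopped") and self.stop_look is None:
            raise ValueError("early stops must record their look")

    @property
    def early_stop(self) -> bool:
        """True when a binding rule ended the trial before the final look."""
        return self.decision.startswith("stopped")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte Carlo design-level summaries with binomial standard errors."""

    prob_positive: float
    se_positive: float
    prob_early_stop: float
    se_early_stop: float
    mean_n: float
    mean_duration: float
    reps: int
    seed: int | None
    decision_counts: dict


class _DesignState:
    """Per-design precomputation shared across replicates."""

    def __init__(self, design: DesignSpec):
        self.design = design
        sched = design.schedule
        self.eff_interims = frozenset(sched.eff_looks[:-1])
        self.final_eff_n = sched.eff_looks[-1]
        if design.tox_rule == "pp":
            self.tox_interims = frozenset(sched.tox_looks)
            self.pp_stop = pp_stop_counts(design.max_enroll, design.tox_prior,
                                          design.phi_tox, design.pp_threshold)
        elif design.tox_rule == "joint":
            # the look equal to the toxicity cap is the final analysis
            self.tox_interims = frozenset(
                n for n in sched.tox_looks if n < sched.n_tox)
            self.pp_stop = None
        else:
            self.tox_interims = frozenset()
            self.pp_stop = None


def _joint_tox_trigger(design: DesignSpec, state: _DesignState,
                       arrival, tox, t_tox, day: float, look_n: int,
                       windows: ObservationWindows,
                       met_arrival=None, met_tox=None, met_t_tox=None) -> bool:
    """Evaluate the joint-design toxicity rule at one look."""
    if design.weight_toxicity:
        x, m = weighted_endpoint_counts(arrival, t_tox, day, windows.t_tox)
    else:
        x, m = binary_endpoint_counts(arrival, t_tox, day, windows.t_tox)
    prior = design.tox_prior
    if design.informative_tox_prior and met_arrival is not None \
            and len(met_arrival):
        x_pos, n_pos = binary_endpoint_counts(met_arrival, met_t_tox, day,
                                              windows.t_tox)
        prior = prior.updated(x_pos, n_pos)
    n_thr = min(m, look_n) if (design.weight_toxicity
                               and design.cn_on_information) else look_n
    if n_thr <= 0:
        return False
    c_n = cn_threshold(n_thr, design.schedule.n_tox, design.lam, design.gam)
    return beta_tail(prior, x, m, design.phi_tox) > c_n


def run_trial(design: DesignSpec, cohort: CohortStream,
              state: _DesignState | None = None) -> TrialResult:
    """Run one trial of ``design`` on a pre-generated patient stream.

    The cohort must hold at least ``design.max_enroll`` patients; only that
    prefix is used, so a shared 90-patient stream gives common random
    numbers across designs with different caps.
    """
    if len(cohort) < design.max_enroll:
        raise ValueError(
            f"cohort of {len(cohort)} patients is shorter than the design "
            f"maximum {design.max_enroll}")
    state = state or _DesignState(design)
    windows = cohort.windows
    n_max = design.max_enroll

    gaps = cohort.gaps
    mon = np.ones(n_max, dtype=bool) if design.ignore_met \
        else ~cohort.met[:n_max]
    eff = cohort.eff[:n_max]
    tox = cohort.tox[:n_max]
    t_eff = cohort.t_eff[:n_max]
    t_tox = cohort.t_tox[:n_max]

    arr = np.empty(n_max)
    n_mon = 0
    prev_time = 0.0

    for k in range(n_max):
        prev_time = prev_time + gaps[k]
        arr[k] = prev_time
        n_tot = k + 1
        if mon[k]:
            n_mon += 1
        day = arr[k]

        # ---- toxicity look --------------------------------------------
        if design.tox_rule == "pp":
            if n_tot in state.tox_interims:
                # posterior rule on the complete 42-day observations in
                # hand: the trigger count is indexed by the ascertained m,
                # not the look size n
                x_t, m_t = binary_endpoint_counts(arr[:n_tot], t_tox[:n_tot],
                                                  day, windows.t_tox)
                if x_t >= state.pp_stop[m_t]:
                    return TrialResult("stopped_toxicity", n_tot, day,
                                       stop_look=n_tot)
        elif design.tox_rule == "joint":
            if mon[k] and n_mon in state.tox_interims:
                sel = mon[:n_tot]
                pos = ~sel
                if _joint_tox_trigger(
                        design, state, arr[:n_tot][sel], tox[:n_tot][sel],
                        t_tox[:n_tot][sel], day, n_mon, windows,
                        met_arrival=arr[:n_tot][pos],
                        met_tox=tox[:n_tot][pos],
                        met_t_tox=t_tox[:n_tot][pos]):
                    return TrialResult("stopped_toxicity", n_tot, day,
                                       stop_look=n_mon)

        # ---- efficacy interim -----------------------------------------
        if mon[k] and n_mon in state.eff_interims:
            sel = mon[:n_tot]
            if design.tte_efficacy:
                x_e, m_e = weighted_endpoint_counts(
                    arr[:n_tot][sel], t_eff[:n_tot][sel], day, windows.t_eff)
                n_thr = min(m_e, n_mon) if design.cn_on_information else n_mon
                if n_thr <= 0:
                    continue
                c_n = cn_threshold(n_thr, design.schedule.n_eff,
                                   design.lam, design.gam)
                if beta_lower(design.eff_prior, x_e, m_e,
                              design.phi_eff) > c_n:
                    return TrialResult("stopped_futility", n_tot, day,
                                       stop_look=n_mon)
            else:
                # binary design: suspend accrual until every enrolled
                # patient's windows are complete, analyse, then resume
                analysis_day = day + windows.t_eff
                x_e = int(np.count_nonzero(eff[:n_tot][sel]))
                if design.simon is not None:
                    stop = x_e <= design.simon.r1
                else:
                    c_n = cn_threshold(n_mon, design.schedule.n_eff,
                                       design.lam, design.gam)
                    stop = beta_lower(design.eff_prior, x_e, n_mon,
                                      design.phi_eff) > c_n
                if stop:
                    return TrialResult("stopped_futility", n_tot,
                                       analysis_day, stop_look=n_mon)
                prev_time = analysis_day  # accrual resumes after the wait

    # ---- final analysis (complete data) ---------------------------------
    n_tot = n_max
    mon_idx = np.flatnonzero(mon)
    n_final = min(state.final_eff_n, len(mon_idx))
    final_idx = mon_idx[:n_final]

    decision_day = float(np.max(arr[final_idx]) + windows.t_eff) \
        if n_final else float(arr[-1] + windows.t_eff)
    if design.tox_rule is not None:
        decision_day = max(decision_day, float(arr.max() + windows.t_tox))

    x_final = int(np.count_nonzero(eff[final_idx]))
    if design.simon is not None:
        eff_pass = x_final > design.simon.r
    else:
        c_n = cn_threshold(max(n_final, 1), design.schedule.n_eff,
                           design.lam, design.gam)
        eff_pass = beta_lower(design.eff_prior, x_final, n_final,
                              design.phi_eff) <= c_n

    tox_pass = True
    if design.tox_rule == "pp":
        x_t = int(np.count_nonzero(tox))
        tox_pass = x_t < state.pp_stop[n_tot]
    elif design.tox_rule == "joint":
        sel = mon
        pos = ~mon
        n_tox_final = min(design.schedule.n_tox, len(mon_idx))
        tox_idx = mon_idx[:n_tox_final]
        x_t = int(np.count_nonzero(tox[tox_idx]))
        prior = design.tox_prior
        if design.informative_tox_prior and pos.any():
            x_pos = int(np.count_nonzero(tox[pos]))
            prior = prior.updated(x_pos, int(pos.sum()))
        c_n = cn_threshold(max(n_tox_final, 1), design.schedule.n_tox,
                           design.lam, design.gam)
        tox_pass = beta_tail(prior, x_t, n_tox_final,
                             design.phi_tox) <= c_n

    decision = "positive" if (eff_pass and tox_pass) else "negative_final"
    return TrialResult(decision, n_tot, decision_day)


def operating_characteristics(design: DesignSpec,
                              scenario: OutcomeScenario,
                              reps: int = 10_000,
                              seed: int | None = None,
                              accrual: AccrualModel | None = None,
                              windows: ObservationWindows | None = None,
                              cohort_size: int = 90) -> OperatingCharacteristics:
    """Monte Carlo operating characteristics of a design under a scenario.

    Each replicate draws an independent patient stream from a child of the
    root seed, so the same ``seed`` yields identical streams across designs
    (common random numbers for design comparisons).
    """
    if reps < 1:
        raise ValueError("need at least one replicate")
    accrual = accrual or AccrualModel()
    windows = windows or ObservationWindows()
    cohort_size = max(cohort_size, design.max_enroll)
    state = _DesignState(design)
    root = np.random.SeedSequence(seed)
    children = root.spawn(reps)

    counts = {d: 0 for d in DECISIONS}
    n_sum = 0.0
    dur_sum = 0.0
    early = 0
    for child in children:
        rng = np.random.Generator(np.random.PCG64(child))
        cohort = generate_cohort(cohort_size, scenario,
                                 p_met_positive=design.p_met_positive,
                                 accrual=accrual, windows=windows, rng=rng)
        res = run_trial(design, cohort, state=state)
        counts[res.decision] += 1
        n_sum += res.n_enrolled
        dur_sum += res.duration
        early += res.early_stop

    p_pos = counts["positive"] / reps
    p_early = early / reps
    return OperatingCharacteristics(
        prob_positive=p_pos,
        se_positive=math.sqrt(p_pos * (1 - p_pos) / reps),
        prob_early_stop=p_early,
        se_early_stop=math.sqrt(p_early * (1 - p_early) / reps),
        mean_n=n_sum / reps,
        mean_duration=dur_sum / reps,
        reps=reps,
        seed=seed,
        decision_counts=counts,
    )


def scenario_sweep(designs: Sequence[DesignSpec],
                   scenarios: Sequence[OutcomeScenario],
                   reps: int = 10_000,
                   seed: int | None = None,
                   accrual: AccrualModel | None = None,
                   windows: ObservationWindows | None = None) -> pd.DataFrame:
    """Full factorial design x scenario operating-characteristics table.

    Returns one long-format row per combination; the same root seed is used
    for every cell, so designs are compared on common patient streams.
    """
    if not designs or not scenarios:
        raise ValueError("need at least one design and one scenario")
    rows = []
    for scenario in scenarios:
        for design in designs:
            oc = operating_characteristics(design, scenario, reps=reps,
                                           seed=seed, accrual=accrual,
                                           windows=windows)
            rows.append({
                "design": design.kind,
                "scenario": scenario.label or "",
                "p_eff": scenario.p_eff,
                "p_tox": scenario.p_tox,
                "r": scenario.r,
                "prob_positive": oc.prob_positive,
                "se_positive": oc.se_positive,
                "prob_early_stop": oc.prob_early_stop,
                "se_early_stop": oc.se_early_stop,
                "mean_n": oc.mean_n,
                "mean_duration": oc.mean_duration,
                "reps": reps,
                "seed": seed,
            })
    return pd.DataFrame(rows)
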