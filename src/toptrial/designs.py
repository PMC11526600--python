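"""The five monitoring designs and their decision boundaries.

All Bayesian rules share the adaptive threshold ``C_n = 1 - lambda (n/N)^gamma``
compared against a posterior tail probability:

* futility -- stop when ``Pr(p_eff <= phi_eff | D_n) > C_n``;
* toxicity (posterior-probability, "PP", rule) -- stop when
  ``Pr(p_tox > 0.25 | D_n) > 0.95`` at frequent looks;
* toxicity (joint co-primary rule) -- stop when
  ``Pr(p_tox > 0.30 | D_n) > C_n``.

Design kinds
------------
``top_eff``
    Time-to-event futility monitoring only (the initially planned design,
    ``lambda = 0.92, gamma = 0.97``); interim uses pending-patient weights.
``top_pp``
    The main proposal: time-to-event futility (``lambda = 0.865,
    gamma = 0.91``) plus the PP toxicity rule at 5..90 patients.
``simon_pp``
    Simon's two-stage design with stages fixed at 30/81 patients, plus the
    PP toxicity rule; accrual suspends at the interim until all observation
    windows are complete.
``bop_pp``
    Complete-data Bayesian optimal futility boundaries (same lambda/gamma as
    ``top_pp``) plus the PP toxicity rule; accrual suspends at interims.
``top_joint`` / ``itop_joint``
    Co-primary efficacy/toxicity monitoring through a multinomial model
    (``lambda = 0.69, gamma = 0.98``), toxicity looks to 81 MET-negative
    patients; the ``itop`` variant refreshes the toxicity prior with
    completed observations from MET-positive patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .posteriors import BetaParams, DirichletParams, beta_lower, beta_tail
from .scenarios import HypothesisPair, planning_hypotheses

__all__ = [
    "DESIGN_KINDS",
    "LookSchedule",
    "DesignSpec",
    "BoundaryTable",
    "SimonDesign",
    "cn_threshold",
    "pp_tox_boundaries",
    "pp_stop_counts",
    "bop_futility_boundaries",
    "simon_calibrate",
    "itop_prior",
    "make_design",
]

DESIGN_KINDS = ("top_eff", "top_pp", "simon_pp", "bop_pp",
                "top_joint", "itop_joint")

PP_TOX_LOOKS = (5, 10, 15, 20, 30, 40, 50, 60, 70, 80, 90)
JOINT_TOX_LOOKS = (5, 10, 15, 20, 30, 40, 50, 60, 70, 81)


def cn_threshold(n: float, N: float, lam: float, gam: float) -> float:
    """Adaptive probability threshold ``C_n = 1 - lambda (n/N)^gamma``."""
    if not 0 < n <= N:
        raise ValueError(f"need 0 < n <= N, got n={n}, N={N}")
    if not 0 < lam <= 1:
        raise ValueError("lambda must be in (0, 1]")
    if not gam > 0:
        raise ValueError("gamma must be positive")
    return 1.0 - lam * (n / N) ** gam


@dataclass(frozen=True)
class LookSchedule:
    """Interim/final analysis schedule in cumulative patient counts.

    Efficacy looks count evaluable (MET-negative) patients; PP toxicity
    looks count all enrolled patients, joint-design toxicity looks count
    MET-negative patients only.
    """

    eff_looks: tuple[int, ...] = (30, 81)
    tox_looks: tuple[int, ...] = PP_TOX_LOOKS
    n_eff: int = 81
    n_tox: int = 90

    def __post_init__(self) -> None:
        for name, looks in (("eff_looks", self.eff_looks),
                            ("tox_looks", self.tox_looks)):
            if looks and any(b <= a for a, b in zip(looks, looks[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.eff_looks and self.eff_looks[-1] != self.n_eff:
            raise ValueError("last efficacy look must equal n_eff")


@dataclass(frozen=True)
class SimonDesign:
    """Exact two-stage design: continue past stage 1 iff ``X1 > r1``,
    conclude efficacy iff additionally ``X > r`` at the final analysis."""

    n1: int
    r1: int
    n: int
    r: int
    alpha_exact: float
    power_exact: float
    en_p0: float
    pet_p0: float

    def __post_init__(self) -> None:
        if not (0 <= self.r1 <= self.n1 and self.r1 <= self.r <= self.n):
            raise ValueError("need 0 <= r1 <= n1 and r1 <= r <= n")


class BoundaryTable:
    """Per-look integer decision boundaries derived from the posterior rules.

    Each row records the look size ``n``, the threshold ``C_n`` (where the
    rule uses one), the maximal toxicity count compatible with continuing,
    and/or the minimal responder count required to continue.
    """

    def __init__(self, rows: list[dict]):
        self.frame = pd.DataFrame(
            rows, columns=["n", "c_n", "max_tox_to_continue",
                           "min_resp_to_continue"])

    def __len__(self) -> int:
        return len(self.frame)

    def row(self, n: int) -> dict:
        match = self.frame[self.frame["n"] == n]
        if match.empty:
            raise KeyError(f"no look at n={n}")
        return match.iloc[0].to_dict()

    def to_csv(self, path_or_buf, **kwargs) -> None:
        self.frame.to_csv(path_or_buf, index=False, **kwargs)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BoundaryTable(\n{self.frame}\n)"


def pp_stop_counts(max_m: int, prior: BetaParams, cutoff: float = 0.25,
                   threshold: float = 0.95) -> np.ndarray:
    """Minimal toxicity count triggering the PP rule, per ascertained count.

    Entry ``m`` holds the smallest integer ``x`` with
    ``Pr(p_tox > cutoff | Beta(a + x, b + m - x)) > threshold``; the
    sentinel ``m + 1`` means the rule cannot trigger with ``m`` ascertained
    patients.  Indexing by the *ascertained* count (not the look size)
    matters because the binary rule discards incomplete windows.
    """
    out = np.empty(max_m + 1, dtype=int)
    for m in range(max_m + 1):
        out[m] = m + 1
        for x in range(m + 1):
            if beta_tail(prior, x, m, cutoff) > threshold:
                out[m] = x
                break
    return out


def pp_tox_boundaries(schedule: LookSchedule | Sequence[int],
                      prior: BetaParams = BetaParams(1.0, 1.0),
                      cutoff: float = 0.25,
                      threshold: float = 0.95) -> BoundaryTable:
    """Boundary table for the posterior-probability toxicity rule.

    Assumes fully ascertained data at each look (``m = n``), which is how
    the table is published; the engine re-derives the trigger count from
    the ascertained ``m`` at run time.
    """
    looks = schedule.tox_looks if isinstance(schedule, LookSchedule) else tuple(schedule)
    stop = pp_stop_counts(max(looks), prior, cutoff, threshold)
    rows = []
    for n in looks:
        s = stop[n]
        rows.append({"n": n, "c_n": np.nan,
                     "max_tox_to_continue": (s - 1) if s <= n else n,
                     "min_resp_to_continue": np.nan})
    return BoundaryTable(rows)


def bop_futility_boundaries(schedule: LookSchedule | Sequence[int],
                            prior: BetaParams,
                            phi_eff: float = 0.15,
                            lam: float = 0.865,
                            gam: float = 0.91,
                            n_max: int | None = None) -> BoundaryTable:
    """Integer futility boundaries for complete-data looks.

    At a look with ``n`` evaluable patients the trial continues iff the
    responder count reaches the smallest ``x`` with
    ``Pr(p_eff <= phi_eff | Beta(a + x, b + n - x)) <= C_n``; at the final
    look the same condition defines a positive trial.
    """
    if isinstance(schedule, LookSchedule):
        looks = schedule.eff_looks
        n_max = n_max or schedule.n_eff
    else:
        looks = tuple(schedule)
        n_max = n_max or max(looks)
    rows = []
    for n in looks:
        c_n = cn_threshold(n, n_max, lam, gam)
        min_resp = n + 1  # unreachable: always stop
        for x in range(n + 1):
            if beta_lower(prior, x, n, phi_eff) <= c_n:
                min_resp = x
                break
        rows.append({"n": n, "c_n": c_n, "max_tox_to_continue": np.nan,
                     "min_resp_to_continue": min_resp})
    return BoundaryTable(rows)


@lru_cache(maxsize=None)
def simon_calibrate(p0: float = 0.15, p1: float = 0.30,
                    alpha_max: float = 0.05, power_min: float = 0.90,
                    n1: int = 30, n: int = 81) -> SimonDesign:
    """Exhaustive two-stage search with both stage sizes fixed.

    Enumerates all ``(r1, r)`` pairs, keeps those with exact binomial type I
    error at most ``alpha_max`` and exact power at least ``power_min``, and
    among them minimises the expected sample size under ``p0``,
    ``EN(p0) = n1 + (1 - PET(p0)) (n - n1)`` with
    ``PET(p0) = Pr(X1 <= r1 | n1, p0)``.  Ties are broken by smaller type I
    error, then larger power.
    """
    if not p0 < p1:
        raise ValueError("need p0 < p1")
    if not 0 < n1 < n:
        raise ValueError("need 0 < n1 < n")
    best = None
    frontier = None  # closest-to-admissible pair, for the error message
    for r1 in range(n1 + 1):
        pet0 = binom.cdf(r1, n1, p0)
        x1 = np.arange(r1 + 1, n1 + 1)
        pmf0 = binom.pmf(x1, n1, p0)
        pmf1 = binom.pmf(x1, n1, p1)
        for r in range(r1, n + 1):
            tail0 = binom.sf(r - x1, n - n1, p0)
            tail1 = binom.sf(r - x1, n - n1, p1)
            alpha = float((pmf0 * tail0).sum())
            power = float((pmf1 * tail1).sum())
            if frontier is None or (max(alpha - alpha_max, 0.0)
                                    + max(power_min - power, 0.0)
                                    < frontier[0]):
                frontier = (max(alpha - alpha_max, 0.0)
                            + max(power_min - power, 0.0), alpha, power, r1, r)
            if alpha <= alpha_max and power >= power_min:
                en = n1 + (1.0 - pet0) * (n - n1)
                key = (en, alpha, -power)
                if best is None or key < best[0]:
                    best = (key, SimonDesign(n1=n1, r1=r1, n=n, r=r,
                                             alpha_exact=alpha,
                                             power_exact=power,
                                             en_p0=en, pet_p0=float(pet0)))
    if best is None:
        _, alpha, power, r1, r = frontier
        raise ValueError(
            f"no (r1, r) satisfies alpha <= {alpha_max} and power >= "
            f"{power_min}; closest is r1={r1}, r={r} with alpha={alpha:.4f}, "
            f"power={power:.4f}")
    return best[1]


def itop_prior(base: BetaParams | DirichletParams, x_pos: float,
               n_pos: float) -> BetaParams:
    """Informative toxicity prior from concomitant (MET-positive) patients.

    Increments the toxicity pseudo-counts by the completed observations
    ``(x_pos, n_pos - x_pos)``; assumes toxicity is homogeneous across MET
    status.  A Dirichlet base is reduced to its Beta toxicity marginal
    first (the joint rule only ever evaluates the marginal, and a
    toxicity-only increment cannot be placed inside the four cells without
    disturbing the efficacy marginal).
    """
    if not 0 <= x_pos <= n_pos:
        raise ValueError("need 0 <= x_pos <= n_pos")
    if isinstance(base, DirichletParams):
        base = base.tox_marginal()
    return base.updated(x_pos, n_pos)


@dataclass(frozen=True)
class DesignSpec:
    """A fully assembled monitoring design, ready for the trial engine."""

    kind: str
    lam: float
    gam: float
    schedule: LookSchedule
    eff_prior: BetaParams
    tox_prior: BetaParams
    phi_eff: float = 0.15
    phi_tox: float = 0.25
    pp_threshold: float = 0.95
    tte_efficacy: bool = True       # pending-patient weighting at interims
    cn_on_information: bool = True  # weighted interims index C_n by the
                                    # effective (weighted) sample size
    suspend_accrual: bool = False   # complete-data interims (binary designs)
    tox_rule: str | None = "pp"     # "pp", "joint" or None
    weight_toxicity: bool = False   # fractional weights at joint tox looks
    informative_tox_prior: bool = False
    simon: SimonDesign | None = None
    ignore_met: bool = False        # homogeneous population (all evaluable)
    max_enroll: int = 90
    p_met_positive: float = 0.10
    binding: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.lam <= 1:
            raise ValueError("lambda must be in (0, 1]")
        if not self.gam > 0:
            raise ValueError("gamma must be positive")
        if self.tox_rule not in (None, "pp", "joint"):
            raise ValueError(f"unknown tox_rule {self.tox_rule!r}")
        if self.kind == "simon_pp" and self.simon is None:
            raise ValueError("simon_pp design needs a SimonDesign")

    # -- boundary export -------------------------------------------------
    def efficacy_boundaries(self) -> BoundaryTable:
        if self.simon is not None:
            rows = [
                {"n": self.simon.n1, "c_n": np.nan,
                 "max_tox_to_continue": np.nan,
                 "min_resp_to_continue": self.simon.r1 + 1},
                {"n": self.simon.n, "c_n": np.nan,
                 "max_tox_to_continue": np.nan,
                 "min_resp_to_continue": self.simon.r + 1},
            ]
            return BoundaryTable(rows)
        return bop_futility_boundaries(self.schedule, self.eff_prior,
                                       self.phi_eff, self.lam, self.gam,
                                       self.schedule.n_eff)

    def toxicity_boundaries(self) -> BoundaryTable:
        if self.tox_rule == "pp":
            return pp_tox_boundaries(self.schedule, self.tox_prior,
                                     self.phi_tox, self.pp_threshold)
        if self.tox_rule == "joint":
            rows = []
            for n in self.schedule.tox_looks:
                c_n = cn_threshold(n, self.schedule.n_tox, self.lam, self.gam)
                s = n + 1
                for x in range(n + 1):
                    if beta_tail(self.tox_prior, x, n, self.phi_tox) > c_n:
                        s = x
                        break
                rows.append({"n": n, "c_n": c_n,
                             "max_tox_to_continue": (s - 1) if s <= n else n,
                             "min_resp_to_continue": np.nan})
            return BoundaryTable(rows)
        raise ValueError("design has no toxicity rule")

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "kind": self.kind, "lam": self.lam, "gam": self.gam,
            "phi_eff": self.phi_eff, "phi_tox": self.phi_tox,
            "pp_threshold": self.pp_threshold,
            "eff_prior": [self.eff_prior.a, self.eff_prior.b],
            "tox_prior": [self.tox_prior.a, self.tox_prior.b],
            "schedule": {
                "eff_looks": list(self.schedule.eff_looks),
                "tox_looks": list(self.schedule.tox_looks),
                "n_eff": self.schedule.n_eff, "n_tox": self.schedule.n_tox,
            },
            "tte_efficacy": self.tte_efficacy,
            "suspend_accrual": self.suspend_accrual,
            "tox_rule": self.tox_rule,
            "weight_toxicity": self.weight_toxicity,
            "informative_tox_prior": self.informative_tox_prior,
            "ignore_met": self.ignore_met,
            "max_enroll": self.max_enroll,
            "p_met_positive": self.p_met_positive,
            "binding": self.binding,
        }
        if self.simon is not None:
            d["simon"] = {
                "n1": self.simon.n1, "r1": self.simon.r1,
                "n": self.simon.n, "r": self.simon.r,
                "alpha_exact": self.simon.alpha_exact,
                "power_exact": self.simon.power_exact,
                "en_p0": self.simon.en_p0, "pet_p0": self.simon.pet_p0,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        simon = SimonDesign(**d["simon"]) if "simon" in d and d["simon"] else None
        sched = d["schedule"]
        return cls(
            kind=d["kind"], lam=d["lam"], gam=d["gam"],
            schedule=LookSchedule(
                eff_looks=tuple(sched["eff_looks"]),
                tox_looks=tuple(sched["tox_looks"]),
                n_eff=sched["n_eff"], n_tox=sched["n_tox"]),
            eff_prior=BetaParams(*d["eff_prior"]),
            tox_prior=BetaParams(*d["tox_prior"]),
            phi_eff=d["phi_eff"], phi_tox=d["phi_tox"],
            pp_threshold=d["pp_threshold"],
            tte_efficacy=d["tte_efficacy"],
            suspend_accrual=d["suspend_accrual"],
            tox_rule=d["tox_rule"], weight_toxicity=d["weight_toxicity"],
            informative_tox_prior=d["informative_tox_prior"],
            simon=simon, ignore_met=d["ignore_met"],
            max_enroll=d["max_enroll"],
            p_met_positive=d.get("p_met_positive", 0.10),
            binding=d.get("binding", True),
        )


def make_design(kind: str, lam: float | None = None,
                gamma: float | None = None,
                hypotheses: HypothesisPair | None = None,
                **overrides) -> DesignSpec:
    """Assemble one of the study designs with its published defaults.

    ``lam``/``gamma`` override the calibrated threshold hyperparameters
    (e.g. the initially planned futility design used ``0.92/0.97``); any
    :class:`DesignSpec` field can be overridden by keyword.  Priors follow
    the published conventions: the PP toxicity rule uses a uniform
    Beta(1, 1), and the Bayesian optimal family uses a Dirichlet matching
    the null-hypothesis cells with total effective sample size 1, reduced
    to its Beta marginals.
    """
    if kind not in DESIGN_KINDS:
        raise ValueError(f"unknown design kind {kind!r}; choose from "
                         f"{DESIGN_KINDS}")
    hypotheses = hypotheses or planning_hypotheses()
    dirichlet = DirichletParams.from_scenario(hypotheses.h0, ess=1.0)
    eff_prior = dirichlet.eff_marginal()

    base: dict = {
        "kind": kind,
        "eff_prior": eff_prior,
        "schedule": LookSchedule(),
    }
    if kind == "top_eff":
        base.update(lam=0.92, gam=0.97, tox_rule=None,
                    tox_prior=BetaParams(1.0, 1.0))
    elif kind == "top_pp":
        base.update(lam=0.865, gam=0.91, tox_rule="pp", phi_tox=0.25,
                    tox_prior=BetaParams(1.0, 1.0))
    elif kind == "bop_pp":
        base.update(lam=0.865, gam=0.91, tox_rule="pp", phi_tox=0.25,
                    tox_prior=BetaParams(1.0, 1.0),
                    tte_efficacy=False, suspend_accrual=True)
    elif kind == "simon_pp":
        simon = simon_calibrate(p0=hypotheses.h0.p_eff, p1=hypotheses.h1.p_eff)
        base.update(lam=0.865, gam=0.91, tox_rule="pp", phi_tox=0.25,
                    tox_prior=BetaParams(1.0, 1.0),
                    tte_efficacy=False, suspend_accrual=True, simon=simon)
    else:  # joint co-primary designs
        joint_sched = LookSchedule(tox_looks=JOINT_TOX_LOOKS, n_tox=81)
        base.update(lam=0.69, gam=0.98, tox_rule="joint", phi_tox=0.30,
                    tox_prior=dirichlet.tox_marginal(),
                    schedule=joint_sched, weight_toxicity=True)
        if kind == "top_joint":
            # homogeneous-population variant: every patient is evaluable
            base.update(ignore_met=True, max_enroll=81, p_met_positive=0.0)
        else:
            base.update(informative_tox_prior=True)
    if lam is not None:
        base["lam"] = lam
    if gamma is not None:
        base["gam"] = gamma
    base.update(overrides)
    return DesignSpec(**base)
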