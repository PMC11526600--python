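"""Synthetic patient-stream generation.

Emulates continuous accrual into a single-arm trial: arrival times (Poisson
process by default, mean interpatient gap 6 days), an independent
biomarker flag (MET amplification, 10% prevalence), latent correlated
efficacy/toxicity outcomes drawn from a scenario's joint cells, and latent
event times uniform over each observation window (180 days for response,
42 days for unacceptable toxicity).  Everything is generated up front; the
trial engine reveals outcomes only as follow-up accrues.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .scenarios import OutcomeScenario, joint_cell_probs

__all__ = [
    "AccrualModel",
    "ObservationWindows",
    "PatientRecord",
    "CohortStream",
    "simulate_arrivals",
    "generate_cohort",
]


@dataclass(frozen=True)
class AccrualModel:
    """Interpatient arrival model.

    ``exponential`` gaps give a homogeneous Poisson accrual process (the
    default, 5 patients/month for a 6-day mean gap); ``fixed`` places
    arrivals on a deterministic grid, which is convenient for exact tests.
    """

    mean_interarrival: float = 6.0
    mode: str = "exponential"

    def __post_init__(self) -> None:
        if not self.mean_interarrival > 0:
            raise ValueError("mean_interarrival must be positive")
        if self.mode not in ("exponential", "fixed"):
            raise ValueError(f"unknown accrual mode {self.mode!r}")


@dataclass(frozen=True)
class ObservationWindows:
    """Endpoint ascertainment windows, in days from each patient's arrival."""

    t_eff: float = 180.0
    t_tox: float = 42.0

    def __post_init__(self) -> None:
        if not (self.t_eff > 0 and self.t_tox > 0):
            raise ValueError("observation windows must be positive")


def simulate_arrival_gaps(n: int, accrual: AccrualModel,
                          rng: np.random.Generator) -> np.ndarray:
    """Interarrival gaps for ``n`` patients; the first gap is zero."""
    if n < 1:
        raise ValueError("need at least one patient")
    gaps = np.empty(n)
    gaps[0] = 0.0
    if n > 1:
        if accrual.mode == "fixed":
            gaps[1:] = accrual.mean_interarrival
        else:
            gaps[1:] = rng.exponential(accrual.mean_interarrival, size=n - 1)
    return gaps


def simulate_arrivals(n: int, accrual: AccrualModel,
                      rng: np.random.Generator) -> np.ndarray:
    """Arrival days for ``n`` patients; first arrival at day 0, non-decreasing."""
    return np.cumsum(simulate_arrival_gaps(n, accrual, rng))


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient.

    ``t_eff``/``t_tox`` are event-time offsets from arrival, defined only
    when the corresponding latent indicator is true (``None`` otherwise).
    """

    index: int
    arrival: float
    met_positive: bool
    eff: bool
    tox: bool
    t_eff: float | None
    t_tox: float | None


class CohortStream:
    """An ordered stream of simulated patients plus its observation windows.

    Stores the cohort as parallel arrays (fast for the trial engine) and
    exposes :class:`PatientRecord` views.  Event-time arrays use ``+inf``
    for "no event"; records translate that to ``None``.  Interarrival gaps
    are kept alongside arrival days so accrual can be re-timed when a design
    suspends enrollment.
    """

    def __init__(self, gaps: np.ndarray, met: np.ndarray, eff: np.ndarray,
                 tox: np.ndarray, t_eff: np.ndarray, t_tox: np.ndarray,
                 windows: ObservationWindows, seed: int | None = None):
        n = len(gaps)
        for name, arr in (("met", met), ("eff", eff), ("tox", tox),
                          ("t_eff", t_eff), ("t_tox", t_tox)):
            if len(arr) != n:
                raise ValueError(f"array {name!r} length mismatch")
        self.gaps = np.asarray(gaps, dtype=float)
        if np.any(self.gaps < 0):
            raise ValueError("gaps must be non-negative")
        self.met = np.asarray(met, dtype=bool)
        self.eff = np.asarray(eff, dtype=bool)
        self.tox = np.asarray(tox, dtype=bool)
        self.t_eff = np.asarray(t_eff, dtype=float)
        self.t_tox = np.asarray(t_tox, dtype=float)
        self.windows = windows
        self.seed = seed

    def __len__(self) -> int:
        return len(self.gaps)

    @property
    def arrivals(self) -> np.ndarray:
        """Arrival days under uninterrupted accrual (first arrival day 0)."""
        return np.cumsum(self.gaps)

    def __getitem__(self, index: int) -> PatientRecord:
        arr = self.arrivals
        te = self.t_eff[index]
        tt = self.t_tox[index]
        return PatientRecord(
            index=int(index),
            arrival=float(arr[index]),
            met_positive=bool(self.met[index]),
            eff=bool(self.eff[index]),
            tox=bool(self.tox[index]),
            t_eff=None if np.isinf(te) else float(te),
            t_tox=None if np.isinf(tt) else float(tt),
        )

    @property
    def patients(self) -> list[PatientRecord]:
        return [self[i] for i in range(len(self))]

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def to_frame(self) -> pd.DataFrame:
        arr = self.arrivals
        return pd.DataFrame({
            "index": np.arange(len(self)),
            "arrival": arr,
            "met_positive": self.met.astype(int),
            "eff": self.eff.astype(int),
            "tox": self.tox.astype(int),
            "t_eff": np.where(np.isinf(self.t_eff), np.nan, self.t_eff),
            "t_tox": np.where(np.isinf(self.t_tox), np.nan, self.t_tox),
        })

    def to_csv(self, path_or_buf) -> None:
        """Serialize to CSV with the seed and windows in a header comment."""
        header = (f"# toptrial cohort seed={self.seed} "
                  f"t_eff={self.windows.t_eff} t_tox={self.windows.t_tox}\n")
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header)
            self.to_frame().to_csv(path_or_buf, index=False)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(header)
                self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "CohortStream":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        lines = text.splitlines(keepends=True)
        meta = {}
        if lines and lines[0].startswith("#"):
            for token in lines[0].lstrip("#").split():
                if "=" in token:
                    key, val = token.split("=", 1)
                    meta[key] = val
            lines = lines[1:]
        df = pd.read_csv(io.StringIO("".join(lines)))
        arrivals = df["arrival"].to_numpy()
        gaps = np.diff(arrivals, prepend=0.0)
        windows = ObservationWindows(
            t_eff=float(meta.get("t_eff", 180.0)),
            t_tox=float(meta.get("t_tox", 42.0)),
        )
        seed = meta.get("seed")
        seed = None if seed in (None, "None") else int(seed)
        return cls(
            gaps=gaps,
            met=df["met_positive"].to_numpy(dtype=bool),
            eff=df["eff"].to_numpy(dtype=bool),
            tox=df["tox"].to_numpy(dtype=bool),
            t_eff=np.where(df["t_eff"].isna(), np.inf, df["t_eff"]),
            t_tox=np.where(df["t_tox"].isna(), np.inf, df["t_tox"]),
            windows=windows,
            seed=seed,
        )


def generate_cohort(n: int, scenario: OutcomeScenario,
                    p_met_positive: float = 0.10,
                    accrual: AccrualModel | None = None,
                    windows: ObservationWindows | None = None,
                    rng: np.random.Generator | None = None,
                    seed: int | None = None) -> CohortStream:
    """Generate a cohort of ``n`` patients under a true-outcome scenario.

    Outcome pairs are drawn from the scenario's four joint cells; MET status
    is an independent Bernoulli(``p_met_positive``) per patient (toxicity is
    assumed homogeneous across MET status, and MET-positive efficacy never
    enters efficacy monitoring); event times are uniform on ``(0, window]``
    for patients with an event.  All latent values are stored up front and
    revealed only as the trial engine accrues follow-up.
    """
    if n < 1:
        raise ValueError("need at least one patient")
    if not 0.0 <= p_met_positive <= 1.0:
        raise ValueError("p_met_positive must be a probability")
    accrual = accrual or AccrualModel()
    windows = windows or ObservationWindows()
    if rng is None:
        rng = np.random.default_rng(seed)

    gaps = simulate_arrival_gaps(n, accrual, rng)
    met = rng.random(n) < p_met_positive
    # joint outcome cells: 0 = Eff&Tox, 1 = Eff&~Tox, 2 = ~Eff&Tox, 3 = ~Eff&~Tox
    cells = joint_cell_probs(scenario).as_array()
    cut = np.cumsum(cells)
    cell_idx = np.searchsorted(cut, rng.random(n), side="right")
    eff = cell_idx <= 1
    tox = (cell_idx == 0) | (cell_idx == 2)
    # uniform on the half-open interval (0, window]
    t_eff = np.where(eff, (1.0 - rng.random(n)) * windows.t_eff, np.inf)
    t_tox = np.where(tox, (1.0 - rng.random(n)) * windows.t_tox, np.inf)
    return CohortStream(gaps, met, eff, tox, t_eff, t_tox, windows, seed=seed)
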