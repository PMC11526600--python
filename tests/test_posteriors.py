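"""Beta/Dirichlet posterior machinery and pending-patient weighting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import beta as beta_dist, dirichlet

import toptrial as tt
from toptrial.posteriors import binary_endpoint_counts, weighted_endpoint_counts

UNIFORM = tt.BetaParams(1.0, 1.0)
WINDOWS = tt.ObservationWindows()


def _record(arrival, eff, tox, t_eff=None, t_tox=None, index=0):
    return tt.PatientRecord(index=index, arrival=arrival, met_positive=False,
                            eff=eff, tox=tox, t_eff=t_eff, t_tox=t_tox)


def test_uniform_prior_tail_mass():
    assert tt.beta_tail(UNIFORM, 0, 0, 0.25) == pytest.approx(0.75)


def test_tail_at_zero_cutoff_is_one():
    assert tt.beta_tail(tt.BetaParams(2.5, 7.5), 3, 10, 0.0) == 1.0


def test_tail_matches_quadrature():
    """Beta(4, 8) upper tail beyond 0.25 agrees with direct integration."""
    val = tt.beta_tail(UNIFORM, 3, 10, 0.25)
    dens = beta_dist(4, 8).pdf
    oracle, err = integrate.quad(dens, 0.25, 1.0, epsabs=1e-12)
    assert err < 1e-10
    assert val == pytest.approx(oracle, abs=1e-8)


def test_tail_validates_inputs():
    with pytest.raises(ValueError):
        tt.beta_tail(UNIFORM, 3, 10, 1.5)
    with pytest.raises(ValueError):
        tt.beta_tail(UNIFORM, 11, 10, 0.5)
    with pytest.raises(ValueError):
        tt.BetaParams(0.0, 1.0)


@given(x=st.floats(0, 20), extra=st.floats(0, 20),
       c1=st.floats(0.05, 0.9), dc=st.floats(0.01, 0.09))
@settings(max_examples=150, deadline=None)
def test_tail_monotone_in_cutoff_and_events(x, extra, c1, dc):
    m = x + extra
    assert tt.beta_tail(UNIFORM, x, m, c1 + dc) <= tt.beta_tail(UNIFORM, x, m, c1)
    if x + 1 <= m:
        assert tt.beta_tail(UNIFORM, x + 1, m, c1) >= tt.beta_tail(UNIFORM, x, m, c1)


def test_effective_counts_complete_windows_equal_raw_counts():
    patients = [
        _record(0.0, True, True, t_eff=100.0, t_tox=10.0),
        _record(5.0, False, False),
        _record(10.0, True, False, t_eff=50.0),
    ]
    counts = tt.effective_counts(patients, analysis_day=200.0, windows=WINDOWS)
    assert (counts.x_eff, counts.m_eff) == (2.0, 3.0)
    assert (counts.x_tox, counts.m_tox) == (1.0, 3.0)
    assert counts.n_enrolled == 3


def test_pending_patient_contributes_fractional_weight():
    patients = [_record(0.0, False, False)]
    counts = tt.effective_counts(patients, analysis_day=90.0, windows=WINDOWS)
    assert (counts.x_eff, counts.m_eff) == (0.0, 0.5)
    # toxicity side: window complete at day 90, so a full binary count
    assert (counts.x_tox, counts.m_tox) == (0.0, 1.0)


def test_observed_response_counts_fully_despite_open_window():
    patients = [_record(0.0, True, False, t_eff=30.0)]
    counts = tt.effective_counts(patients, analysis_day=40.0, windows=WINDOWS)
    assert (counts.x_eff, counts.m_eff) == (1.0, 1.0)


def test_binary_toxicity_counts_use_complete_windows_only():
    """An early toxicity inside an open 42-day window stays uncounted.

    Counting determined events while their event-free contemporaries are
    invisible would bias the interim toxicity rate upward, so the binary
    convention waits for the window.
    """
    arrival = np.array([0.0, 5.0])
    t_tox = np.array([10.0, np.inf])
    x, m = binary_endpoint_counts(arrival, t_tox, analysis_day=20.0, window=42.0)
    assert (x, m) == (0, 0)
    x, m = binary_endpoint_counts(arrival, t_tox, analysis_day=44.0, window=42.0)
    assert (x, m) == (1, 1)
    with pytest.raises(ValueError):
        binary_endpoint_counts(arrival, t_tox, analysis_day=1.0, window=42.0)


def test_weighted_toxicity_counts_when_requested():
    patients = [_record(0.0, False, True, t_tox=10.0),
                _record(0.0, False, False)]
    counts = tt.effective_counts(patients, analysis_day=21.0, windows=WINDOWS,
                                 weight_toxicity=True)
    assert (counts.x_tox, counts.m_tox) == (1.0, 1.5)


def test_dirichlet_marginals_aggregate_to_beta():
    prior = tt.DirichletParams((1.0, 1.0, 1.0, 1.0))
    assert prior.eff_marginal() == tt.BetaParams(2.0, 2.0)
    eff_lower, tox_upper = tt.dirichlet_marginal_tails(
        prior, (0.0, 0.0, 0.0, 0.0), 0.15, 0.30)
    assert eff_lower == pytest.approx(
        1 - tt.beta_tail(tt.BetaParams(2, 2), 0, 0, 0.15), abs=1e-12)


@given(c=st.tuples(*(st.floats(0, 30) for _ in range(4))))
@settings(max_examples=100, deadline=None)
def test_dirichlet_tails_equal_beta_on_aggregated_counts(c):
    prior = tt.DirichletParams((0.2, 0.4, 0.6, 0.8))
    eff_lower, tox_upper = tt.dirichlet_marginal_tails(prior, c, 0.15, 0.30)
    total = sum(c)
    exp_eff = 1 - tt.beta_tail(prior.eff_marginal(), c[0] + c[1], total, 0.15)
    exp_tox = tt.beta_tail(prior.tox_marginal(), c[0] + c[2], total, 0.30)
    assert eff_lower == pytest.approx(exp_eff, abs=1e-12)
    assert tox_upper == pytest.approx(exp_tox, abs=1e-12)


def test_dirichlet_tails_match_monte_carlo_sampling():
    prior = tt.DirichletParams((0.08, 0.07, 0.22, 0.63))
    counts = (3.0, 4.5, 2.0, 10.5)
    eff_lower, tox_upper = tt.dirichlet_marginal_tails(prior, counts, 0.15, 0.30)
    alpha = np.array(prior.alpha) + np.array(counts)
    draws = dirichlet(alpha).rvs(100_000, random_state=1)
    p_eff = draws[:, 0] + draws[:, 1]
    p_tox = draws[:, 0] + draws[:, 2]
    for est, target in (((p_eff <= 0.15).mean(), eff_lower),
                        ((p_tox > 0.30).mean(), tox_upper)):
        assert abs(est - target) < 3 * math.sqrt(target * (1 - target) / 1e5) + 1e-4


def test_zero_toxicity_cells_drive_tail_to_zero():
    prior = tt.DirichletParams((0.25, 0.25, 0.25, 0.25))
    _, tox_upper = tt.dirichlet_marginal_tails(prior, (0, 500.0, 0, 500.0),
                                               0.15, 0.30)
    assert tox_upper < 1e-10


def test_dirichlet_prior_from_scenario_matches_cells():
    h0 = tt.planning_hypotheses().h0
    prior = tt.DirichletParams.from_scenario(h0, ess=1.0)
    assert sum(prior.alpha) == pytest.approx(1.0)
    assert prior.eff_marginal().mean == pytest.approx(0.15, abs=1e-12)
    assert prior.tox_marginal().mean == pytest.approx(0.30, abs=1e-12)
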