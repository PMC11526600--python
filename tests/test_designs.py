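"""Decision thresholds, boundary tables, Simon calibration, design assembly."""

import math

import numpy as np
import pytest
from scipy.stats import beta as beta_dist, binom
import sympy

import toptrial as tt


# ---------------------------------------------------------------- thresholds
def test_cn_threshold_edge_values():
    assert tt.cn_threshold(81, 81, 0.865, 0.91) == pytest.approx(0.135)
    assert tt.cn_threshold(50, 50, 1.0, 2.3) == pytest.approx(0.0)


def test_cn_threshold_matches_arbitrary_precision():
    lam, gam = sympy.Rational(865, 1000), sympy.Rational(91, 100)
    exact = 1 - lam * sympy.Rational(30, 81) ** gam
    assert tt.cn_threshold(30, 81, 0.865, 0.91) == pytest.approx(
        float(sympy.N(exact, 30)), abs=1e-12)
    assert tt.cn_threshold(30, 81, 0.865, 0.91) == pytest.approx(0.6497, abs=5e-5)


def test_cn_threshold_decreasing_in_n():
    vals = [tt.cn_threshold(n, 81, 0.69, 0.98) for n in range(1, 82)]
    assert np.all(np.diff(vals) < 0)


def test_cn_threshold_validates():
    with pytest.raises(ValueError):
        tt.cn_threshold(82, 81, 0.9, 1.0)
    with pytest.raises(ValueError):
        tt.cn_threshold(10, 81, 1.2, 1.0)
    with pytest.raises(ValueError):
        tt.cn_threshold(10, 81, 0.9, 0.0)


# ----------------------------------------------------------- toxicity tables
def _pp_stop_oracle(n, cutoff=0.25, threshold=0.95):
    """Smallest trigger count via the binomial identity for integer Betas."""
    for x in range(n + 1):
        # Pr(p > c | Beta(1+x, 1+n-x)) = Pr(Bin(n+1, c) <= x)
        if binom.cdf(x, n + 1, cutoff) > threshold:
            return x
    return n + 1


@pytest.mark.parametrize("n,expected", [(5, 3), (10, 5)])
def test_pp_boundaries_match_published_counts(n, expected):
    table = tt.pp_tox_boundaries([n])
    assert table.row(n)["max_tox_to_continue"] == expected - 1
    assert _pp_stop_oracle(n) == expected


def test_pp_stop_counts_agree_with_binomial_oracle():
    stops = tt.pp_stop_counts(90, tt.BetaParams(1, 1))
    for m in range(91):
        assert stops[m] == _pp_stop_oracle(m)


def test_pp_threshold_one_never_stops():
    stops = tt.pp_stop_counts(30, tt.BetaParams(1, 1), threshold=1.0)
    assert np.all(stops == np.arange(31) + 1)  # sentinel everywhere


# ----------------------------------------------------------- futility tables
def test_bop_boundary_single_look_toy_vs_brute_force():
    prior = tt.BetaParams(1.0, 1.0)
    table = tt.bop_futility_boundaries([10], prior, phi_eff=0.15,
                                       lam=0.9, gam=1.0, n_max=10)
    c_n = 1 - 0.9 * (10 / 10) ** 1.0
    brute = next(x for x in range(11)
                 if beta_dist.cdf(0.15, 1 + x, 1 + 10 - x) <= c_n)
    assert table.row(10)["min_resp_to_continue"] == brute


def test_bop_boundary_zero_phi_never_stops():
    table = tt.bop_futility_boundaries([20, 40], tt.BetaParams(1, 1),
                                       phi_eff=0.0, lam=0.9, gam=1.0, n_max=40)
    assert (table.frame["min_resp_to_continue"] == 0).all()


def test_bop_boundaries_nondecreasing_and_rule_consistent():
    design = tt.make_design("bop_pp")
    table = design.efficacy_boundaries()
    bounds = table.frame["min_resp_to_continue"].to_numpy()
    assert np.all(np.diff(bounds) >= 0)
    # every feasible count reproduces the stop/continue decision it encodes
    for _, row in table.frame.iterrows():
        n, bdy = int(row["n"]), int(row["min_resp_to_continue"])
        for x in range(n + 1):
            posterior_stop = tt.beta_lower(design.eff_prior, x, n,
                                           design.phi_eff) > row["c_n"]
            assert posterior_stop == (x < bdy)


def test_joint_toxicity_boundaries_rule_consistent():
    design = tt.make_design("top_joint")
    table = design.toxicity_boundaries()
    for _, row in table.frame.iterrows():
        n, max_ok = int(row["n"]), int(row["max_tox_to_continue"])
        for x in range(n + 1):
            trig = tt.beta_tail(design.tox_prior, x, n,
                                design.phi_tox) > row["c_n"]
            assert trig == (x > max_ok)


# ------------------------------------------------------------------- Simon
def _simon_exact(r1, r, n1=30, n=81, p=0.15):
    x1 = np.arange(r1 + 1, n1 + 1)
    return float((binom.pmf(x1, n1, p) * binom.sf(r - x1, n - n1, p)).sum())


def test_simon_search_agrees_with_brute_force():
    design = tt.simon_calibrate()
    best = None
    for r1 in range(31):
        for r in range(r1, 82):
            alpha = _simon_exact(r1, r, p=0.15)
            power = _simon_exact(r1, r, p=0.30)
            if alpha <= 0.05 and power >= 0.90:
                en = 30 + (1 - binom.cdf(r1, 30, 0.15)) * 51
                key = (en, alpha, -power)
                if best is None or key < best[0]:
                    best = (key, r1, r)
    assert (design.r1, design.r) == (best[1], best[2])
    assert design.alpha_exact == pytest.approx(_simon_exact(design.r1, design.r))
    assert design.pet_p0 == pytest.approx(binom.cdf(design.r1, 30, 0.15))


def test_simon_alpha_matches_two_stage_simulation():
    design = tt.simon_calibrate()
    rng = np.random.default_rng(12)
    n = 100_000
    x1 = rng.binomial(design.n1, 0.15, size=n)
    x2 = rng.binomial(design.n - design.n1, 0.15, size=n)
    rej = ((x1 > design.r1) & (x1 + x2 > design.r)).mean()
    se = math.sqrt(design.alpha_exact * (1 - design.alpha_exact) / n)
    assert abs(rej - design.alpha_exact) < 3 * se


def test_simon_never_reject_boundary_has_zero_alpha():
    assert _simon_exact(0, 81) == pytest.approx(0.0, abs=1e-15)


def test_simon_infeasible_constraints_report_frontier():
    with pytest.raises(ValueError, match="closest"):
        tt.simon_calibrate(p0=0.15, p1=0.17, alpha_max=0.01, power_min=0.99)


# ----------------------------------------------------------- informative prior
def test_itop_prior_updates_toxicity_pseudocounts():
    assert tt.itop_prior(tt.BetaParams(1, 1), 2, 5) == tt.BetaParams(3.0, 4.0)
    assert tt.itop_prior(tt.BetaParams(1, 1), 0, 0) == tt.BetaParams(1.0, 1.0)
    base = tt.DirichletParams.from_scenario(tt.planning_hypotheses().h0)
    updated = tt.itop_prior(base, 1, 4)
    assert updated == base.tox_marginal().updated(1.0, 4.0)
    with pytest.raises(ValueError):
        tt.itop_prior(tt.BetaParams(1, 1), 3, 2)


def test_itop_more_observed_toxicity_tightens_boundaries():
    """Boundaries are monotone: a worse concomitant record never loosens."""
    n_pos = 8
    prev = None
    for x_pos in range(n_pos + 1):
        prior = tt.itop_prior(tt.BetaParams(0.3, 0.7), x_pos, n_pos)
        stops = tt.pp_stop_counts(40, prior, cutoff=0.30, threshold=0.60)
        if prev is not None:
            assert np.all(stops <= prev)
        prev = stops


# ----------------------------------------------------------- design assembly
def test_make_design_published_defaults():
    assert (tt.make_design("top_pp").lam, tt.make_design("top_pp").gam) \
        == (0.865, 0.91)
    assert (tt.make_design("top_joint").lam, tt.make_design("top_joint").gam) \
        == (0.69, 0.98)
    initial = tt.make_design("top_eff")
    assert (initial.lam, initial.gam) == (0.92, 0.97)
    assert initial.tox_rule is None


def test_make_design_structure_of_the_five_designs():
    pp = tt.make_design("top_pp")
    assert pp.schedule.tox_looks[-1] == 90 and pp.schedule.n_eff == 81
    assert pp.eff_prior.mean == pytest.approx(0.15)
    assert pp.tox_prior == tt.BetaParams(1.0, 1.0)
    simon = tt.make_design("simon_pp")
    assert simon.simon is not None and simon.suspend_accrual
    assert (simon.simon.n1, simon.simon.n) == (30, 81)
    bop = tt.make_design("bop_pp")
    assert bop.suspend_accrual and not bop.tte_efficacy
    joint = tt.make_design("top_joint")
    assert joint.schedule.tox_looks[-1] == 81 and joint.phi_tox == 0.30
    assert joint.ignore_met and joint.max_enroll == 81
    assert joint.tox_prior.mean == pytest.approx(0.30)
    itop = tt.make_design("itop_joint")
    assert itop.informative_tox_prior and itop.max_enroll == 90
    with pytest.raises(ValueError, match="unknown design kind"):
        tt.make_design("bop3")


def test_design_dict_roundtrip():
    for kind in tt.DESIGN_KINDS:
        design = tt.make_design(kind)
        assert tt.DesignSpec.from_dict(design.to_dict()) == design


def test_look_schedule_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        tt.LookSchedule(eff_looks=(30, 30, 81))
    with pytest.raises(ValueError, match="n_eff"):
        tt.LookSchedule(eff_looks=(30, 60), n_eff=81)
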