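import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrforge.estimators import (LambdaSeries, ThermoContext, ToyPotential,
                                 WorkProfileSet, gaussian_ji_truth,
                                 guided_free_energy, ji_cumulant, ji_direct,
                                 pmf_from_work, steered_toy_simulate,
                                 ti_integrate)
from tcrforge.fixtures import make_lambda_series, make_work_ensemble

CTX = ThermoContext(300.0)


# ---------------------------------------------------------------------------
# Thermodynamic integration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("scheme", ["linear", "quadratic", "pow34"])
def test_ti_exact_for_constant_integrand(scheme):
    series, truth = make_lambda_series("constant", (5.0,))
    dg, _err = ti_integrate(series, scheme)
    assert dg == pytest.approx(5.0, abs=1e-12)


@pytest.mark.parametrize("scheme", ["linear", "quadratic"])
def test_ti_exact_for_linear_integrand(scheme):
    series, truth = make_lambda_series("linear", (0.0, 2.0))
    dg, _err = ti_integrate(series, scheme)
    assert dg == pytest.approx(1.0, abs=1e-12)


def test_ti_pow34_recovers_singular_integral():
    """The integrand lambda^(-3/4) integrates to exactly 4 on (0,1); the
    pow34 endpoint scheme recovers it within 2% on the 11-point grid."""
    series, truth = make_lambda_series("pow-34")
    dg, err = ti_integrate(series, "pow34")
    assert truth["truth"] == 4.0
    assert abs(dg - 4.0) / 4.0 < 0.02


@settings(deadline=None, derandomize=True, max_examples=25)
@given(a=st.floats(-5, 5), b=st.floats(-5, 5))
def test_ti_linear_scheme_exact_for_degree_one(a, b):
    series, truth = make_lambda_series("linear", (a, b))
    dg, _ = ti_integrate(series, "linear")
    assert dg == pytest.approx(truth["truth"], abs=1e-9)


def test_ti_input_validation():
    with pytest.raises(ValueError):
        ti_integrate(LambdaSeries([0.5], [1.0]))      # single point
    with pytest.raises(ValueError):
        LambdaSeries([0.0, 0.5], [1.0, 1.0])          # lambda at boundary
    with pytest.raises(ValueError):
        LambdaSeries([0.5, 0.3], [1.0, 1.0])          # not increasing
    series, _ = make_lambda_series("constant", (1.0,))
    with pytest.raises(ValueError):
        ti_integrate(series, "simpson")


def test_ti_scheme_spread_shrinks_with_refinement():
    fine = np.linspace(0.01, 0.99, 49)
    coarse = np.linspace(0.05, 0.95, 7)
    f = lambda lam: 3.0 * lam ** 2 + 1.0
    spread = []
    for grid in (coarse, fine):
        vals = [ti_integrate(LambdaSeries(grid, f(grid)), s)[0]
                for s in ("linear", "quadratic", "pow34")]
        spread.append(np.ptp(vals))
    assert spread[1] < spread[0]


# ---------------------------------------------------------------------------
# Jarzynski estimators
# ---------------------------------------------------------------------------

def test_ji_direct_degenerate_distribution():
    assert ji_direct(np.full(50, 12.3), CTX) == pytest.approx(12.3)


def test_ji_direct_two_value_closed_form():
    beta = CTX.beta_kj
    w = np.array([0.0, 1000.0])
    expected = -np.log((1 + np.exp(-beta * 1000.0)) / 2) / beta
    assert ji_direct(w, CTX) == pytest.approx(expected, abs=1e-9)
    assert 0.0 < ji_direct(w, CTX) < np.log(2) / beta + 1e-9


def test_ji_direct_overflow_safe_for_large_beta_w():
    w = np.array([-2.5e4, 2.5e4])   # |beta W| ~ 1e4
    val = ji_direct(w, CTX)
    assert np.isfinite(val)
    assert val == pytest.approx(-2.5e4 + np.log(2) / CTX.beta_kj, rel=1e-6)


def test_ji_gaussian_consistency():
    """On 1e5 Gaussian work values both estimators agree with the
    closed form mu - beta sigma^2/2 within 3 standard errors."""
    mu, sigma, n = 20.0, 5.0, 100_000
    wps, truth = make_work_ensemble("gaussian", {"mu": mu, "sigma": sigma},
                                    n=n, seed=11, context=CTX)
    w = wps.endpoint_work
    beta = CTX.beta_kj
    target = gaussian_ji_truth(mu, sigma, CTX)
    assert truth["dg_true"] == pytest.approx(target)
    x = np.exp(-beta * (w - w.min()))
    se_direct = x.std() / (x.mean() * beta * np.sqrt(n))
    assert abs(ji_direct(w, CTX) - target) < 3 * se_direct
    se_cum = (sigma / np.sqrt(n)) * (1 + beta * sigma)
    assert abs(ji_cumulant(w, CTX) - target) < 3 * se_cum
    assert abs(ji_direct(w, CTX) - ji_cumulant(w, CTX)) < \
        3 * np.hypot(se_direct, se_cum)


def test_ji_cumulant_is_definitional():
    rng = np.random.default_rng(2)
    w = rng.normal(30, 8, 500)
    expected = w.mean() - 0.5 * CTX.beta_kj * w.var(ddof=1)
    assert ji_cumulant(w, CTX) == pytest.approx(expected, abs=1e-12)
    assert ji_cumulant(np.full(10, 7.0), CTX) == pytest.approx(7.0)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(st.floats(-50, 50), min_size=1, max_size=40))
def test_ji_direct_never_exceeds_mean_work(work):
    """Jensen bound: the exponential average is always <= the mean work."""
    w = np.asarray(work)
    assert ji_direct(w, CTX) <= w.mean() + 1e-9


def test_ji_input_validation():
    with pytest.raises(ValueError):
        ji_direct(np.array([]), CTX)
    with pytest.raises(ValueError):
        ji_cumulant(np.array([1.0]), CTX)
    with pytest.raises(ValueError):
        ThermoContext(-1.0)


# ---------------------------------------------------------------------------
# PMF from work profiles
# ---------------------------------------------------------------------------

def test_pmf_flat_potential_is_flat_within_noise():
    wps = steered_toy_simulate(ToyPotential("flat"), k_guide=200.0, speed=0.2,
                               n_traj=120, n_steps=20000, dt=1e-4, seed=1,
                               context=CTX)
    prof = pmf_from_work(wps, "cumulant", CTX)
    w = wps.endpoint_work
    assert abs(w.mean()) < 3 * w.std() / np.sqrt(len(w))
    assert np.abs(prof.g).max() < 0.5


def test_pmf_harmonic_quasi_static_matches_analytic_well():
    pot = ToyPotential("harmonic", (20.0, 0.0))
    wps = steered_toy_simulate(pot, k_guide=400.0, speed=0.2, n_traj=150,
                               n_steps=50000, dt=5e-5, seed=2, context=CTX)
    prof = pmf_from_work(wps, "cumulant", CTX)
    truth = guided_free_energy(pot, 400.0, wps.xi, CTX)
    truth = truth - truth[0]
    assert np.abs(prof.g - truth).max() < 0.3
    # and close to the bare 1/2 k xi^2 parabola for a stiff guide
    assert prof.g[-1] == pytest.approx(0.5 * 20.0 * wps.xi[-1] ** 2, rel=0.15)


def test_pmf_requires_two_trajectories_for_cumulant():
    wps = WorkProfileSet(np.linspace(0, 1, 5), np.zeros((1, 5)))
    with pytest.raises(ValueError, match="2 trajectories"):
        pmf_from_work(wps, "cumulant", CTX)


def test_work_profile_validation():
    with pytest.raises(ValueError, match="start at 0"):
        WorkProfileSet(np.linspace(0, 1, 3), np.array([[1.0, 2.0, 3.0]]))
    with pytest.raises(ValueError, match="mismatch"):
        WorkProfileSet(np.linspace(0, 1, 3), np.zeros((2, 4)))


# ---------------------------------------------------------------------------
# Toy simulator
# ---------------------------------------------------------------------------

def test_simulator_bit_reproducible():
    a = steered_toy_simulate(ToyPotential("flat"), seed=5, n_traj=8,
                             n_steps=500)
    b = steered_toy_simulate(ToyPotential("flat"), seed=5, n_traj=8,
                             n_steps=500)
    assert np.array_equal(a.work, b.work)
    assert np.array_equal(a.xi, b.xi)


def test_simulator_second_law_dissipation():
    wps = steered_toy_simulate(ToyPotential("flat"), k_guide=200.0, speed=5.0,
                               n_traj=100, n_steps=4000, dt=1e-4, seed=3,
                               context=CTX)
    w = wps.endpoint_work
    assert w.mean() > 3 * w.std() / np.sqrt(len(w))


def test_simulator_rejects_unstable_timestep():
    with pytest.raises(ValueError, match="unstable"):
        steered_toy_simulate(ToyPotential("flat"), k_guide=1e4, dt=1e-3,
                             friction=1.0, n_traj=2, n_steps=10)


def test_work_starts_at_zero_each_trajectory():
    wps = steered_toy_simulate(ToyPotential("double-well", (10.0, 1.0)),
                               seed=9, n_traj=12, n_steps=1000)
    assert np.all(wps.work[:, 0] == 0.0)
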