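"""Solver correctness: matrix-exponential oracle, conservation, equilibria."""

import numpy as np
import pytest
from scipy.linalg import expm

from trmkin.kinetics import (
    KineticParameters,
    LabelStateVector,
    RecruitmentMode,
    solve_label_trajectories,
    steady_state_ki67_fraction,
)
from trmkin import _fast


def _random_params(rng):
    mode = RecruitmentMode(str(rng.choice([m.value for m in RecruitmentMode])))
    return KineticParameters(
        mu=float(rng.uniform(0.005, 0.1)),
        rho=float(rng.uniform(0.002, 0.05)),
        beta=float(rng.uniform(0.1, 0.5)),
        mode=mode,
        precursor_ki67=float(rng.uniform(0.05, 0.6)) if mode == RecruitmentMode.NEUTRAL else None,
    )


def _random_initial(rng):
    return LabelStateVector.from_marginals(
        yfp=float(rng.uniform(0.05, 0.6)),
        ki67_in_yfp_pos=float(rng.uniform(0.05, 0.8)),
        ki67_in_yfp_neg=float(rng.uniform(0.02, 0.4)),
        mtom=float(rng.uniform(0.1, 0.8)),
    )


def _piecewise(breaks, values):
    """Right-continuous step function on [t0, inf)."""
    breaks = np.asarray(breaks)

    def f(t):
        return values[int(np.searchsorted(breaks, t, side="right")) - 1]

    return f


def _expm_oracle(params, gy_vals, gm_vals, breaks, x0, times):
    """Exact affine solution on each constant piece via a 6x6 augmented expm."""
    mu, rho, beta, delta = params.mu, params.rho, params.beta, params.delta
    h = params.immigrant_ki67()
    x = np.append(x0, 1.0)
    out = {times[0]: x0.copy()}
    t_now = times[0]
    checkpoints = sorted(set(times) | set(b for b in breaks if b > times[0]))
    for t_next in checkpoints:
        if t_next <= t_now:
            continue
        # constant piece(s) between t_now and t_next
        seg = [t_now] + [b for b in breaks if t_now < b < t_next] + [t_next]
        for lo, hi in zip(seg[:-1], seg[1:]):
            i = int(np.searchsorted(breaks, lo, side="right")) - 1
            gy, gm = gy_vals[i], gm_vals[i]
            A = np.array(
                [
                    [rho - (beta + delta), 2 * rho, 0, 0, 0],
                    [beta, -(rho + delta), 0, 0, 0],
                    [0, 0, rho - (beta + delta), 2 * rho, 0],
                    [0, 0, beta, -(rho + delta), 0],
                    [0, 0, 0, 0, -mu],
                ]
            )
            f = mu * np.array(
                [gy * h, gy * (1 - h), (1 - gy) * h, (1 - gy) * (1 - h), gm]
            )
            M = np.zeros((6, 6))
            M[:5, :5] = A
            M[:5, 5] = f
            x = expm(M * (hi - lo)) @ x
        t_now = t_next
        out[t_now] = x[:5].copy()
    return np.array([out[t] for t in times])


@pytest.mark.parametrize("draw", range(20))
def test_solver_matches_matrix_exponential_oracle(draw):
    """Piecewise-constant forcing: adaptive solver agrees with exact expm to 1e-8."""
    rng = np.random.default_rng(1000 + draw)
    params = _random_params(rng)
    initial = _random_initial(rng)
    breaks = [5.0, 15.0, 40.0]
    gy_vals = rng.uniform(0.05, 0.6, size=3)
    gm_vals = rng.uniform(0.05, 0.7, size=3)
    times = np.array([5.0, 9.0, 15.0, 22.0, 40.0, 55.0, 63.0])
    traj = solve_label_trajectories(
        params,
        _piecewise(breaks, gy_vals),
        _piecewise(breaks, gm_vals),
        None,
        initial,
        times,
        t_breaks=breaks,
        rtol=1e-11,
        atol=1e-13,
    )
    expected = _expm_oracle(params, gy_vals, gm_vals, breaks, initial.as_array(), times)
    np.testing.assert_allclose(traj.states, expected, atol=1e-8, rtol=0)
    # conservation of the four YFP x Ki67 fractions at every output time
    np.testing.assert_allclose(traj.states[:, :4].sum(axis=1), 1.0, atol=1e-9, rtol=0)


def test_closed_population_keeps_label_frequencies_constant():
    """With no influx (mu=0), balanced division and loss leave mTom flat."""
    params = KineticParameters(mu=0.0, rho=0.03, beta=0.25, mode=RecruitmentMode.QUIESCENT)
    initial = LabelStateVector.from_marginals(0.3, 0.4, 0.1, mtom=0.37)
    traj = solve_label_trajectories(params, 0.5, 0.5, None, initial, np.linspace(5, 200, 40))
    np.testing.assert_allclose(traj.mtom, 0.37, atol=1e-8)
    # YFP frequency is likewise conserved without influx
    np.testing.assert_allclose(traj.yfp, 0.3, atol=1e-8)


def test_mtom_follows_scalar_exponential_relaxation():
    """Constant precursor g: m(t) = g + (m0 - g) exp(-mu (t - t0))."""
    mu, g, m0 = 0.04, 0.2, 0.6
    params = KineticParameters(mu=mu, rho=0.01, beta=0.3, mode=RecruitmentMode.QUIESCENT)
    initial = LabelStateVector.from_marginals(0.2, 0.3, 0.1, mtom=m0)
    times = np.array([5.0, 30.0, 100.0, 300.0])
    traj = solve_label_trajectories(params, 0.3, g, None, initial, times)
    expected = g + (m0 - g) * np.exp(-mu * (times - 5.0))
    np.testing.assert_allclose(traj.mtom, expected, atol=1e-8)


def test_fast_batch_integrator_matches_reference_solver():
    """The half-day RK4 fitting path tracks the adaptive solver to ~5e-6,
    far below the binomial noise floor of the count data it serves."""
    rng = np.random.default_rng(7)
    K = 8
    mu = rng.uniform(0.005, 0.08, K)
    rho = rng.uniform(0.002, 0.04, K)
    beta = rng.uniform(0.15, 0.5, K)
    h = rng.choice([0.0, 1.0], K)
    aY, bY, cY = rng.normal(-1, 0.5, K), rng.uniform(-1, 1, K), rng.uniform(0.005, 0.05, K)
    aM, bM, cM = rng.normal(-2, 0.5, K), rng.uniform(0.5, 2, K), rng.uniform(0.005, 0.05, K)
    y0, kp0, kn0, m0 = (rng.uniform(0.1, 0.5, K) for _ in range(4))
    x0 = np.column_stack([y0 * kp0, y0 * (1 - kp0), (1 - y0) * kn0, (1 - y0) * (1 - kn0), m0])
    obs_times = np.array([5.0, 12.0, 33.0, 63.0, 150.0, 399.0])
    grid, out_idx = _fast.build_grid(5.0, obs_times)
    states = _fast.integrate_batch(mu, rho, beta, h, aY, bY, cY, aM, bM, cM, x0, grid, out_idx)
    from scipy.special import expit

    for k in range(K):
        params = KineticParameters(
            mu=mu[k], rho=rho[k], beta=beta[k],
            mode=RecruitmentMode.DIVISION_LINKED if h[k] == 1.0 else RecruitmentMode.QUIESCENT,
        )
        traj = solve_label_trajectories(
            params,
            lambda t, k=k: expit(aY[k] + bY[k] * np.exp(-cY[k] * (t - 5.0))),
            lambda t, k=k: expit(aM[k] + bM[k] * np.exp(-cM[k] * (t - 5.0))),
            None,
            LabelStateVector(*x0[k]),
            obs_times,
        )
        np.testing.assert_allclose(states[k], traj.states, atol=5e-6, rtol=0)


def test_solver_converges_to_steady_state_ki67_fraction():
    """Long runs with constant forcing reach the closed-form equilibrium."""
    for mode, h in [
        (RecruitmentMode.QUIESCENT, None),
        (RecruitmentMode.DIVISION_LINKED, None),
        (RecruitmentMode.NEUTRAL, 0.3),
    ]:
        params = KineticParameters(mu=0.05, rho=0.02, beta=0.3, mode=mode, precursor_ki67=h)
        horizon = 5.0 + 25.0 / min(params.mu + params.rho, params.beta)
        initial = LabelStateVector.from_marginals(0.3, 0.6, 0.1, mtom=0.5)
        traj = solve_label_trajectories(
            params, 0.4, 0.3, h, initial, np.array([5.0, horizon])
        )
        k_total = traj.states[-1, 0] + traj.states[-1, 2]
        assert abs(k_total - steady_state_ki67_fraction(params)) < 1e-6


def test_increasing_replacement_accelerates_mtom_relaxation():
    """Larger mu pulls |m(t) - g| toward zero strictly faster."""
    g, m0, t_check = 0.1, 0.6, 60.0
    gaps = []
    for mu in (0.01, 0.02, 0.04, 0.08):
        params = KineticParameters(mu=mu, rho=0.02, beta=0.3, mode=RecruitmentMode.QUIESCENT)
        initial = LabelStateVector.from_marginals(0.2, 0.3, 0.1, mtom=m0)
        traj = solve_label_trajectories(params, 0.3, g, None, initial, np.array([5.0, t_check]))
        gaps.append(abs(traj.mtom[-1] - g))
    assert all(a > b for a, b in zip(gaps[:-1], gaps[1:]))


def test_steady_state_ki67_matches_measured_tissue_frequencies():
    """Reference-rate check: skin ~0.15 (division-linked), LP ~0.07 (quiescent)."""
    k_skin = steady_state_ki67_fraction(
        KineticParameters(mu=0.02, rho=1 / 49, beta=1 / 3, mode=RecruitmentMode.DIVISION_LINKED)
    )
    assert round(k_skin, 2) == 0.15
    assert abs(k_skin - 0.15) / 0.15 < 0.15
    k_lp = steady_state_ki67_fraction(
        KineticParameters(mu=0.055, rho=1 / 63, beta=1 / 3, mode=RecruitmentMode.QUIESCENT)
    )
    assert abs(k_lp - 0.07) / 0.07 < 0.15


def test_no_division_no_ki67hi_source_gives_zero():
    params = KineticParameters(mu=0.03, rho=0.0, beta=0.3, mode=RecruitmentMode.QUIESCENT)
    assert steady_state_ki67_fraction(params) == 0.0


def test_parameter_domain_errors():
    with pytest.raises(ValueError):
        KineticParameters(mu=float("nan"), rho=0.01, beta=0.3)
    with pytest.raises(ValueError):
        KineticParameters(mu=-0.01, rho=0.01, beta=0.3)
    with pytest.raises(ValueError):
        KineticParameters(mu=0.01, rho=0.01, beta=0.0)
    params = KineticParameters(mu=0.01, rho=0.01, beta=0.3)
    initial = LabelStateVector.from_marginals(0.2, 0.3, 0.1, mtom=0.5)
    with pytest.raises(ValueError, match="sorted"):
        solve_label_trajectories(params, 0.3, 0.3, None, initial, [5.0, 20.0, 10.0])
    with pytest.raises(ValueError, match="precursor_ki67"):
        KineticParameters(mu=0.01, rho=0.01, beta=0.3, mode=RecruitmentMode.NEUTRAL).immigrant_ki67()


def test_label_state_vector_enforces_normalisation():
    with pytest.raises(ValueError, match="sum to 1"):
        LabelStateVector(0.5, 0.5, 0.5, 0.5, 0.2)
    with pytest.raises(ValueError, match="out of"):
        LabelStateVector(1.2, -0.2, 0.0, 0.0, 0.2)
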