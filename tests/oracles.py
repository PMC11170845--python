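"""Independent oracles used only by the test-suite.

Each function here re-derives a quantity the package computes analytically
or by approximation, using a slower, conceptually independent route: direct
ODE integration for the infusion model, dense Gauss-Hermite quadrature for
the marginal likelihood, and explicit per-individual loops for PTA counts.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from mgpk.estimation import Design, ModelSpec, _predict, _residual_variance, _typical_params


def ode_concentration(regimen, params, times):
    """One-compartment infusion model solved numerically.

    dA/dt = R(t) - k*A with R(t) the summed infusion rate; C = A/V plus
    baseline.  Tight-tolerance adaptive integration (Radau would be
    overkill; the RHS is mildly discontinuous at infusion boundaries, so
    integration is split at every event edge).
    """
    starts, durs, rates = regimen.arrays()
    edges = np.unique(np.concatenate([starts, starts + durs]))
    k = params.CL / params.V

    def rhs(t, A):
        active = (t >= starts) & (t < starts + durs)
        return [float((rates * active).sum()) - k * A[0]]

    times = np.asarray(times, dtype=float)
    t_end = float(times.max())
    t_eval_all = np.unique(np.concatenate([times, edges[edges <= t_end]]))
    sol_vals = {}
    A = 0.0
    t_prev = 0.0
    checkpoints = np.unique(np.concatenate([edges[(edges > 0) & (edges < t_end)], [t_end]]))
    for t_next in checkpoints:
        seg_times = t_eval_all[(t_eval_all >= t_prev) & (t_eval_all <= t_next)]
        sol = solve_ivp(rhs, (t_prev, t_next), [A], t_eval=seg_times,
                        rtol=1e-10, atol=1e-12, max_step=np.inf)
        for tt, aa in zip(sol.t, sol.y[0]):
            sol_vals[round(float(tt), 12)] = aa
        A = sol.y[0][-1]
        t_prev = t_next
    conc = np.array([sol_vals[round(float(tt), 12)] for tt in times]) / params.V
    return conc + params.baseline


def gauss_hermite_neg2ll(design: Design, spec: ModelSpec, params, n_nodes: int = 60):
    """Exact marginal -2 log-likelihood by dense 2-d Gauss-Hermite quadrature.

    For each subject, integrates p(y | eta) over eta ~ N(0, Omega) with the
    substitution eta = sqrt(2) * omega * z; accurate when the integrand is
    well covered by the node range (small-to-moderate omega).
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    omega = np.sqrt([params["omega2_CL"], params["omega2_V"]])
    z1, z2 = np.meshgrid(nodes, nodes, indexing="ij")
    w = np.outer(weights, weights).ravel() / np.pi
    eta1 = np.sqrt(2.0) * omega[0] * z1.ravel()
    eta2 = np.sqrt(2.0) * omega[1] * z2.ravel()

    CLtyp, Vtyp = _typical_params(design, spec, params)
    total = 0.0
    for i in range(design.n_subjects):
        m = design.mask[i] > 0
        sub = Design(
            ids=design.ids[i : i + 1],
            y=design.y[i : i + 1], mask=design.mask[i : i + 1],
            t=design.t[i : i + 1],
            ev_start=design.ev_start[i : i + 1], ev_dur=design.ev_dur[i : i + 1],
            ev_rate=design.ev_rate[i : i + 1],
            baseline=design.baseline[i : i + 1], cov={},
        )
        # evaluate p(y | eta) on the whole grid at once
        CL = CLtyp[i] * np.exp(eta1)
        V = Vtyp[i] * np.exp(eta2)
        grid = Design(
            ids=np.repeat(sub.ids, CL.size),
            y=np.repeat(sub.y, CL.size, axis=0), mask=np.repeat(sub.mask, CL.size, axis=0),
            t=np.repeat(sub.t, CL.size, axis=0),
            ev_start=np.repeat(sub.ev_start, CL.size, axis=0),
            ev_dur=np.repeat(sub.ev_dur, CL.size, axis=0),
            ev_rate=np.repeat(sub.ev_rate, CL.size, axis=0),
            baseline=np.repeat(sub.baseline, CL.size), cov={},
        )
        f = _predict(grid, CL, V)
        s2 = _residual_variance(spec.residual, params, f)
        r = grid.y - f
        log_lik = -0.5 * ((np.log(2 * np.pi * s2) + r * r / s2) * grid.mask).sum(axis=1)
        lik = np.exp(log_lik)
        marg = float((w * lik).sum())
        total += -2.0 * np.log(marg)
    return total


def brute_force_pta(conc, times, window_mg, check_hours):
    """Per-hour in-window fractions by an explicit double loop."""
    fractions = []
    for h in check_hours:
        col = int(np.argmin(np.abs(np.asarray(times) - h)))
        count = 0
        for i in range(conc.shape[0]):
            if window_mg[0] <= conc[i, col] <= window_mg[1]:
                count += 1
        fractions.append(count / conc.shape[0])
    return np.array(fractions)
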