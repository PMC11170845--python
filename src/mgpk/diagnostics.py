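"""Model diagnostics: goodness-of-fit table, nonparametric bootstrap, VPC.

GOF quantities follow the standard pharmacometric definitions: PRED is the
population prediction (all etas zero), IPRED the prediction at each
subject's empirical-Bayes eta, and CWRES the conditional weighted residual
— the observation-minus-linearized-population-prediction vector whitened by
the FOCE model-implied covariance G Omega G' + Sigma evaluated at the EBE.
Under a correctly specified model CWRES is approximately standard normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .estimation import (
    Design,
    FitResult,
    ModelSpec,
    _predict,
    _residual_variance,
    _typical_params,
    compile_design,
    foce_fit,
)
from .io import EventDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def gof_table(fit: FitResult, dataset: EventDataset) -> pd.DataFrame:
    """Per-observation DV, PRED, IPRED, CWRES and time.

    Subjects whose model-implied covariance is singular get NaN CWRES and a
    log entry rather than an exception.
    """
    spec = fit.spec
    design = compile_design(dataset, spec)
    params = fit.params
    CLtyp, Vtyp = _typical_params(design, spec, params)
    f_pop = _predict(design, CLtyp, Vtyp)

    etas = fit.etas
    CL = CLtyp * np.exp(etas[:, 0])
    V = Vtyp * np.exp(etas[:, 1])
    f_ind, G = _predict(design, CL, V, grad=True)
    s2 = _residual_variance(spec.residual, params,
                            f_ind if spec.residual != "additive" else f_pop)
    omega2 = np.array([params["omega2_CL"], params["omega2_V"]])

    rows = []
    for i in range(design.n_subjects):
        m = design.mask[i] > 0
        n_i = int(m.sum())
        Gi = G[i][m]
        Vi = Gi @ np.diag(omega2) @ Gi.T + np.diag(s2[i][m])
        ri = design.y[i][m] - f_ind[i][m] + Gi @ etas[i]
        try:
            L = np.linalg.cholesky(Vi)
            cwres = solve_triangular(L, ri, lower=True)
        except np.linalg.LinAlgError:
            logger.warning("singular covariance for subject %r; CWRES missing",
                           design.ids[i])
            cwres = np.full(n_i, np.nan)
        for j in range(n_i):
            rows.append(
                {
                    "ID": design.ids[i],
                    "TIME": design.t[i][m][j],
                    "DV": design.y[i][m][j],
                    "PRED": f_pop[i][m][j],
                    "IPRED": f_ind[i][m][j],
                    "CWRES": cwres[j],
                }
            )
    return pd.DataFrame(rows)


def gof_plots(gof: pd.DataFrame, path_prefix) -> list[str]:
    """DV-vs-PRED/IPRED and CWRES-vs-PRED/time scatter panels (PNG).

    The plotted numbers come straight from the GOF table, which is also
    written as CSV by the pipeline so figures are regenerable.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, x, y in (
        (axes[0, 0], "IPRED", "DV"),
        (axes[0, 1], "PRED", "DV"),
    ):
        ax.scatter(gof[x], gof[y], s=12, alpha=0.6)
        lim = [0, max(gof[[x, y]].max()) * 1.05]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(f"{x} (mg/L)")
        ax.set_ylabel(f"{y} (mg/L)")
    for ax, x in ((axes[1, 0], "PRED"), (axes[1, 1], "TIME")):
        ax.scatter(gof[x], gof["CWRES"], s=12, alpha=0.6)
        ax.axhline(0, color="k", lw=1)
        for yline in (-2, 2):
            ax.axhline(yline, color="grey", ls="--", lw=1)
        ax.set_xlabel(x)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    out = f"{path_prefix}_gof.png"
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return [out]


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapSummary:
    table: pd.DataFrame        # index: parameter; median/p2.5/p97.5/se/cv_pct
    n_success: int
    n_requested: int
    replicates: pd.DataFrame   # one row per successful replicate

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def bootstrap(
    dataset: EventDataset,
    spec: ModelSpec,
    B: int = 1000,
    seed: int = 0,
    inits: dict | None = None,
    fit_fn: Callable = None,
) -> BootstrapSummary:
    """Nonparametric bootstrap resampling subjects with replacement.

    Each replicate redraws ``n_subjects`` subjects (all their rows) and
    refits the model; non-convergent replicates are excluded and counted.
    One master seed spawns independent per-replicate substreams, so results
    do not depend on execution order.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    fit_fn = fit_fn or (lambda ds, sp, inits=None: foce_fit(ds, sp, inits=inits))
    ids = list(dataset.subject_ids)
    n = len(ids)
    streams = np.random.SeedSequence(seed).spawn(B)
    rows = []
    n_success = 0
    for b, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        draw = [ids[j] for j in rng.integers(0, n, size=n)]
        ds_b = dataset.subset_subjects(draw, relabel=True)
        try:
            fit_b = fit_fn(ds_b, spec, inits=inits)
        except Exception as exc:
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
        if not fit_b.converged:
            logger.warning("bootstrap replicate %d did not converge; excluded", b)
            continue
        n_success += 1
        rows.append({"replicate": b, **fit_b.params})

    if not rows:
        raise RuntimeError("no bootstrap replicate converged")
    reps = pd.DataFrame(rows).set_index("replicate")
    table = pd.DataFrame(
        {
            "median": reps.median(),
            "p2.5": reps.quantile(0.025),
            "p97.5": reps.quantile(0.975),
            "se": reps.std(ddof=1) if len(reps) > 1 else np.nan,
        }
    )
    table["cv_pct"] = 100 * table["se"] / table["median"].abs()
    return BootstrapSummary(table=table, n_success=n_success, n_requested=B,
                            replicates=reps)


# ---------------------------------------------------------------------------
# visual predictive check
# ---------------------------------------------------------------------------


@dataclass
class VPCResult:
    table: pd.DataFrame        # per bin: observed & simulated percentile bands
    fraction_in_band: float    # share of observations inside simulated 2.5-97.5
    n_sim: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def vpc(
    fit: FitResult,
    dataset: EventDataset,
    n_sim: int = 1000,
    seed: int = 0,
    bins: np.ndarray | None = None,
    obs_percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
) -> VPCResult:
    """Visual predictive check at the observed design.

    Simulates ``n_sim`` replicate studies from the fitted model using every
    subject's own covariates, doses and sampling times, then compares
    observed percentiles per time bin with the distribution of the same
    percentiles across simulations (2.5/50/97.5 bands).  Sparse
    nominal-time designs bin naturally on the distinct sampling times;
    pass explicit bin edges otherwise.  Bins left empty are merged into
    their left neighbor.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    spec = fit.spec
    design = compile_design(dataset, spec)
    params = fit.params
    CLtyp, Vtyp = _typical_params(design, spec, params)
    omega2 = np.array([params["omega2_CL"], params["omega2_V"]])
    rng = np.random.default_rng(seed)

    m = design.mask > 0
    t_flat = design.t[m]
    y_flat = design.y[m]
    if bins is None:
        labels_flat = np.round(t_flat, 6)
    else:
        edges = np.asarray(bins, float)
        idx = np.clip(np.digitize(t_flat, edges) - 1, 0, len(edges) - 2)
        labels_flat = edges[idx]
    uniq = np.unique(labels_flat)
    # merge empty-observation bins is implicit (bins defined from data)

    N = design.n_subjects
    sims = np.empty((n_sim, y_flat.size))
    for s in range(n_sim):
        eta = rng.normal(0.0, 1.0, size=(N, 2)) * np.sqrt(omega2)
        CL = CLtyp * np.exp(eta[:, 0])
        V = Vtyp * np.exp(eta[:, 1])
        f = _predict(design, CL, V)
        s2 = _residual_variance(spec.residual, params, f)
        y_sim = f + rng.normal(0.0, 1.0, size=f.shape) * np.sqrt(s2)
        sims[s] = np.clip(y_sim[m], 0.0, None)

    rows = []
    inside = 0
    for lbl in uniq:
        sel = labels_flat == lbl
        obs_vals = y_flat[sel]
        sim_vals = sims[:, sel]
        lo_band, hi_band = np.percentile(sim_vals, [2.5, 97.5])
        inside += int(((obs_vals >= lo_band) & (obs_vals <= hi_band)).sum())
        row = {"bin": lbl, "n_obs": int(sel.sum()),
               "sim_p2.5_pooled": lo_band, "sim_p97.5_pooled": hi_band}
        for q in obs_percentiles:
            row[f"obs_p{q:g}"] = np.percentile(obs_vals, q)
            per_sim = np.percentile(sim_vals, q, axis=1)
            row[f"sim_p{q:g}_lo"] = np.percentile(per_sim, 2.5)
            row[f"sim_p{q:g}_med"] = np.percentile(per_sim, 50.0)
            row[f"sim_p{q:g}_hi"] = np.percentile(per_sim, 97.5)
        rows.append(row)

    return VPCResult(
        table=pd.DataFrame(rows),
        fraction_in_band=inside / y_flat.size,
        n_sim=n_sim,
    )


def vpc_plot(result: VPCResult, path) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = result.table.sort_values("bin")
    fig, ax = plt.subplots(figsize=(7, 5))
    for q, color in ((5, "tab:blue"), (50, "tab:red"), (95, "tab:blue")):
        ax.plot(tab["bin"], tab[f"obs_p{q}"], "o-", color=color, label=f"obs p{q}")
        ax.fill_between(tab["bin"], tab[f"sim_p{q}_lo"], tab[f"sim_p{q}_hi"],
                        color=color, alpha=0.2)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("serum Mg (mg/L)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
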