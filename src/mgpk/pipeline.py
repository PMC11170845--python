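"""End-to-end analysis pipeline: data -> base fit -> SCM -> final fit ->
bootstrap -> GOF/VPC -> Monte Carlo PTA -> recommendation.

Every stage writes its outputs (CSV/JSON) under the run directory and all
randomness flows from the seeds declared in the configuration, so a rerun
with the same config is numerically identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import diagnostics, dosing_sim, scm, synthetic_data
from .covariate_model import OmegaMatrix, ThetaVector
from .estimation import ModelSpec, foce_fit
from .io import read_dataset, write_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: dict, outdir) -> dict:
    """Run all configured stages; returns a report dict (also written as
    ``report.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("mgpk")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    report: dict = {}

    try:
        stage = "data"
        data_cfg = config["data"]
        if data_cfg.get("path"):
            dataset = read_dataset(data_cfg["path"], dv_unit=data_cfg["dv_unit"])
            logger.info("read dataset from %s", data_cfg["path"])
        else:
            design = synthetic_data.StudyDesign(n_subjects=data_cfg["n_subjects"])
            dataset, truth = synthetic_data.generate_study(
                seed=config["seeds"]["data"], design=design
            )
            write_dataset(dataset, outdir / "simulated_data.csv")
            with open(outdir / "truth.json", "w") as fh:
                json.dump(
                    {"params": truth["params"], "etas": truth["etas"], "seed": truth["seed"]},
                    fh, indent=2, default=_json_default,
                )
            logger.info("simulated study with %d subjects", dataset.n_subjects)
        dataset.validate()
        report["n_subjects"] = int(dataset.n_subjects)
        report["n_obs"] = int(dataset.n_obs)

        stage = "base_fit"
        mcfg = config["model"]
        base_spec = ModelSpec(effects=(), residual=mcfg["residual"],
                              baseline=mcfg["baseline"])
        est_opts = {"maxfev": config["estimation"]["maxfev"]}
        base_fit = foce_fit(dataset, base_spec, options=est_opts)
        base_fit.parameter_table().to_csv(outdir / "base_fit.csv", index=False)
        report["base_fit"] = base_fit.to_dict()

        stage = "scm"
        if config["scm"]["run"]:
            cov_tab = dataset.covariate_table()
            refs = {c: float(cov_tab[c].median())
                    for c in config["scm"]["continuous"] if c in cov_tab}
            candidates = scm.default_candidates(
                continuous_refs=refs,
                continuous=[c for c in config["scm"]["continuous"] if c in cov_tab],
                categorical=[c for c in config["scm"]["categorical"] if c in cov_tab],
            )
            fit_fn = lambda ds, sp, inits=None: foce_fit(ds, sp, inits=inits, options=est_opts)
            trace = scm.run_scm(
                dataset, base_spec, candidates,
                forward_alpha=config["scm"]["forward_alpha"],
                backward_alpha=config["scm"]["backward_alpha"],
                fit_fn=fit_fn, base_fit=base_fit,
            )
            trace.to_csv(outdir / "scm_trace.csv")
            final_spec = trace.final_spec
            report["scm_selected"] = [e.name for e in final_spec.effects]
        else:
            final_spec = base_spec
            report["scm_selected"] = []

        stage = "final_fit"
        final_fit = foce_fit(dataset, final_spec, options=est_opts,
                             compute_se=config["estimation"]["compute_se"])
        final_fit.parameter_table().to_csv(outdir / "final_fit.csv", index=False)
        final_fit.eta_table().to_csv(outdir / "etas.csv", index=False)
        report["final_fit"] = final_fit.to_dict()

        stage = "bootstrap"
        if config["bootstrap"]["run"]:
            bs = diagnostics.bootstrap(
                dataset, final_spec, B=config["bootstrap"]["B"],
                seed=config["seeds"]["bootstrap"], inits=final_fit.params,
            )
            bs.to_csv(outdir / "bootstrap.csv")
            report["bootstrap_n_success"] = bs.n_success

        stage = "gof"
        gof = diagnostics.gof_table(final_fit, dataset)
        gof.to_csv(outdir / "gof.csv", index=False)
        report["cwres_within_2"] = float((gof["CWRES"].abs() <= 2).mean())
        if config.get("plots"):
            diagnostics.gof_plots(gof, str(outdir / "final"))

        stage = "vpc"
        if config["vpc"]["run"]:
            v = diagnostics.vpc(final_fit, dataset, n_sim=config["vpc"]["n_sim"],
                                seed=config["seeds"]["vpc"])
            v.to_csv(outdir / "vpc.csv")
            report["vpc_fraction_in_band"] = v.fraction_in_band
            if config.get("plots"):
                diagnostics.vpc_plot(v, outdir / "vpc.png")

        stage = "pta"
        if config["pta"]["run"]:
            p = final_fit.params
            theta = ThetaVector(
                tvCL=p["tvCL"], tvV=p["tvV"],
                dCLdCCR=p.get("dCLdCCR", 0.0), dCLdBMI=p.get("dCLdBMI", 0.0),
                dCLdfurosemide=p.get("dCLdfurosemide", 0.0),
                dVdfurosemide=p.get("dVdfurosemide", 0.0),
                ref_CCR=next((e.reference for e in final_spec.effects
                              if e.name == "dCLdCCR"), config["model"]["ref_CCR"]),
                ref_BMI=next((e.reference for e in final_spec.effects
                              if e.name == "dCLdBMI"), config["model"]["ref_BMI"]),
            )
            omega = OmegaMatrix(p["omega2_CL"], p["omega2_V"])
            regimens = None
            if config["pta"].get("regimens"):
                from .pk_core import Regimen

                regimens = {
                    name: Regimen.from_grams(
                        [(d["start"], d["grams"], d["duration_h"]) for d in doses]
                    )
                    for name, doses in config["pta"]["regimens"].items()
                }
            grid = dosing_sim.run_grid(
                theta, omega, regimens=regimens,
                n=config["pta"]["n"], seed=config["seeds"]["pta"],
                ccr_levels=config["pta"]["ccr_levels"],
                bmi_levels=config["pta"]["bmi_levels"],
                window_mmol=tuple(config["pta"]["window_mmol"]),
            )
            grid.to_csv(outdir / "pta.csv", index=False)
            rec = dosing_sim.recommend(grid, regimens=regimens)
            with open(outdir / "recommendation.json", "w") as fh:
                json.dump(rec, fh, indent=2, default=_json_default)
            report["recommendation"] = rec
    except Exception as exc:
        logger.exception("pipeline failed in stage %s", stage)
        raise PipelineError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report
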