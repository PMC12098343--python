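"""End-to-end pipeline driver: data -> SBM -> Malmquist -> Tobit -> summaries.

A single YAML config describes the run::

    output_dir: out/
    seed: 1
    synthetic: {n_units: 41, T: 6}         # or instead:
    # input: {path: panel.csv, schema: {unit: city, period: year,
    #          inputs: [...], outputs: [...], bads: [...],
    #          covariates: [...], group: province}}
    # indicators: true                      # input holds raw city records
    dea: {rts: CRS, frontier_scope: contemporaneous, super: true}
    decompose: true
    malmquist: {enabled: true, bad_mode: as_input}
    tobit: {enabled: true, model: re, quad_nodes: 12, censor_lower: 0.0}

Artifacts are CSVs in ``output_dir`` plus a YAML run log recording the
seed, options, solver statuses and infeasibility counts.  Reruns with an
identical config produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from . import malmquist as mq
from . import report, sbm, tobit
from .panel import PanelSchema, build_indicators, read_panel, write_table
from .synthetic import SyntheticConfig, generate_panel

__all__ = ["run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def _load_data(cfg: dict):
    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"] or {})
        syn.setdefault("seed", cfg.get("seed", 0))
        data, truth = generate_panel(SyntheticConfig(**syn))
        return data, truth
    if "input" not in cfg:
        raise ValueError("config needs a 'synthetic' or 'input' block")
    inp = cfg["input"]
    path = Path(inp["path"])
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if cfg.get("indicators"):
        raw = pd.read_csv(path)
        return build_indicators(raw, group_col=inp.get("group")), None
    schema = PanelSchema.from_mapping(inp.get("schema", {}))
    return read_panel(path, schema), None


def run_pipeline(config_path) -> Path:
    """Execute the full analysis described by a YAML config.

    Returns the artifact directory.  Any stage error aborts with the stage
    name; no partial file is left unlabeled (the run log records which
    stages completed).
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    out_dir = Path(cfg.get("output_dir", "healtheff_out"))
    log: dict = {"seed": cfg.get("seed"), "config": cfg, "stages": [],
                 "statuses": {}, "infeasible": {}}

    stage = "load"
    try:
        data, truth = _load_data(cfg)
        log["stages"].append(stage)

        out_dir.mkdir(parents=True, exist_ok=True)
        opts = sbm.DEAOptions(**(cfg.get("dea") or {}))

        stage = "efficiency"
        eff = sbm.efficiency_table(data, opts)
        write_table(eff, out_dir / "efficiency.csv")
        log["statuses"]["efficiency"] = eff["status"].value_counts().to_dict()
        log["infeasible"]["efficiency"] = int((eff["status"] == "infeasible").sum())
        log["stages"].append(stage)

        if cfg.get("decompose", True):
            stage = "decompose"
            dec = sbm.decompose_scale(data, opts)
            write_table(dec, out_dir / "decomposition.csv")
            log["infeasible"]["decompose"] = int((dec["status"] != "optimal").sum())
            log["stages"].append(stage)
        else:
            dec = None

        mcfg = cfg.get("malmquist") or {}
        if mcfg.get("enabled", True) and data.n_periods >= 2:
            stage = "malmquist"
            mtab = mq.malmquist_table(data, bad_mode=mcfg.get("bad_mode", "as_input"))
            write_table(mtab, out_dir / "malmquist.csv")
            write_table(mq.malmquist_summary(mtab, by="unit"),
                        out_dir / "malmquist_by_unit.csv")
            grouping = data.group_map() if data.has_group else None
            write_table(mq.malmquist_summary(mtab, grouping=grouping, by="period"),
                        out_dir / "malmquist_by_period.csv")
            log["infeasible"]["malmquist"] = int(mtab["n_infeasible"].sum())
            log["stages"].append(stage)

        tcfg = cfg.get("tobit") or {}
        if tcfg.get("enabled", True) and data.p > 0:
            stage = "tobit"
            joined = eff.merge(
                data.frame[["unit", "period", *data.covariates]],
                on=["unit", "period"], validate="one_to_one")
            censor = tobit.CensorSpec(lower=tcfg.get("censor_lower", 0.0),
                                      upper=tcfg.get("censor_upper", float("inf")))
            X = joined[list(data.covariates)]
            if tcfg.get("model", "re") == "re":
                fit = tobit.fit_tobit_re(joined["score"].to_numpy(), X,
                                         joined["unit"].to_numpy(), censor,
                                         quad_nodes=int(tcfg.get("quad_nodes", 12)))
            else:
                fit = tobit.fit_tobit_pooled(joined["score"].to_numpy(), X, censor)
            table8 = fit.summary_frame()
            extra = pd.DataFrame({
                "variable": [f"wald_chi2({fit.wald_df})", "wald_p",
                             "sigma_u", "sigma_e", "log_likelihood"],
                "coefficient": [fit.wald_chi2, fit.wald_p, fit.sigma_u,
                                fit.sigma_e, fit.loglik],
            })
            write_table(pd.concat([table8, extra], ignore_index=True),
                        out_dir / "tobit.csv")
            log["statuses"]["tobit"] = {"converged": bool(fit.converged),
                                        "n_censored": int(fit.n_censored)}
            log["stages"].append(stage)

        stage = "summaries"
        write_table(report.city_averages_and_ranks(eff),
                    out_dir / "city_means_ranks.csv")
        if data.has_group:
            write_table(report.group_means(eff, data.group_map(),
                                           decomposed=dec),
                        out_dir / "group_means.csv")
        log["stages"].append(stage)

        if truth is not None:
            stage = "truth"
            tr = truth.true_efficiency.reset_index(names="unit")
            write_table(tr, out_dir / "true_efficiency.csv")
            log["stages"].append(stage)
    except Exception as err:
        raise PipelineError(stage, err) from err

    with open(out_dir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return out_dir
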