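"""End-to-end pipeline: simulate -> QC -> fluxes -> hot moments -> budgets
-> coherence, with a manifest for bit-identical re-runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__, budgets, hotmoments, io, qaqc, wavelet
from .fluxfit import FitConfig, estimate_fluxes
from .synthetic import CampaignConfig, TrueFluxModel, generate_campaign


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    simulate: bool = True
    campaign: CampaignConfig = field(default_factory=CampaignConfig)
    model: Optional[TrueFluxModel] = None
    deployments_path: Optional[str] = None
    sensors_path: Optional[str] = None
    nee_path: Optional[str] = None
    fit: FitConfig = field(default_factory=FitConfig)
    qc_rules: qaqc.QCRules = field(default_factory=qaqc.QCRules)
    run_qaqc: bool = True
    hot: hotmoments.HotMomentConfig = field(default_factory=hotmoments.HotMomentConfig)
    gwp: budgets.GWPConfig = field(default_factory=budgets.GWPConfig)
    run_coherence: bool = False
    coherence_cfg: wavelet.WaveletConfig = field(
        default_factory=lambda: wavelet.WaveletConfig(n_sims=200)
    )
    utc_offset_hours: float = 0.0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_echo(cfg) -> Dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return convert(cfg)


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Run every enabled stage and write CSV outputs plus a manifest.

    Returns the in-memory result bundle (frames keyed by stage).  Stage
    failures propagate with the stage name attached; outputs written
    before the failure are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: Dict = {}
    manifest: Dict = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config": _config_echo(cfg),
        "inputs": {},
        "outputs": {},
    }

    stage = "simulate"
    try:
        if cfg.simulate:
            campaign = dataclasses.replace(cfg.campaign, seed=cfg.seed)
            deployments, sensors, vegetation, nee, truth = generate_campaign(
                campaign, cfg.model
            )
            bundle["truth"] = truth
        else:
            deployments = io.read_deployments_csv(cfg.deployments_path)
            manifest["inputs"]["deployments"] = _sha256(Path(cfg.deployments_path))
            sensors = io.read_sensors_csv(cfg.sensors_path) if cfg.sensors_path else None
            nee = io.read_nee_csv(cfg.nee_path) if cfg.nee_path else None
            vegetation = None

        stage = "qaqc"
        if cfg.run_qaqc:
            kept, qc_summary = qaqc.filter_deployments(deployments, cfg.qc_rules)
        else:
            kept, qc_summary = list(deployments), qaqc.QCSummary(
                n_input=len({d.deployment_id for d in deployments})
            )

        stage = "fluxes"
        fluxes, rejected = estimate_fluxes(kept, cfg.fit)
        if cfg.run_qaqc:
            _, qc_summary = qaqc.filter_deployments(
                deployments, cfg.qc_rules, rejected_by_fitting=rejected
            )
        fluxes = fluxes[~fluxes["deployment_id"].isin({r[0] for r in rejected})]
        fluxes = fluxes.copy()
        fluxes["site_year"] = budgets.assign_site_year(fluxes["timestamp"])
        bundle["fluxes"] = fluxes
        bundle["qc_summary"] = qc_summary
        io.write_fluxes_csv(fluxes, out / "fluxes.csv")
        qaqc.summarize_qc(qc_summary).to_csv(out / "qc_report.csv", index=False)

        stage = "hotmoments"
        hot_table = hotmoments.hot_moment_table(fluxes, gas="n2o", cfg=cfg.hot)
        bundle["hot_moments"] = hot_table
        hot_table.to_csv(out / "hot_moments.csv", index=False)

        stage = "budget"
        daily = budgets.daily_composite(fluxes)
        annual = budgets.annualize(daily)
        budget = budgets.annual_budget_table(annual, nee, cfg.gwp) if nee is not None else annual
        bundle["daily"] = daily
        bundle["annual"] = annual
        bundle["budget"] = budget
        daily.to_csv(out / "daily_fluxes.csv", index=False)
        budget.to_csv(out / "annual_budget.csv", index=False)

        stage = "coherence"
        if cfg.run_coherence and sensors is not None:
            n2o_daily = (
                daily[daily["gas"] == "n2o"].set_index("date")["mean"].asfreq("D")
            )
            moist = sensors[
                (sensors["variable"] == "moisture") & (sensors["depth_cm"] == 10.0)
            ]
            moist_daily = (
                moist.set_index("timestamp")["value"].resample("D").mean()
            )
            joined = pd.concat(
                {"n2o": n2o_daily, "moisture": moist_daily}, axis=1, join="inner"
            )
            x, _, _ = wavelet.preprocess(joined["n2o"].to_numpy(), cfg.coherence_cfg)
            y, _, _ = wavelet.preprocess(joined["moisture"].to_numpy(), cfg.coherence_cfg)
            coh_cfg = dataclasses.replace(cfg.coherence_cfg, seed=cfg.seed)
            result = wavelet.significance(x, y, coh_cfg)
            bundle["coherence"] = result
            long = pd.DataFrame(
                {
                    "time": np.tile(result.time, result.period.size),
                    "period": np.repeat(result.period, result.time.size),
                    "coherence": result.coherence.ravel(),
                    "phase": result.phase.ravel(),
                    "p_value": result.p_value.ravel(),
                    "significant": result.significant.ravel(),
                }
            )
            long.to_csv(out / "coherence.csv", index=False)
    except Exception as err:  # pragma: no cover - re-raise with stage context
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    for p in sorted(out.glob("*.csv")):
        manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    bundle["manifest"] = manifest
    return bundle
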