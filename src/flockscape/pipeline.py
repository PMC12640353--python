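"""End-to-end orchestration of the analysis stages on simulated data.

``run_pipeline`` executes, in order: simulation, QC, demographic risk
scoring, diversity/ROH, temporal Fst per breed, QTL enrichment of the
top-Fst SNPs, climate correlation, and (when an introgression plan is
configured) ancestry summarisation.  Every stage writes tab-separated
artifacts under the output directory and is recorded in a manifest with
parameters, seed and content hashes, so identical config + seed gives
identical manifest hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, climate, demography, differentiation, diversity, qc
from .genio import write_ped_map
from .sim import (CensusPlan, ClimatePlan, IntrogressionPlan, RohPlan,
                  SimConfig, simulate_ancestry_dosage, simulate_census,
                  simulate_climate, simulate_features, simulate_panel)
from .introgression import ancestry_summary, call_high_introgression

__all__ = ["load_config", "run_pipeline", "PipelineError"]

_PLAN_TYPES = {"introgression": IntrogressionPlan, "roh_plan": RohPlan,
               "climate_plan": ClimatePlan, "census_plan": CensusPlan}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _build(cls, block: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {name}: {sorted(unknown)}")
    return cls(**block)


def load_config(source) -> dict:
    """Load and validate a YAML run config (path, mapping, or YAML text).

    Recognised top-level blocks: ``sim`` (SimConfig fields, with nested
    plan blocks), ``qc`` (QcParams fields), ``roh`` (RohParams fields),
    ``seed``, ``out``.  Unknown keys are rejected by name.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        raw = yaml.safe_load(text) or {}
    allowed = {"sim", "qc", "roh", "seed", "out"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    sim_block = dict(raw.get("sim", {}))
    for key, cls in _PLAN_TYPES.items():
        if key in sim_block and isinstance(sim_block[key], dict):
            sim_block[key] = _build(cls, sim_block[key], f"sim.{key}")
    sim_block.setdefault("seed", seed)
    cfg = {
        "seed": seed,
        "out": raw.get("out", "flockscape_run"),
        "sim": _build(SimConfig, sim_block, "sim"),
        "qc": _build(qc.QcParams, dict(raw.get("qc", {})), "qc"),
        "roh": _build(diversity.RohParams, dict(raw.get("roh", {})), "roh"),
    }
    return cfg


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, stages: tuple = ("simulate", "qc",
                 "demography", "diversity", "fst", "enrich", "climate",
                 "introgress")) -> dict:
    """Run the requested stages; returns the manifest (also written as
    ``manifest.json`` in the output directory)."""
    out = Path(config["out"])
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg: SimConfig = config["sim"]
    manifest = {"seed": config["seed"],
                "parameters": {
                    "sim": dataclasses.asdict(sim_cfg),
                    "qc": dataclasses.asdict(config["qc"]),
                    "roh": dataclasses.asdict(config["roh"])},
                "artifacts": {}}
    art = manifest["artifacts"]
    state: dict = {}

    def stage(name):
        return name in stages

    try:
        name = "simulate"
        panel, truth = simulate_panel(sim_cfg)
        state["panel"], state["truth"] = panel, truth
        for cohort in ("historical", "current"):
            idx = panel.samples.index[
                panel.samples["cohort"] == cohort].to_numpy()
            ped, mp = write_ped_map(panel.take_samples(idx), out / cohort)
            art[f"{cohort}_ped"] = hashlib.sha256(
                Path(ped).read_bytes()).hexdigest()

        if stage("qc"):
            name = "qc"
            filtered, report = qc.filter_panel(panel, config["qc"])
            art["qc_report"] = _write(report, out / "qc_report.tsv")
            state["filtered"] = filtered

        if stage("demography"):
            name = "demography"
            census = simulate_census(sim_cfg)
            art["census"] = _write(census, out / "census.tsv")
            art["demography"] = _write(
                demography.demography_report(census), out / "demography.tsv")

        if stage("diversity"):
            name = "diversity"
            filtered = state.get("filtered", panel)
            art["het"] = _write(diversity.het_summary(filtered),
                                out / "heterozygosity.tsv")
            segments = diversity.detect_roh(panel, config["roh"])
            art["roh"] = _write(segments, out / "roh_segments.tsv")
            art["froh"] = _write(
                diversity.froh(segments, panel.snp_map,
                               panel.samples["sample_id"].tolist()),
                out / "froh.tsv")

        if stage("fst"):
            name = "fst"
            filtered = state.get("filtered", panel)
            per_breed = {}
            top_sets = {}
            tables = []
            for b in sorted(filtered.samples["breed"].unique()):
                s = filtered.samples
                ga = s.index[(s["breed"] == b)
                             & (s["cohort"] == "historical")].to_numpy()
                gb = s.index[(s["breed"] == b)
                             & (s["cohort"] == "current")].to_numpy()
                if len(ga) < 2 or len(gb) < 2:
                    continue
                comp = differentiation.fst_per_snp(filtered, ga, gb)
                per_breed[b] = comp.set_index("snp_id")["theta"]
                top_sets[b] = differentiation.top_fst_fraction(comp)
                comp.insert(0, "breed", b)
                tables.append(comp)
            fst_table = pd.concat(tables, ignore_index=True)
            art["fst"] = _write(fst_table, out / "fst.tsv")
            state["fst_by_breed"] = pd.DataFrame(per_breed)
            state["top_sets"] = top_sets

        if stage("enrich"):
            name = "enrich"
            filtered = state.get("filtered", panel)
            features = simulate_features(sim_cfg, state["truth"])
            rows = []
            for b, top in state.get("top_sets", {}).items():
                res = annotate.qtl_enrichment(
                    top, filtered.snp_map["snp_id"].tolist(),
                    filtered.snp_map, features)
                res.insert(0, "breed", b)
                rows.append(res)
            if rows:
                art["enrichment"] = _write(pd.concat(rows, ignore_index=True),
                                           out / "qtl_enrichment.tsv")

        if stage("climate"):
            name = "climate"
            clim = simulate_climate(sim_cfg, state["truth"])
            art["climate"] = _write(clim, out / "climate.tsv")
            deltas = climate.breed_climate_delta(clim)
            art["climate_deltas"] = _write(deltas, out / "climate_deltas.tsv")
            if "fst_by_breed" in state and state["fst_by_breed"].shape[1] >= 4:
                scan = climate.fst_climate_scan(
                    state["fst_by_breed"], deltas,
                    top_fst_sets=state.get("top_sets"))
                art["climate_scan"] = _write(scan, out / "climate_scan.tsv")

        if stage("introgress") and sim_cfg.introgression is not None:
            name = "introgress"
            dosage = simulate_ancestry_dosage(sim_cfg, state["truth"])
            summary = ancestry_summary(dosage)
            calls = call_high_introgression(summary, dosage.sources[0])
            per_snp = summary.per_snp_mean.reset_index(names="snp_id")
            per_snp["high_introgression"] = per_snp["snp_id"].isin(set(calls))
            art["introgression"] = _write(per_snp, out / "introgression.tsv")
    except Exception as exc:  # noqa: BLE001 — stage name must reach the user
        raise PipelineError(name, exc) from exc

    manifest["hash"] = hashlib.sha256(
        json.dumps(art, sort_keys=True).encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    return manifest
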