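"""End-to-end orchestration: simulate -> clocks -> CTH -> acceleration -> GBTA -> stats.

A run is driven by a config mapping (YAML or JSON on disk) holding either a
``simulate`` block (synthetic cohort parameters) or an ``inputs`` block
(paths to a sample sheet, per-tissue beta matrices and clock coefficient
tables) — exactly one of the two.  Every stage writes its tables under the
output directory and the run finishes with a JSON manifest recording the
seed, package versions, per-stage derived seeds and a SHA-256 digest of
every output file, so two runs with the same config and seed are
digest-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from csfaging import __version__
from csfaging.acceleration import build_acceleration_table, filter_blood_to_time1
from csfaging.celltypes import estimate_proportions
from csfaging.clocks import compute_dnam_age, load_clock_table
from csfaging.simulate import (
    CohortConfig,
    make_planted_clock,
    read_beta_matrix,
    simulate_beta,
    simulate_cell_mixtures,
    simulate_cohort,
    write_beta_matrix,
    write_sample_sheet,
    write_truth_json,
)
from csfaging.stats import pearson
from csfaging.trajectory import model_search, posterior_qc, profile_groups

__all__ = ["load_config", "validate_config", "run_all", "PipelineError"]

log = logging.getLogger("csfaging.pipeline")

STAGES = ("simulate", "clock", "cth", "accel", "gbta", "stats")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(cfg, dict):
        raise PipelineError(f"config {path} did not parse to a mapping")
    return cfg


def validate_config(cfg: dict) -> None:
    """Check config shape and referenced files before any stage runs."""
    has_sim = "simulate" in cfg
    has_inputs = "inputs" in cfg
    if has_sim == has_inputs:
        raise PipelineError("config must contain exactly one of 'simulate' or 'inputs'")
    if has_inputs:
        inputs = cfg["inputs"]
        paths = [inputs.get("sample_sheet")]
        paths += list(inputs.get("betas", {}).values())
        paths += [c.get("path") for c in inputs.get("clocks", [])]
        for p in paths:
            if p is None or not Path(p).exists():
                raise PipelineError(f"input file missing: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derived_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {stage: int(c.generate_state(1)[0] % (2**31)) for stage, c in zip(STAGES, children)}


def run_all(
    cfg: dict,
    outdir: str | Path,
    seed: int | None = None,
    stages: tuple[str, ...] | None = None,
) -> dict[str, Any]:
    """Execute the pipeline; returns (and writes) the run manifest."""
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    run_stages = stages or tuple(cfg.get("stages", STAGES))
    seeds = _derived_seeds(seed)
    outputs: dict[str, Path] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = path
        log.info("wrote %s", path)

    state: dict[str, Any] = {}
    stage = "setup"
    try:
        stage = "simulate"
        if "simulate" in cfg:
            sim = dict(cfg["simulate"])
            K = int(sim.pop("K", 5))
            decay_rate = float(sim.pop("decay_rate", 0.15))
            n_probes = int(sim.pop("n_probes", 300))
            n_clock_probes = int(sim.pop("n_clock_probes", 100))
            noise_sd = float(sim.pop("noise_sd", 0.005))
            cc = CohortConfig(**sim, seed=seeds["simulate"])
            sheet, truth = simulate_cohort(cc)
            mix = simulate_cell_mixtures(sheet, K=K, decay_rate=decay_rate, n_probes=n_probes, seed=seeds["simulate"])
            planted = make_planted_clock(mix, n_clock_probes=n_clock_probes, seed=seeds["simulate"])
            betas = simulate_beta(sheet, truth, mix, planted, noise_sd=noise_sd, seed=seeds["simulate"])
            emit("sample_sheet", write_sample_sheet(sheet, outdir / "sample_sheet.csv"))
            for tissue in sheet["tissue"].unique():
                cols = sheet.loc[sheet["tissue"] == tissue, "sample_id"]
                emit(f"betas_{tissue}", write_beta_matrix(betas[cols], outdir / f"betas_{tissue}.tsv"))
            emit("truth", write_truth_json(truth, mix, outdir / "truth.json"))
            clocks = {"planted": planted.clock}
            state.update(sheet=sheet, betas={t: betas[sheet.loc[sheet["tissue"] == t, "sample_id"]] for t in sheet["tissue"].unique()}, clocks=clocks)
        else:
            inputs = cfg["inputs"]
            sheet = pd.read_csv(inputs["sample_sheet"])
            betas = {t: read_beta_matrix(p) for t, p in inputs["betas"].items()}
            clocks = {
                c["name"]: load_clock_table(
                    c["path"],
                    name=c["name"],
                    transform=c.get("transform", "identity"),
                    standardize_per_sample=bool(c.get("standardize", False)),
                )
                for c in inputs.get("clocks", [])
            }
            state.update(sheet=sheet, betas=betas, clocks=clocks)

        sheet = filter_blood_to_time1(state["sheet"])
        state["sheet"] = sheet
        all_betas = pd.concat(list(state["betas"].values()), axis=1)
        all_betas = all_betas.loc[:, [s for s in sheet["sample_id"] if s in all_betas.columns]]

        stage = "clock"
        if "clock" in run_stages or "all" in run_stages:
            tables = [
                compute_dnam_age(clock, all_betas, probe_policy="intersect_tissues", tissue_matrices=state["betas"])
                for clock in state["clocks"].values()
            ]
            dnam = pd.concat(tables)
            dnam.to_csv(outdir / "dnam_age.tsv", sep="\t")
            emit("dnam_age", outdir / "dnam_age.tsv")
            state["dnam"] = dnam

        stage = "cth"
        cth_cfg = cfg.get("cth", {"enabled": True})
        if cth_cfg.get("enabled", True) and ("cth" in run_stages or "all" in run_stages):
            props = estimate_proportions(all_betas, K=int(cth_cfg.get("K", 5)), seed=seeds["cth"])
            props.to_table().to_csv(outdir / "cell_proportions.tsv", sep="\t")
            emit("cell_proportions", outdir / "cell_proportions.tsv")
            state["props"] = props

        stage = "accel"
        if "accel" in run_stages or "all" in run_stages:
            covs = state["props"].covariates() if "props" in state else None
            accel = build_acceleration_table(sheet, state["dnam"], covs)
            accel.to_csv(outdir / "acceleration.tsv", sep="\t", index=False)
            emit("acceleration", outdir / "acceleration.tsv")
            state["accel"] = accel

        stage = "gbta"
        gcfg = cfg.get("gbta", {})
        if "gbta" in run_stages or "all" in run_stages:
            clock_name = gcfg.get("clock") or next(iter(state["clocks"]))
            flavor = gcfg.get("flavor", "unadjusted")
            accel = state["accel"]
            panel = (
                accel.query("clock == @clock_name and tissue == 'CSF' and flavor == @flavor")
                .rename(columns={"residual": "value"})[["participant_id", "time_bin", "value"]]
            )
            g_lo, g_hi = gcfg.get("G_range", [1, 5])
            table, best = model_search(
                panel,
                G_range=range(int(g_lo), int(g_hi) + 1),
                order_menu=tuple(gcfg.get("orders", (0, 1, 2))),
                seed=seeds["gbta"],
                n_starts=int(gcfg.get("n_starts", 5)),
            )
            table.to_csv(outdir / "gbta_search.tsv", sep="\t", index=False)
            emit("gbta_search", outdir / "gbta_search.tsv")
            best.posteriors.to_csv(outdir / "gbta_posteriors.tsv", sep="\t")
            emit("gbta_posteriors", outdir / "gbta_posteriors.tsv")
            fit_json = {
                "pi": best.pi.tolist(),
                "coefficients": [c.tolist() for c in best.coefficients],
                "sigma": best.sigma.tolist(),
                "loglik": best.loglik,
                "k": best.n_params,
                "bic": best.bic,
                "bic_obs": best.bic_obs,
                "converged": bool(best.converged),
                "n_groups": int(best.spec.n_groups),
                "order": best.spec.orders if isinstance(best.spec.orders, int) else list(best.spec.orders),
            }
            (outdir / "gbta_fit.json").write_text(json.dumps(fit_json, indent=1, sort_keys=True))
            emit("gbta_fit", outdir / "gbta_fit.json")
            qc = posterior_qc(best, app_min=float(gcfg.get("app_min", 0.7)), occ_min=float(gcfg.get("occ_min", 5.0)))
            qc_json = {"passed": qc.passed, "groups": qc.table.to_dict(orient="records")}
            (outdir / "gbta_qc.json").write_text(json.dumps(qc_json, indent=1, sort_keys=True, default=str))
            emit("gbta_qc", outdir / "gbta_qc.json")
            covars = sheet.drop_duplicates("participant_id").set_index("participant_id")[["age", "sex", "race", "smoking", "bmi", "fisher"]]
            profile = profile_groups(best, covars)
            profile.to_csv(outdir / "gbta_group_profile.tsv", sep="\t", index=False)
            emit("gbta_group_profile", outdir / "gbta_group_profile.tsv")
            state["gbta"] = best

        stage = "stats"
        if "stats" in run_stages or "all" in run_stages:
            dnam = state["dnam"].join(sheet.set_index("sample_id")[["age", "tissue"]], how="inner")
            rows = []
            for (clock_name, tissue), grp in dnam.groupby(["clock", "tissue"]):
                if len(grp) >= 3 and grp["age"].std() > 0:
                    res = pearson(grp["age"], grp["dnam_age"])
                    rows.append({"clock": clock_name, "tissue": tissue, "R": res.r, "p": res.p, "n": res.n})
            pd.DataFrame(rows).to_csv(outdir / "age_correlations.tsv", sep="\t", index=False)
            emit("age_correlations", outdir / "age_correlations.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - error path
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "stage_seeds": seeds,
        "stages_run": list(run_stages),
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in sorted(outputs.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
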