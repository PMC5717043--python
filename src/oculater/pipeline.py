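"""Reproducible pipeline: simulate -> preprocess -> analyze -> fit -> compare.

A run is driven by a single config (YAML file or dict).  Stage seeds are
derived from one master seed by fixed offsets, every output file is
checksummed into a manifest, and rerunning the same config reproduces the
outputs byte for byte.

Config layout (all sections optional except one of simulation/input)::

    simulation:
      experiment: 6          # 1..6 or "exp6"
      n_participants: 2
      theta0: {...}          # optional GenerativeParams overrides
      mu: 0.004347
    input: trials.csv        # alternatively: analyze an existing table
    window: {lo_ms: 100, hi_ms: 450}
    fit: {theta_t: 1.0, n_starts: 10, n_boot: 100, min_trials: 20}
    stats: {alpha: 0.05, m_comparisons: 6}
    seed: 17
    output_dir: out/
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess, stats
from .designs import get_design
from .later import VARIANTS, fit_variant, reciprobit_points
from .model_selection import baseline_reduction, bootstrap_compare
from .simulate import GenerativeParams, default_study_params, simulate_experiment
from .trials import read_trials, write_trials

log = logging.getLogger("oculater")

# fixed offsets deriving stage seeds from the master seed
_SEED_SIM = 1
_SEED_FIT = 2


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if ("simulation" not in cfg) == ("input" not in cfg):
        raise ValueError("config needs exactly one of 'simulation' or 'input'")
    if not isinstance(cfg.get("seed", 0), int):
        raise ValueError("seed must be an integer")
    win = cfg.get("window", {})
    lo, hi = win.get("lo_ms", 100.0), win.get("hi_ms", 450.0)
    if lo >= hi:
        raise ValueError(f"window lo_ms ({lo}) must be < hi_ms ({hi})")
    if "simulation" in cfg:
        get_design(cfg["simulation"].get("experiment", 6))  # raises if unknown
        if cfg["simulation"].get("n_participants", 1) < 1:
            raise ValueError("n_participants must be >= 1")


def _gen_params(sim_cfg: dict) -> GenerativeParams:
    base = default_study_params()
    overrides = {k: v for k, v in sim_cfg.items()
                 if k not in {"experiment", "n_participants"}}
    return dataclasses.replace(base, **overrides) if overrides else base


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config, output_dir=None) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    cfg = load_config(config)
    out = Path(output_dir or cfg.get("output_dir", "oculater_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    written: list[Path] = []
    stage = "setup"
    try:
        # ---- simulate / load ------------------------------------------------
        stage = "simulate"
        if "simulation" in cfg:
            sim = cfg["simulation"]
            design = get_design(sim.get("experiment", 6))
            params = _gen_params(sim)
            df = simulate_experiment(design, params,
                                     int(sim.get("n_participants", 1)),
                                     seed=seed + _SEED_SIM)
            log.info("simulated %d trials (experiment %d, seed %d)",
                     len(df), design.experiment, seed + _SEED_SIM)
        else:
            df = read_trials(cfg["input"])
            log.info("loaded %d trials from %s", len(df), cfg["input"])
        trials_path = out / "trials.csv"
        write_trials(df, trials_path)
        written.append(trials_path)

        # ---- preprocess -----------------------------------------------------
        stage = "preprocess"
        labeled = preprocess.label_previous_trial(df)
        win = cfg.get("window", {})
        kept, report = preprocess.apply_latency_window(
            labeled, win.get("lo_ms", 100.0), win.get("hi_ms", 450.0))
        (out / "exclusion.json").write_text(report.to_json() + "\n")
        written.append(out / "exclusion.json")
        misses = preprocess.classify_misses(labeled)
        (out / "misses.json").write_text(misses.to_json() + "\n")
        written.append(out / "misses.json")

        # ---- condition effects ---------------------------------------------
        stage = "effects"
        table = stats.condition_effects(kept, ["choice_proportion"])
        table.aggregate.to_csv(out / "effects_aggregate.csv", index=False)
        table.per_participant.to_csv(out / "effects_per_participant.csv", index=False)
        written += [out / "effects_aggregate.csv", out / "effects_per_participant.csv"]

        # ---- sequential (N-1) effects --------------------------------------
        stage = "sequential"
        seq = stats.sequential_effects(kept)
        seq.to_csv(out / "sequential.csv", index=False)
        written.append(out / "sequential.csv")

        # ---- LATER fits per participant ------------------------------------
        stage = "fit-later"
        fit_cfg = cfg.get("fit", {})
        theta_t = float(fit_cfg.get("theta_t", 1.0))
        n_starts = int(fit_cfg.get("n_starts", 10))
        min_trials = int(fit_cfg.get("min_trials", 20))
        fits, recip_dir = {}, out / "reciprobit"
        recip_dir.mkdir(exist_ok=True)
        fittable = {}
        for pid, grp in kept.groupby("participant_id", sort=False):
            conds = preprocess.later_conditions(grp)
            conds = {k: v for k, v in conds.items() if v.size >= min_trials}
            if len(conds) < 2:
                log.warning("participant %s: fewer than 2 fittable conditions; "
                            "skipped", pid)
                continue
            fittable[pid] = conds
            fits[pid] = {}
            for variant in VARIANTS:
                f = fit_variant(conds, variant, theta_t_fixed=theta_t,
                                n_starts=n_starts, seed=seed + _SEED_FIT,
                                min_trials=min_trials)
                fits[pid][variant] = f.to_dict()
            for cond, lat in conds.items():
                pts = reciprobit_points(lat)
                pts.to_csv(recip_dir / f"{pid}_{cond}.csv", index=False)
                written.append(recip_dir / f"{pid}_{cond}.csv")
        _dump_json(fits, out / "fits.json")
        written.append(out / "fits.json")

        # ---- bootstrap model comparison ------------------------------------
        stage = "compare"
        n_boot = int(fit_cfg.get("n_boot", 100))
        comparison, reductions = {}, {}
        for pid, conds in fittable.items():
            comp = bootstrap_compare(conds, n_boot=n_boot, theta_t_fixed=theta_t,
                                     seed=seed + _SEED_FIT, n_starts=n_starts,
                                     min_trials=min_trials)
            comparison[pid] = json.loads(comp.to_json())
            t0fit = comp.variant_fits_full_data["vary_theta0"]
            red = {}
            for ctx in ("no_choice", "with_choice"):
                hi, lo = f"{ctx}_high", f"{ctx}_low"
                if hi in t0fit.condition_values and lo in t0fit.condition_values:
                    red[ctx] = baseline_reduction(t0fit, hi, lo)
            reductions[pid] = red
        _dump_json(comparison, out / "comparison.json")
        _dump_json(reductions, out / "baseline_reductions.json")
        written += [out / "comparison.json", out / "baseline_reductions.json"]

        # ---- manifest -------------------------------------------------------
        stage = "manifest"
        cfg_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
        manifest = {
            "config": cfg,
            "config_sha256": cfg_hash,
            "seed": seed,
            "stage_seeds": {"simulate": seed + _SEED_SIM, "fit": seed + _SEED_FIT},
            "output_dir": str(out),
            "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
        }
        _dump_json(manifest, out / "manifest.json")
        return manifest
    except Exception as exc:
        for p in written:  # partial-output cleanup
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc


def make_report(manifest: dict | str | Path) -> str:
    """Markdown summary of one pipeline run."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    out = Path(manifest["output_dir"])
    if not out.exists() or not manifest.get("files"):
        raise FileNotFoundError(f"run directory {out} is missing or empty")
    lines = ["# oculater run report", "",
             f"- config sha256: `{manifest['config_sha256']}`",
             f"- master seed: {manifest['seed']}", ""]

    eff = out / "effects_aggregate.csv"
    if eff.exists():
        lines += ["## Latency difference (low - high reward) by choice proportion", "",
                  pd.read_csv(eff).to_string(index=False), ""]
    seq = out / "sequential.csv"
    if seq.exists():
        lines += ["## Sequential (N-1) effects", "",
                  pd.read_csv(seq).to_string(index=False), ""]

    comp_path = out / "comparison.json"
    if comp_path.exists():
        comp = json.loads(comp_path.read_text())
        lines += ["## LATER variant comparison (bootstrap BIC weights)", ""]
        for pid, c in comp.items():
            lines.append(f"### participant {pid} (top-ranked: {c['best_variant']})")
            for v in VARIANTS:
                lo, hi = c["weights_ci"][v]
                lines.append(f"- {v}: mean weight {c['weights_mean'][v]:.3f} "
                             f"[{lo:.3f}, {hi:.3f}]")
            lines.append("")
        red_path = out / "baseline_reductions.json"
        if red_path.exists():
            red = json.loads(red_path.read_text())
            lines += ["## Baseline-level reduction (low vs high reward, %)", ""]
            for pid, r in red.items():
                parts = ", ".join(f"{k}: {v:.1f}%" for k, v in r.items())
                lines.append(f"- {pid}: {parts}")
            lines.append("")
    else:
        lines += ["## LATER model", "", "_no model fits in this run_", ""]
    return "\n".join(lines)
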