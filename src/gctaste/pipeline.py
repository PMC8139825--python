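"""Orchestrated end-to-end runs: generate -> analyze -> consolidated report.

A run is described by a :class:`RunConfig` (deserializable from YAML): a
generator configuration, per-stage toggles and seeds, and an output
directory.  Stages run in dependency order; a stage failure is recorded in
the report and downstream dependents are skipped.  Identical configuration
and seeds reproduce identical reports (MCMC stages are themselves seeded).
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .datamodel import TASTES, EnsembleDataset, write_dataset
from .synthgen import GeneratorConfig, generate_ensemble
from . import single_unit as su
from .latency import compare_fits
from .decoding import jackknife_classify, cross_condition_classify
from .transitions import transition_pipeline

log = logging.getLogger("gctaste.pipeline")

_STAGES = ("generate", "single_unit", "latency_model", "decode", "transitions")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    generator: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)     # stage -> bool
    seeds: dict = field(default_factory=dict)      # stage -> int
    out_dir: str = "results"
    glm_steps: int = 2000
    glm_burn: int = 1000
    hmm_restarts: int = 5
    hmm_states: int = 4
    sigmoid_steps: int = 800
    sigmoid_burn: int = 600

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    def seed(self, stage: str) -> int:
        return int(self.seeds.get(stage, 0))


def _generator_config(cfg: RunConfig) -> GeneratorConfig:
    g = dict(cfg.generator)
    kind = g.pop("kind", "taste_specific")
    g.setdefault("rng_seed", cfg.seed("generate"))
    if kind == "taste_specific":
        return GeneratorConfig.taste_specific(**g)
    if kind == "null":
        return GeneratorConfig.null(**g)
    raise ValueError(f"unknown generator kind {kind!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the consolidated report dict.

    The report is also written to ``<out_dir>/report.json`` together with a
    human-readable ``summary.txt`` and the generated session container.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seeds": {s: config.seed(s) for s in _STAGES},
        "stages": {},
        "errors": {},
    }
    dataset: EnsembleDataset | None = None
    truth = None

    def stage(name, fn, *deps):
        if not config.enabled(name):
            report["stages"][name] = {"skipped": True}
            log.warning("stage %s disabled", name)
            return None
        for d in deps:
            if d is None:
                report["stages"][name] = {"skipped": True,
                                          "reason": "dependency failed"}
                log.warning("stage %s skipped: missing dependency", name)
                return None
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:  # recorded, not raised: partial report
            log.exception("stage %s failed", name)
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
            return None
        report["stages"][name] = result
        report["stages"][name]["wall_s"] = round(time.time() - t0, 2)
        log.info("stage %s done in %.1fs", name, time.time() - t0)
        return result

    # ---- generate -----------------------------------------------------
    def do_generate():
        nonlocal dataset, truth
        gen_cfg = _generator_config(config)
        dataset, truth = generate_ensemble(gen_cfg)
        write_dataset(dataset, out / "session.h5")
        truth.to_frame().to_csv(out / "truth_trials.csv", index=False)
        return {
            "n_trials": dataset.n_trials,
            "n_units": dataset.n_units,
            "trials_per_taste": int(dataset.n_trials / len(TASTES)),
        }

    gen = stage("generate", do_generate)

    # ---- single-unit stats --------------------------------------------
    def do_single_unit():
        rows = []
        latencies = []
        for u in range(dataset.n_units):
            raster = dataset.rasters[:, u, :]
            resp, t, p = su.taste_responsive(raster, dataset.trial_table)
            spec, _ = su.taste_specific(raster, dataset.trial_table)
            pal = su.palatability_correlation(raster, dataset.trial_table)
            glm = su.laser_impact_glm(
                raster, dataset.trial_table,
                n_burn=config.glm_burn, n_steps=config.glm_steps,
                seed=config.seed("single_unit") + u,
            )
            lat = su.impact_latency(raster, dataset.trial_table)
            if glm.impacted and lat is not None:
                latencies.append(lat)
            kind = su.classify_unit_type(
                float(dataset.unit_table["half_width_ms"].iloc[u])
            )
            rows.append(
                {
                    "unit": u,
                    "type": kind,
                    "responsive": resp,
                    "specific": spec,
                    "palatability": pal.flagged,
                    "impacted": glm.impacted,
                    "impact_latency_ms": lat,
                }
            )
        frac = lambda key: float(np.mean([r[key] for r in rows]))
        return {
            "units": rows,
            "fraction_responsive": frac("responsive"),
            "fraction_specific": frac("specific"),
            "fraction_palatability": frac("palatability"),
            "fraction_impacted": frac("impacted"),
            "impact_latencies_ms": latencies,
        }

    sus = stage("single_unit", do_single_unit, gen)

    # ---- latency model ------------------------------------------------
    def do_latency():
        lats = sus["impact_latencies_ms"]
        if len(lats) < 10:
            return {"skipped": True,
                    "reason": f"only {len(lats)} impact latencies (< 10)"}
        cmp_res = compare_fits(np.asarray(lats), seed=config.seed("latency_model"))
        return {
            "n": len(lats),
            "mixture_means_ms": [float(m) for m in cmp_res.mixture.means_ms],
            "mixture_sds_ms": [float(s) for s in cmp_res.mixture.sds_ms],
            "r2_mixture": cmp_res.r2_mixture,
            "r2_exponential": cmp_res.r2_exponential,
            "error_t": cmp_res.t_statistic,
            "error_p": cmp_res.p_value,
        }

    stage("latency_model", do_latency, gen, sus)

    # ---- decoding -----------------------------------------------------
    def do_decode():
        within_off = jackknife_classify(dataset, "Off")
        within_on = jackknife_classify(dataset, "On")
        cross = cross_condition_classify(dataset, "Off", "On")
        return {
            "within_off_pct": 100 * within_off.overall_accuracy,
            "within_on_pct": 100 * within_on.overall_accuracy,
            "cross_off_to_on_pct": 100 * cross.overall_accuracy,
            "per_taste_off_pct": {
                t: 100 * v for t, v in within_off.per_taste_accuracy.items()
            },
        }

    stage("decode", do_decode, gen)

    # ---- transitions --------------------------------------------------
    def do_transitions():
        ana = transition_pipeline(
            dataset,
            n_states=config.hmm_states,
            restarts=config.hmm_restarts,
            seed=config.seed("transitions"),
            mcmc_kwargs={"n_burn": config.sigmoid_burn,
                         "n_steps": config.sigmoid_steps},
        )
        return {
            "sigmoid_slope_off": ana.sigmoid_off.slope_mean,
            "sigmoid_slope_on": ana.sigmoid_on.slope_mean,
            "sigmoid_slopes_differ": ana.sigmoid_slopes_differ,
            "slope_regression": ana.comparison.regression_slope,
            "slope_regression_p_vs_unity": ana.comparison.p_vs_unity,
            "latency_chi2_p": ana.comparison.latency_p,
            "latency_mean_off_ms": ana.comparison.latency_mean_off,
            "latency_mean_on_ms": ana.comparison.latency_mean_on,
        }

    stage("transitions", do_transitions, gen)

    report["ok"] = not report["errors"]
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)
    with open(out / "summary.txt", "w") as fh:
        fh.write(_summarize(report))
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _summarize(report: dict) -> str:
    lines = [f"gctaste pipeline report (version {report['version']})", ""]
    for name, body in report["stages"].items():
        if body.get("skipped"):
            lines.append(f"[{name}] skipped ({body.get('reason', 'disabled')})")
            continue
        lines.append(f"[{name}] ({body.get('wall_s', '?')} s)")
        for k, v in body.items():
            if k in ("units", "wall_s"):
                continue
            lines.append(f"  {k}: {v}")
    for name, err in report.get("errors", {}).items():
        lines.append(f"[{name}] FAILED: {err}")
    lines.append("")
    return "\n".join(lines)
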