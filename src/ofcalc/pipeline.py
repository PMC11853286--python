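"""End-to-end orchestration: simulate/load -> align -> detect -> classify
-> behavior -> summary statistics.

Configuration is a plain dict (or YAML file) with one input source —
either ``simulate`` (a cell-class map and generator knobs) or ``inputs``
(paths to trace/GPIO/behavior/schedule files) — plus optional
``detection``, ``classification`` and ``behavior`` parameter blocks.  A
run manifest (config hash, master seed, package version, outputs) is
written next to the reports; outputs are byte-identical across reruns
with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import ConditionBehavior, condition_metrics, extract_bouts
from .classify import CellReport, classify_session, session_summary
from .detection import SpikeTrain, detect_session
from .errors import ConfigError, OfcalcError
from .io import (
    align_to_experiment_start,
    read_behavior_csv,
    read_gpio_csv,
    read_trace_csv,
    write_report,
)
from .schedule import ExperimentSchedule
from .stats import chisq_goodness_of_fit, format_p
from .synthetic import generate_session, write_session


@dataclass
class PipelineResult:
    schedule: ExperimentSchedule
    trains: list[SpikeTrain]
    reports: list[CellReport]
    summary: dict
    behavior_off: ConditionBehavior
    behavior_on: ConditionBehavior
    out_dir: Path
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except OfcalcError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return wrapped
    return deco


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    if ("simulate" in config) == ("inputs" in config):
        raise ConfigError("config needs exactly one of 'simulate' or 'inputs'")
    return config


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@_stage("load")
def _load_inputs(config: dict, seed):
    if "simulate" in config:
        sim = dict(config["simulate"])
        classes = sim.pop("n_cells_per_class", None)
        if not classes:
            raise ConfigError("simulate block needs n_cells_per_class")
        session = generate_session(classes, seed=seed, **sim)
        return session.traces, session.gpio, session.behavior, session.schedule, session
    inputs = config["inputs"]
    for key in ("traces", "gpio", "behavior", "schedule"):
        if key not in inputs:
            raise ConfigError(f"inputs block missing {key!r}")
    return (
        read_trace_csv(inputs["traces"]),
        read_gpio_csv(inputs["gpio"]),
        read_behavior_csv(inputs["behavior"]),
        ExperimentSchedule.from_yaml(inputs["schedule"]),
        None,
    )


def run_pipeline(config, out_dir, seed=None) -> PipelineResult:
    """Run every stage and write reports under ``out_dir``.

    ``seed`` (master) drives both simulation and shuffle classification;
    any stage failure is re-raised naming the stage.
    """
    config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)

    traces, gpio, behavior_log, schedule, session = _load_inputs(
        config, np.random.default_rng(master.integers(2**31))
    )
    if session is not None:
        write_session(session, out_dir / "session")

    aligned = _stage("align")(align_to_experiment_start)(
        traces, gpio,
        trigger_channel=config.get("trigger_channel", "trigger"),
        session_length=schedule.session_length,
    )

    det_cfg = config.get("detection", {})
    trains = _stage("detect")(detect_session)(
        aligned,
        baseline_method=det_cfg.get("baseline_method", "full"),
        sd_multiplier=det_cfg.get("sd_multiplier", 2.0),
        min_separation=det_cfg.get("min_separation", 0.25),
        habituation_end=schedule.habituation_duration,
    )

    cls_cfg = config.get("classification", {})
    reports = _stage("classify")(classify_session)(
        trains, schedule,
        n_shuffles=cls_cfg.get("n_shuffles", 1000),
        shift_range=tuple(cls_cfg.get("shift_range", (20.0, 1200.0))),
        seed=np.random.default_rng(master.integers(2**31)),
        conditions=tuple(cls_cfg.get("conditions", ("OFF", "ON"))),
        use_led_windows=cls_cfg.get("use_led_windows", False),
    )
    summary = session_summary(reports)
    if summary["n_src"] > 0:
        chi = chisq_goodness_of_fit(
            (summary["n_suppressed"], summary["n_src"] - summary["n_suppressed"])
        )
        summary["suppression_chi_square"] = {
            "statistic": round(chi.statistic, 3),
            "df": chi.df,
            "p": chi.p,
            "p_formatted": format_p(chi.p),
        }

    beh_cfg = config.get("behavior", {})
    bouts = _stage("behavior")(extract_bouts)(
        behavior_log, min_duration=beh_cfg.get("min_bout_duration", 2.0)
    )
    clip = beh_cfg.get("clip_to_period", False)
    beh = {}
    for cond in ("OFF", "ON"):
        beh[cond] = condition_metrics(
            bouts,
            schedule.condition_period(cond),
            schedule.shock_windows(),
            condition=cond,
            clip_to_period=clip,
        )

    # ---- outputs ----------------------------------------------------------
    write_report(reports, summary, out_dir / "report.tsv", out_dir / "summary.json")
    beh_frame = pd.DataFrame([vars(beh["OFF"]), vars(beh["ON"])])
    beh_frame.to_csv(out_dir / "behavior.tsv", sep="\t", index=False,
                     float_format="%.6g")

    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": None if seed is None else int(seed),
        "ofcalc_version": __version__,
        "outputs": sorted(
            str(p.relative_to(out_dir)) for p in out_dir.rglob("*") if p.is_file()
        ),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")

    return PipelineResult(
        schedule=schedule,
        trains=trains,
        reports=reports,
        summary=summary,
        behavior_off=beh["OFF"],
        behavior_on=beh["ON"],
        out_dir=out_dir,
        manifest=manifest,
    )
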