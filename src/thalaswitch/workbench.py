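"""Experiment configuration, persistence, fixtures and the command line.

The workbench ties the pipeline stages together: a declarative
``ExperimentConfig`` names one of the study's computational experiments,
``run_experiment`` dispatches it to the right module chain and writes result
artifacts (CSV/JSON tables, HDF5 traces) together with the resolved
configuration and seeds, and ``make_fixtures`` generates the small
constructed inputs (toy normal form, labelled spike trains, epoch-tagged
LFP signals) used by the test suite.

Desk-scale mode shrinks sample counts, population sizes and epoch durations
by documented factors while preserving the 1 s classification transients
and the integration step.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import click
import h5py
import numpy as np
import yaml

from . import __version__
from .channel_models import load_builtin, make_restored_variant, scale_cat_tau, timescale_anchors
from .population_network import (
    build_network,
    default_network_protocol,
    heterogeneity_tau_table,
    simulate_network,
)
from .sim_engine import (
    SINGLE_CELL_CLASSIFIER,
    SimulationResult,
    StepProtocol,
    epoch_patterns,
    integrate,
    single_cell_system,
)
from .variability_sampling import (
    TAU_SCREEN_ETAS,
    VariabilitySpec,
    capacitance_scan,
    circuit_switch_screen,
    normalized_log_position,
    tau_scaling_screen,
)

__all__ = ["ExperimentConfig", "run_experiment", "make_fixtures", "cli"]

EXPERIMENTS = ("fig1a", "fig1d", "fig2b", "fig3", "fig4", "fig5", "fig6", "fig7")

#: desk-mode rescaling of the full-size experiments
DESK_SCALE = {
    "n_samples_divisor": 20,  # 1000 -> 50 circuits, 400 -> 20
    "circuit_epoch_ms": 8_000.0,  # instead of 41 s
    "network_epoch_ms": 10_000.0,  # instead of 21 s
    "network_cells": 20,  # per population, instead of 100
}


@dataclass
class ExperimentConfig:
    experiment: str
    model_id: str = "1"
    seed: int = 0
    scale_mode: str = "desk"  # "full" | "desk"
    widths: Optional[Sequence[float]] = None
    etas: Optional[Sequence[float]] = None
    n_samples: Optional[int] = None
    dt: Optional[float] = None

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; valid: {EXPERIMENTS}"
            )
        if self.scale_mode not in ("full", "desk"):
            raise ValueError("scale_mode must be full|desk")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


def _provenance(config: ExperimentConfig) -> dict:
    return {
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "package_version": __version__,
    }


def save_result_hdf5(result: SimulationResult, path) -> None:
    """Persist a SimulationResult (traces + spikes + protocol) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["dt"] = result.dt
        f.attrs["labels"] = json.dumps(result.labels)
        p = result.protocol
        f.attrs["protocol"] = json.dumps(
            {"i_depol": p.i_depol, "i_hyper": p.i_hyper,
             "t_depol": p.t_depol, "t_hyper": p.t_hyper,
             "targets": None if p.targets is None else list(p.targets)}
        )
        f.create_dataset("t_states", data=result.t_states)
        f.create_dataset("states", data=result.states)
        f.attrs["state_names"] = json.dumps(result.recorded_state_names)
        f.create_dataset("t_lfp", data=result.t_lfp)
        f.create_dataset("isyn", data=result.isyn)
        g = f.create_group("spikes")
        for k, s in enumerate(result.spikes):
            g.create_dataset(str(k), data=np.asarray(s))


def _model_for(model_id: str):
    return load_builtin(model_id)


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Dispatch a named experiment and write its artifacts under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = _model_for(config.model_id)
    desk = config.scale_mode == "desk"
    artifacts: dict = {}

    if config.experiment == "fig1a":
        p = model.presets.get("single_cell", {})
        proto = StepProtocol(p.get("i_depol", 2.0), p.get("i_hyper", -1.0),
                             2_000.0, 4_000.0)
        res = integrate(
            single_cell_system(model), proto,
            config.dt or model.recommended_dt,
            spike_threshold=SINGLE_CELL_CLASSIFIER.spike_threshold,
            record_cells=[0],
        )
        dep, hyp = epoch_patterns(res, 0, SINGLE_CELL_CLASSIFIER)
        h5 = out / f"fig1a_model{config.model_id}.h5"
        save_result_hdf5(res, h5)
        artifacts["trace_h5"] = str(h5)
        summary = {"depolarized": dep, "hyperpolarized": hyp}
    elif config.experiment == "fig1d":
        factors = (
            list(np.round(np.arange(0.01, 0.11, 0.01), 2))
            + list(np.round(np.arange(0.1, 5.01, 0.1), 2))
            if config.scale_mode == "full"
            else [0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0]
        )
        scan = capacitance_scan(model, factors)
        summary = {
            "factors": scan["factors"],
            "supported": [bool(s) for s in scan["supported"]],
            "interval": list(scan["interval"]),
        }
    elif config.experiment == "fig2b":
        widths = config.widths or (10.0, 20.0, 30.0)
        n = config.n_samples or (1000 if not desk else 1000 // DESK_SCALE["n_samples_divisor"])
        epoch = 41_000.0 if not desk else DESK_SCALE["circuit_epoch_ms"]
        rows = []
        for w in widths:
            spec = VariabilitySpec(
                intrinsic_width=w, n_samples=n, seed=config.seed,
                t_depol=epoch, t_hyper=epoch,
            )
            sr = circuit_switch_screen(model, spec)
            sr.to_csv(out / f"fig2b_model{config.model_id}_w{w:g}.csv")
            rows.append({"width": w, "percent": float(sr.percent[0])})
        summary = {"screen": rows}
    elif config.experiment == "fig3":
        etas = config.etas or TAU_SCREEN_ETAS
        n = config.n_samples or (400 if not desk else 400 // DESK_SCALE["n_samples_divisor"])
        epoch = 41_000.0 if not desk else DESK_SCALE["circuit_epoch_ms"]
        spec = VariabilitySpec(
            intrinsic_width=20.0, n_samples=n, seed=config.seed,
            t_depol=epoch, t_hyper=epoch,
        )
        sr = tau_scaling_screen(model, etas, spec)
        sr.to_csv(out / f"fig3_model{config.model_id}.csv")
        anchors = timescale_anchors(model)
        summary = {
            "etas": list(etas),
            "percent": [float(x) for x in sr.percent],
            "normalized_positions": [
                normalized_log_position(anchors, e) for e in etas
            ],
        }
    elif config.experiment in ("fig4", "fig5"):
        n_pop = 100 if not desk else DESK_SCALE["network_cells"]
        epoch = 21_000.0 if not desk else DESK_SCALE["network_epoch_ms"]
        if config.experiment == "fig4":
            width = model.presets.get("network", {}).get("heterogeneity", 20.0)
            rows = []
            for w in (0.0, width):
                spec = build_network(model, n_pop, n_pop, w, seed=config.seed)
                res = simulate_network(spec, default_network_protocol(model, epoch))
                rows.append(
                    {"width": w, "switch": bool(res.switch),
                     "band_power_ratio": float(res.band_power_ratio)}
                )
            summary = {"networks": rows}
        else:
            widths = config.widths or tuple(range(0, 55, 5))
            etas = config.etas or (1/8, 1/5, 1/4, 1/3, 1/2, 1, 2, 3, 4, 5, 8)
            table = heterogeneity_tau_table(
                model, widths=widths, etas=etas,
                n_e=n_pop, n_i=n_pop, seed=config.seed, t_epoch=epoch,
            )
            table.to_csv(out / f"fig5_model{config.model_id}.csv", index=False)
            summary = {"table": table.to_dict(orient="records")}
    elif config.experiment in ("fig6", "fig7"):
        from . import reduction_phase as rp

        cm_scale = 1.0 if config.experiment == "fig6" else 1.0 / 3.0
        red = rp.reduce_model(model, cm_scale=cm_scale)
        p = model.presets.get("single_cell", {})
        i_hyp = p.get("i_hyper", -1.0)
        sn = rp.saddle_node(red, i_hyp)
        summary = {"cm_scale": cm_scale, "saddle_node": None}
        if sn is not None:
            nc = rp.v_nullcline(red, sn.v_u, i_hyp)
            summary["saddle_node"] = {"v": sn.v, "v_u": sn.v_u}
            summary["n_nullcline_components"] = nc.n_components
            summary["lower_branch"] = rp.lower_branch_present(nc, sn.v)
    else:  # pragma: no cover
        raise AssertionError(config.experiment)

    payload = {"summary": summary, **_provenance(config)}
    jpath = out / f"{config.experiment}_model{config.model_id}.json"
    jpath.write_text(json.dumps(payload, indent=2, default=str))
    artifacts["summary_json"] = str(jpath)
    return artifacts


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------


def make_fixtures(kind: str, seed: int = 0) -> dict:
    """Constructed test inputs with known ground truth.

    - ``toy_oracles``: a fold normal form dV/dt = mu(V_u) + V^2 with its
      analytic saddle-node location;
    - ``spike_trains``: spike-time lists with known silent/tonic/burst labels;
    - ``lfp_signals``: epoch-tagged LFP traces (oscillation only in the
      hyperpolarized epoch, or identical noise in both).
    """
    rng = np.random.default_rng(seed)
    if kind == "toy_oracles":
        return {
            "description": "dV/dt = -(V_u + 50)/10 - V^2; dVs/dt=(V-Vs)/5",
            "mu_slope": -0.1,
            "mu_offset": -50.0,
            "sn_v": 0.0,
            "sn_v_u": -50.0,
        }
    if kind == "spike_trains":
        tonic = np.arange(100) * 20.0 + 600.0
        burst = []
        t = 600.0
        for _ in range(20):
            burst.extend(t + 5.0 * np.arange(4))
            t += 500.0
        jittered = tonic + rng.normal(0.0, 0.5, tonic.size)
        return {
            "silent": [],
            "tonic": tonic.tolist(),
            "tonic_jitter": np.sort(jittered).tolist(),
            "burst": list(map(float, burst)),
        }
    if kind == "lfp_signals":
        fs = 1000.0
        t = np.arange(0, 20.0, 1.0 / fs)
        t_switch = 10.0
        osc = np.where(t >= t_switch, np.sin(2 * np.pi * 4.0 * t), 0.0)
        noise = rng.normal(0.0, 1.0, t.size)
        return {
            "fs": fs,
            "t_s": t.tolist(),
            "t_switch_s": t_switch,
            "switching": (osc + 0.01 * noise).tolist(),
            "stationary_noise": noise.tolist(),
        }
    raise ValueError(f"unknown fixture kind {kind!r}")


# --------------------------------------------------------------------------
# CLI
# --------------------------------------------------------------------------


@click.group()
def cli():
    """Thalamic rhythm-switch robustness experiments."""


@cli.command("run")
@click.option("--experiment", type=click.Choice(EXPERIMENTS), required=True)
@click.option("--model", "model_id", default="1", show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--scale", "scale_mode", type=click.Choice(["full", "desk"]),
              default="desk", show_default=True)
@click.option("--out", "out_dir", default="results", show_default=True)
def cli_run(experiment, model_id, seed, scale_mode, out_dir):
    """Run one named experiment and write artifacts."""
    cfg = ExperimentConfig(
        experiment=experiment, model_id=model_id, seed=seed, scale_mode=scale_mode
    )
    artifacts = run_experiment(cfg, out_dir)
    for k, v in artifacts.items():
        click.echo(f"{k}: {v}")


@cli.command("run-config")
@click.argument("config_file", type=click.Path(exists=True))
@click.option("--out", "out_dir", default="results", show_default=True)
def cli_run_config(config_file, out_dir):
    """Run an experiment described by a YAML config file."""
    cfg = ExperimentConfig.from_yaml(config_file)
    artifacts = run_experiment(cfg, out_dir)
    for k, v in artifacts.items():
        click.echo(f"{k}: {v}")


@cli.command("make-fixtures")
@click.option("--kind", type=click.Choice(["toy_oracles", "spike_trains", "lfp_signals"]),
              required=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_file", default="-", show_default=True)
def cli_make_fixtures(kind, seed, out_file):
    """Generate constructed test inputs as JSON."""
    data = make_fixtures(kind, seed)
    text = json.dumps(data, indent=2)
    if out_file == "-":
        click.echo(text)
    else:
        Path(out_file).write_text(text)


@cli.command("list-models")
def cli_list_models():
    """List shipped model description files."""
    from .channel_models import available_models

    for mid in available_models():
        click.echo(mid)
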