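"""CSV schemas, experiment configuration, and reproducible experiment runs.

Three table schemas are supported:

* ``wide_community`` — ``time`` column plus one column per species.
* ``run_record`` — ``time_min, input_temp_C, sensor_temp_C, cell_count``
  at the fine (substep) resolution, with the commanded temperature
  repeated across each input interval; condition/replicate/substeps live
  in a small YAML sidecar next to the CSV.
* ``task_signal`` — two columns ``u, y`` plus a YAML sidecar of task
  metadata.

:func:`run_experiment` ties the modules into one reproducible run: it
generates a synthetic community, builds one simplex-projection reservoir
per species, drives them with a task input, multiplexes, trains a ridge
readout, and writes states, weights, a JSON report, the exact config used
and a log.  The report is byte-identical across invocations of the same
config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (EvaluationReport, correlation_skill, esp_converged,
                         esp_distance, nmse)
from .experiments import build_reservoirs as build_community_reservoirs
from .readout import readout_predict, train_ridge
from .reservoirs import erc_run, multiplex_states
from .synthetic import RunRecord, random_community_params, simulate_community
from .tasks import gen_lorenz, gen_narma, gen_uniform_input

__all__ = [
    "ExperimentConfig",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "run_experiment",
    "build_community_reservoirs",
]

CSV_KW = dict(float_format="%.12g", index=False)


def _check_uniform_time(t: np.ndarray):
    if t.size >= 2:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("non-uniform time step")


def read_timeseries_csv(path, schema: str):
    """Read a typed table; validates columns, finiteness and time spacing.

    Returns a DataFrame for ``wide_community``/``task_signal`` and a
    :class:`~ecoreservoir.synthetic.RunRecord` for ``run_record``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError("NaN values are not allowed")
    if schema == "wide_community":
        if "time" not in df.columns or df.shape[1] < 2:
            raise ValueError("schema error: need 'time' plus species columns")
        _check_uniform_time(df["time"].to_numpy(dtype=float))
        if not np.all(np.isfinite(df.to_numpy(dtype=float))):
            raise ValueError("non-finite values")
        return df
    if schema == "task_signal":
        for col in ("u", "y"):
            if col not in df.columns:
                raise ValueError(f"schema error: missing column '{col}'")
        return df
    if schema == "run_record":
        required = ["time_min", "input_temp_C", "sensor_temp_C", "cell_count"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"schema error: missing column '{col}'")
        _check_uniform_time(df["time_min"].to_numpy(dtype=float))
        meta = yaml.safe_load(path.with_suffix(".meta.yaml").read_text())
        sub = int(meta["substeps_per_input"])
        fine_u = df["input_temp_C"].to_numpy(dtype=float)
        if fine_u.size % sub:
            raise ValueError("fine length not divisible by substeps_per_input")
        return RunRecord(
            condition=meta["condition"], replicate=int(meta["replicate"]),
            input_temps=fine_u[::sub],
            sensor_temps=df["sensor_temp_C"].to_numpy(dtype=float),
            counts=df["cell_count"].to_numpy(dtype=float),
            substeps_per_input=sub,
        )
    raise ValueError(f"unknown schema {schema!r}")


def write_timeseries_csv(obj, path, schema: str):
    """Write a typed table; inverse of :func:`read_timeseries_csv`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if schema == "wide_community":
        obj.to_csv(path, **CSV_KW)
    elif schema == "task_signal":
        pd.DataFrame({"u": np.ravel(obj.u), "y": np.ravel(obj.y)}).to_csv(
            path, **CSV_KW)
        meta = {"name": obj.name, "horizon": int(obj.horizon),
                "params": {k: (float(v) if isinstance(v, (int, float, np.floating))
                               else v) for k, v in obj.params.items()},
                "seed": obj.seed}
        path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(meta))
    elif schema == "run_record":
        rec = obj
        fine_u = np.repeat(rec.input_temps, rec.substeps_per_input)
        pd.DataFrame({
            "time_min": np.arange(rec.n_fine, dtype=float),
            "input_temp_C": fine_u,
            "sensor_temp_C": rec.sensor_temps,
            "cell_count": rec.counts,
        }).to_csv(path, **CSV_KW)
        path.with_suffix(".meta.yaml").write_text(yaml.safe_dump({
            "condition": rec.condition, "replicate": int(rec.replicate),
            "substeps_per_input": int(rec.substeps_per_input)}))
    else:
        raise ValueError(f"unknown schema {schema!r}")
    return path


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment.

    Every stochastic component carries an explicit seed; the config
    round-trips through YAML losslessly.
    """

    name: str = "lorenz-multiplex-demo"
    task: str = "lorenz"                    # lorenz | narma2 | uniform
    task_params: dict = field(default_factory=dict)
    n_species: int = 20
    series_length: int = 400
    E_max: int = 8
    input_scale: float = 0.3
    variant: str = "project_then_add"
    lam: float = 0.05
    washout: int = 50
    intercept: bool = True
    train_frac: float = 0.7
    seed: int = None
    output_dir: str = "runs"

    def validate(self):
        if self.seed is None:
            raise ValueError("config must specify an explicit seed")
        if self.task not in ("lorenz", "narma2", "uniform"):
            raise ValueError(f"unknown task {self.task!r}")

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path):
        return cls(**yaml.safe_load(Path(path).read_text()))


def _make_task(cfg: ExperimentConfig):
    if cfg.task == "lorenz":
        return gen_lorenz(**{"n": 600, "horizon": 1, **cfg.task_params})
    if cfg.task == "narma2":
        u = gen_uniform_input(cfg.task_params.get("n", 600), 0.0, 0.5,
                              seed=cfg.seed + 1).u
        return gen_narma(2, u)
    return gen_uniform_input(cfg.task_params.get("n", 600), 0.0, 0.5,
                             seed=cfg.seed + 1)


def run_experiment(config: ExperimentConfig, output_dir=None):
    """Generate → embed → run → train → evaluate; artifacts on disk.

    Writes ``states.csv``, ``weights.csv``, ``report.json``,
    ``config.yaml`` and ``log.txt`` into a directory named after the
    config.  Two invocations with the same config produce byte-identical
    reports.  Returns an :class:`EvaluationReport`.
    """
    config.validate()
    out = Path(output_dir if output_dir is not None else config.output_dir) \
        / config.name
    out.mkdir(parents=True, exist_ok=True)
    log = [f"ecoreservoir {__version__}", f"experiment {config.name}",
           f"seed {config.seed}"]

    sig = _make_task(config)
    params = random_community_params(config.n_species, seed=config.seed)
    community = simulate_community(params, config.series_length)
    log.append(f"community: S={config.n_species}, n={config.series_length}")

    reservoirs = build_community_reservoirs(
        community, seed=config.seed, E_max=config.E_max,
        input_scale=config.input_scale, variant=config.variant)
    trajs = [erc_run(r, sig.u) for r in reservoirs]
    states = multiplex_states(trajs)
    log.append(f"reservoirs: {len(reservoirs)}, total size {states.state_dim}")

    n = states.T
    split = int(round(config.train_frac * n))
    model = train_ridge(states.matrix[:split], np.ravel(sig.y)[:split],
                        lam=config.lam, washout=config.washout,
                        intercept=config.intercept, standardize_targets=True,
                        standardize_features=True)
    pred = readout_predict(model, states.matrix[split:])
    obs = np.ravel(sig.y)[split:]

    def rerun(inputs, init):
        rs = build_community_reservoirs(
            community, seed=config.seed, E_max=config.E_max,
            input_scale=config.input_scale, variant=config.variant)
        return multiplex_states([erc_run(r, inputs, init_state=np.full(
            r.embedding.E, float(init[0]))) for r in rs])

    n_esp = min(150, n)
    d = esp_distance(lambda u, i: rerun(u[:n_esp], i), sig.u, [0.1], [0.9])
    report = EvaluationReport(
        nmse_per_horizon={sig.horizon: nmse(pred, obs)},
        correlation_per_horizon={sig.horizon: correlation_skill(pred, obs)},
        esp_distances=d,
        esp_converged=esp_converged(d),
        metadata={"config": asdict(config), "version": __version__,
                  "total_reservoir_size": int(states.state_dim),
                  "n_species_used": len(reservoirs)},
    )

    pd.DataFrame(states.matrix).to_csv(out / "states.csv", **CSV_KW)
    pd.DataFrame(model.w_out).to_csv(out / "weights.csv", **CSV_KW)
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), sort_keys=True, indent=2,
                   default=float) + "\n")
    config.to_yaml(out / "config.yaml")
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return report
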