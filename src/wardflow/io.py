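"""CSV and config-file handling.

Observation series travel as CSV with a ``time_min`` column plus one column
per observed node; the run configuration is a YAML document validated
fail-closed (unknown keys are errors).  All times are minutes from run start;
clock-of-day only appears inside the porter arrival profile.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimator import EstimatorConfig
from .kalman import ObservationModel, ObservationSeries
from .network import FlowNetwork, RateParameters, parse_rule_file

__all__ = [
    "RunConfig",
    "read_observations",
    "write_observations",
    "load_config",
    "dump_config",
    "config_hash",
]

TIME_COLUMN = "time_min"


class ConfigError(ValueError):
    """A config document violates the schema."""


def read_observations(path) -> ObservationSeries:
    """Read a time-stamped observation CSV (``time_min`` + channel columns)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if TIME_COLUMN not in frame.columns:
        raise ValueError(f"{path}: missing required column {TIME_COLUMN!r}")
    channels = [c for c in frame.columns if c != TIME_COLUMN]
    if not channels:
        raise ValueError(f"{path}: no observation channels")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()].index
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric cell in column {col!r} (file row {row})")
    times = frame[TIME_COLUMN].to_numpy(dtype=float)
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 3  # +1 header, +1 one-based, +1 second row
        raise ValueError(f"{path}: times not strictly increasing at file row {row}")
    return ObservationSeries(times, frame[channels].to_numpy(dtype=float), tuple(channels))


def write_observations(series: ObservationSeries, path) -> None:
    """Write a series as CSV with repr-round-trip float precision."""
    channels = series.channels or tuple(f"ch{i}" for i in range(series.values.shape[1]))
    frame = pd.DataFrame(series.values, columns=list(channels))
    frame.insert(0, TIME_COLUMN, series.times)
    frame.to_csv(path, index=False)  # shortest-repr floats; reader uses round_trip parsing


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (plain values; builders resolve against the network)."""

    network_path: str
    seed: int = 0
    rates: dict | None = None
    observed: tuple[str, ...] = ()
    obs_noise_sd: float = 1.0
    sigma0: float = 10.0
    process_noise: float = 1e-2
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    inputs: dict = field(default_factory=dict)  # channel -> constant value
    synthetic: dict = field(default_factory=dict)
    output_dir: str = "out"
    log_level: str = "INFO"

    def load_network(self) -> FlowNetwork:
        return parse_rule_file(Path(self.network_path).read_text())

    def rate_parameters(self, net: FlowNetwork) -> RateParameters:
        if not self.rates:
            raise ConfigError("config has no 'rates' section")
        return RateParameters.from_dict(net, dict(self.rates))

    def observation_model(self, net: FlowNetwork) -> ObservationModel:
        observed = self.observed or net.species
        H = np.zeros((len(observed), net.n_species))
        for i, name in enumerate(observed):
            H[i, net.species_index(name)] = 1.0
        R = self.obs_noise_sd**2 * np.eye(len(observed))
        return ObservationModel(H, R)

    def input_signal(self, net: FlowNetwork):
        if not net.input_channels:
            return None
        return np.array([float(self.inputs.get(ch, 0.0)) for ch in net.input_channels])


_ESTIMATOR_KEYS = {"a", "p0", "refresh", "burn_in_epochs", "cadence"}
_TOP_KEYS = {
    "network",
    "seed",
    "rates",
    "observation",
    "filter",
    "estimator",
    "inputs",
    "synthetic",
    "output_dir",
    "log_level",
}
_OBS_KEYS = {"observed", "noise_sd"}
_FILTER_KEYS = {"sigma0", "process_noise"}


def _reject_unknown(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (fail-closed)."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, str(path))
    if "network" not in doc:
        raise ConfigError(f"{path}: missing required key 'network'")
    net_path = doc["network"]
    if not Path(net_path).is_absolute():
        net_path = str(path.parent / net_path)

    obs = doc.get("observation", {}) or {}
    _reject_unknown(obs, _OBS_KEYS, "observation")
    filt = doc.get("filter", {}) or {}
    _reject_unknown(filt, _FILTER_KEYS, "filter")
    est = doc.get("estimator", {}) or {}
    _reject_unknown(est, _ESTIMATOR_KEYS, "estimator")

    seed = int(doc.get("seed", 0))
    if seed < 0:
        raise ConfigError("seed must be a nonnegative integer")

    cfg = RunConfig(
        network_path=net_path,
        seed=seed,
        rates=doc.get("rates"),
        observed=tuple(obs.get("observed", ())),
        obs_noise_sd=float(obs.get("noise_sd", 1.0)),
        sigma0=float(filt.get("sigma0", 10.0)),
        process_noise=float(filt.get("process_noise", 1e-2)),
        estimator=EstimatorConfig(
            a=float(est.get("a", 0.1)),
            p0=float(est.get("p0", 1e4)),
            sigma0=float(filt.get("sigma0", 10.0)),
            refresh=bool(est.get("refresh", True)),
            burn_in_epochs=int(est.get("burn_in_epochs", 10)),
            cadence=int(est.get("cadence", 1)),
        ),
        inputs=dict(doc.get("inputs", {}) or {}),
        synthetic=dict(doc.get("synthetic", {}) or {}),
        output_dir=str(doc.get("output_dir", "out")),
        log_level=str(doc.get("log_level", "INFO")),
    )

    # resolve referenced names against the network
    net = cfg.load_network()
    for name in cfg.observed:
        if name not in net.species:
            raise ConfigError(f"observed node {name!r} not declared in the network")
    if cfg.rates is not None:
        cfg.rate_parameters(net)  # raises on mismatch
    for ch in cfg.inputs:
        if ch not in net.input_channels:
            raise ConfigError(f"input channel {ch!r} not declared in the network")
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    """Write a RunConfig back to YAML such that load_config reproduces it."""
    doc = {
        "network": cfg.network_path,
        "seed": cfg.seed,
        "rates": cfg.rates,
        "observation": {"observed": list(cfg.observed), "noise_sd": cfg.obs_noise_sd},
        "filter": {"sigma0": cfg.sigma0, "process_noise": cfg.process_noise},
        "estimator": {
            "a": cfg.estimator.a,
            "p0": cfg.estimator.p0,
            "refresh": cfg.estimator.refresh,
            "burn_in_epochs": cfg.estimator.burn_in_epochs,
            "cadence": cfg.estimator.cadence,
        },
        "inputs": cfg.inputs,
        "synthetic": cfg.synthetic,
        "output_dir": cfg.output_dir,
        "log_level": cfg.log_level,
    }
    if doc["rates"] is None:
        del doc["rates"]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a configuration, for run logging."""
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
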