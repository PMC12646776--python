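"""Experiment configuration: a flat two-level YAML file, validated fail-fast.

Sections
--------
network
    ``source``: ``ba`` | ``edge_list`` | ``temporal``, plus per-source keys
    (``n_nodes``, ``m_attach`` for BA; ``path`` for file sources;
    ``window_start``, ``window_length`` for temporal aggregation).
params
    The scalar model constants ``beta, mu, d, cost_infection, cost_support,
    omega``.
init
    ``sigma0``/``rho0`` product mixing, or ``state_file`` pointing at a CSV
    ``node,p_DS,p_DI,p_TS,p_TI`` of per-node rows.
run
    ``n_steps``, ``window``, ``engine`` (``mmca`` | ``mc``), ``n_runs``.
intervention
    :class:`~epigame.interventions.InterventionSpec` fields.
output
    ``directory`` and optional ``prefix``.
rng_seed
    Master seed; every stochastic component derives a sub-seed from it.

Unknown keys anywhere are rejected with the offending key path, so typos
surface immediately instead of silently running defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ParameterError, ParseError
from .interventions import InterventionSpec
from .mmca import ModelParams, StateMatrix
from .network import (
    MultiplexNetwork,
    aggregate_window,
    generate_ba_network,
    load_edge_list,
    load_temporal_contacts,
)

_NETWORK_KEYS = {"source", "n_nodes", "m_attach", "path", "window_start", "window_length"}
_PARAM_KEYS = {"beta", "mu", "d", "cost_infection", "cost_support", "omega"}
_INIT_KEYS = {"sigma0", "rho0", "state_file"}
_RUN_KEYS = {"n_steps", "window", "engine", "n_runs"}
_INTERVENTION_KEYS = {
    "strategy",
    "k_seeds",
    "neighbour_prob",
    "apply_time",
    "persistent",
}
_OUTPUT_KEYS = {"directory", "prefix"}
_TOP_KEYS = {"network", "params", "init", "run", "intervention", "output", "rng_seed"}


def _check_keys(section: dict, allowed: set, path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ParameterError(
            f"unknown config key(s) {sorted(unknown)} under '{path}'"
        )


@dataclass
class ExperimentConfig:
    """Fully resolved experiment configuration."""

    network: dict
    params: ModelParams
    sigma0: float = 0.5
    rho0: float = 0.1
    state_file: str | None = None
    n_steps: int = 2000
    window: int = 100
    engine: str = "mmca"
    n_runs: int = 50
    intervention: InterventionSpec = field(default_factory=InterventionSpec)
    output_dir: str = "."
    prefix: str = "run"
    rng_seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        if not isinstance(raw, dict):
            raise ParameterError("config root must be a mapping")
        _check_keys(raw, _TOP_KEYS, "<root>")
        net = dict(raw.get("network") or {})
        _check_keys(net, _NETWORK_KEYS, "network")
        if net.get("source", "ba") not in ("ba", "edge_list", "temporal"):
            raise ParameterError(f"network.source must be ba|edge_list|temporal")

        par = dict(raw.get("params") or {})
        _check_keys(par, _PARAM_KEYS, "params")
        try:
            params = ModelParams(
                beta=float(par.get("beta", 0.3)),
                mu=float(par.get("mu", 0.5)),
                d=float(par.get("d", 0.6)),
                cost_infection=float(par.get("cost_infection", 2.0)),
                cost_support=float(par.get("cost_support", 0.2)),
                omega=float(par.get("omega", 0.5)),
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ParameterError):
                raise
            raise ParameterError(f"invalid params section: {exc}") from exc

        init = dict(raw.get("init") or {})
        _check_keys(init, _INIT_KEYS, "init")
        run = dict(raw.get("run") or {})
        _check_keys(run, _RUN_KEYS, "run")
        engine = run.get("engine", "mmca")
        if engine not in ("mmca", "mc"):
            raise ParameterError("run.engine must be 'mmca' or 'mc'")

        intr = dict(raw.get("intervention") or {})
        _check_keys(intr, _INTERVENTION_KEYS, "intervention")
        spec = InterventionSpec(
            strategy=intr.get("strategy", "none"),
            k_seeds=int(intr.get("k_seeds", 0)),
            neighbour_prob=float(intr.get("neighbour_prob", 1.0)),
            apply_time=int(intr.get("apply_time", 0)),
            persistent=bool(intr.get("persistent", True)),
        )

        out = dict(raw.get("output") or {})
        _check_keys(out, _OUTPUT_KEYS, "output")

        return cls(
            network={"source": "ba", "n_nodes": 500, "m_attach": 3, **net},
            params=params,
            sigma0=float(init.get("sigma0", 0.5)),
            rho0=float(init.get("rho0", 0.1)),
            state_file=init.get("state_file"),
            n_steps=int(run.get("n_steps", 2000)),
            window=int(run.get("window", 100)),
            engine=engine,
            n_runs=int(run.get("n_runs", 50)),
            intervention=spec,
            output_dir=str(out.get("directory", ".")),
            prefix=str(out.get("prefix", "run")),
            rng_seed=int(raw.get("rng_seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raw = {}
        return cls.from_dict(raw)

    def build_network(self) -> MultiplexNetwork:
        src = self.network["source"]
        if src == "ba":
            return generate_ba_network(
                int(self.network["n_nodes"]),
                int(self.network.get("m_attach", 3)),
                self.rng_seed,
            )
        if src == "edge_list":
            return load_edge_list(self.network["path"])
        records = load_temporal_contacts(self.network["path"])
        return aggregate_window(
            records,
            window_start=self.network.get("window_start"),
            window_length=int(self.network.get("window_length", 86_400)),
        )

    def build_initial_state(self, n_nodes: int) -> StateMatrix:
        if self.state_file is not None:
            return load_state_csv(self.state_file, n_nodes)
        return StateMatrix.uniform_mixing(n_nodes, self.sigma0, self.rho0)

    def resolved(self) -> dict:
        """JSON-serialisable view of every resolved setting (for manifests)."""
        return {
            "network": dict(self.network),
            "params": {
                "beta": self.params.beta,
                "mu": self.params.mu,
                "d": self.params.d,
                "cost_infection": self.params.cost_infection,
                "cost_support": self.params.cost_support,
                "omega": self.params.omega,
            },
            "init": {
                "sigma0": self.sigma0,
                "rho0": self.rho0,
                "state_file": self.state_file,
            },
            "run": {
                "n_steps": self.n_steps,
                "window": self.window,
                "engine": self.engine,
                "n_runs": self.n_runs,
            },
            "intervention": {
                "strategy": self.intervention.strategy,
                "k_seeds": self.intervention.k_seeds,
                "neighbour_prob": self.intervention.neighbour_prob,
                "apply_time": self.intervention.apply_time,
                "persistent": self.intervention.persistent,
                "seed_set": list(self.intervention.seed_set),
            },
            "output": {"directory": self.output_dir, "prefix": self.prefix},
            "rng_seed": self.rng_seed,
        }


def load_state_csv(path, n_nodes: int) -> StateMatrix:
    """Read per-node initial rows from CSV ``node,p_DS,p_DI,p_TS,p_TI``."""
    import pandas as pd

    df = pd.read_csv(path)
    expected = ["node", "p_DS", "p_DI", "p_TS", "p_TI"]
    if list(df.columns) != expected:
        raise ParseError(f"state file must have columns {expected}, got {list(df.columns)}")
    if len(df) != n_nodes:
        raise ParameterError(
            f"state file has {len(df)} rows but the network has {n_nodes} nodes"
        )
    return StateMatrix(df[["p_DS", "p_DI", "p_TS", "p_TI"]].to_numpy())
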