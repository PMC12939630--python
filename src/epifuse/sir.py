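"""Discrete-time stochastic SIR simulation on a graph.

One run starts with a single infected seed node at time t = 1 and evolves
synchronously: at each step every susceptible node with k infected
neighbors becomes infected with probability 1 - (1 - beta)^k (independent
per-contact attempts), and every infected node recovers with probability
gamma.  Recovered nodes are absorbing.  The run is recorded as a binary
time-state matrix: entry (t, j) is 1 iff node j is infectious at step t;
susceptible and recovered nodes are both recorded as 0.

The terminal all-zero row (extinction) is kept so that the last infection
generation still yields a t -> t+1 transition pair for downstream counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graphio import Graph

__all__ = ["SIRConfig", "TimeStateMatrix", "simulate_once", "simulate_batch",
           "write_time_state_csv", "read_time_state_csv", "write_batch"]

_S, _I, _R = 0, 1, 2


@dataclass(frozen=True)
class SIRConfig:
    """Propagation parameters for one simulation campaign.

    beta : per-contact, per-step infection probability.
    gamma : per-step recovery probability; gamma = 1 means an infected
        node is infectious for exactly one step.
    max_steps : safety cap on recorded steps; ``None`` resolves to 4N at
        simulation time (with gamma = 1 extinction occurs within N + 1
        steps regardless).
    rng_seed : base seed; each replicate draws from a child stream derived
        from (rng_seed, seed-node index, replicate index).
    """

    beta: float
    gamma: float = 1.0
    max_steps: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.max_steps is not None and self.max_steps < 1:
            raise ValueError(f"max_steps must be >= 1, got {self.max_steps}")


@dataclass(frozen=True)
class TimeStateMatrix:
    """T x N binary record of one SIR run.

    Row t (1-based time) marks which nodes are infectious at step t;
    columns follow the graph's node order.
    """

    values: np.ndarray
    nodes: tuple[str, ...]
    seed_node: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        if v.ndim != 2 or v.shape[1] != len(self.nodes):
            raise ValueError("time-state matrix shape does not match node list")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("time-state entries must be 0 or 1")
        object.__setattr__(self, "values", v)

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


def _replicate_rng(cfg: SIRConfig, seed_index: int, replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=cfg.rng_seed, spawn_key=(seed_index, replicate))
    return np.random.default_rng(ss)


def simulate_once(
    g: Graph,
    seed_node: str,
    cfg: SIRConfig,
    rng: np.random.Generator | None = None,
) -> TimeStateMatrix:
    """Run a single SIR realization and return its time-state matrix.

    Updates are synchronous: infections and recoveries for step t + 1 are
    both computed from the state at step t.  The run stops after the first
    recorded all-zero row (extinction) or when ``max_steps`` rows have been
    recorded.
    """
    seed_node = str(seed_node)
    seed_idx = g.index_of(seed_node)
    n = g.n_nodes
    if rng is None:
        rng = _replicate_rng(cfg, seed_idx, 0)
    max_steps = cfg.max_steps if cfg.max_steps is not None else 4 * n

    adj = g.adjacency_matrix().astype(bool)
    state = np.full(n, _S, dtype=np.int8)
    state[seed_idx] = _I

    rows = []
    for _ in range(max_steps):
        infected = state == _I
        rows.append(infected.astype(np.int8))
        if not infected.any():
            break
        # k infected neighbors => infection prob 1 - (1 - beta)^k
        k = adj[:, infected].sum(axis=1)
        susceptible = state == _S
        p_inf = 1.0 - (1.0 - cfg.beta) ** k
        new_inf = susceptible & (rng.random(n) < p_inf)
        recover = infected & (rng.random(n) < cfg.gamma)
        state[new_inf] = _I
        state[recover] = _R
    return TimeStateMatrix(np.array(rows, dtype=np.int8), g.nodes, seed_node)


def simulate_batch(g: Graph, seed_node: str, cfg: SIRConfig, m: int) -> list[TimeStateMatrix]:
    """M independent SIR runs from one seed node, reproducible from cfg.

    Replicate r uses the RNG stream spawned from
    (cfg.rng_seed, index of seed_node, r), so the batch is deterministic
    and independent of evaluation order.
    """
    if m < 1:
        raise ValueError(f"number of replicates must be >= 1, got {m}")
    seed_idx = g.index_of(str(seed_node))
    return [
        simulate_once(g, seed_node, cfg, rng=_replicate_rng(cfg, seed_idx, r))
        for r in range(m)
    ]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_time_state_csv(ts: TimeStateMatrix, path: str | Path) -> None:
    pd.DataFrame(ts.values, columns=list(ts.nodes)).to_csv(path, index=False)


def read_time_state_csv(path: str | Path, seed_node: str = "?") -> TimeStateMatrix:
    df = pd.read_csv(path)
    nodes = tuple(str(c) for c in df.columns)
    return TimeStateMatrix(df.to_numpy(dtype=np.int8), nodes, str(seed_node))


def write_batch(
    batch: list[TimeStateMatrix],
    directory: str | Path,
    *,
    graph_file: str | None = None,
    cfg: SIRConfig | None = None,
) -> Path:
    """Store a batch as one CSV per replicate plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for r, ts in enumerate(batch):
        write_time_state_csv(ts, directory / f"run_{r:04d}.csv")
    manifest = {
        "seed_node": batch[0].seed_node if batch else None,
        "replicates": len(batch),
        "graph_file": graph_file,
        "beta": cfg.beta if cfg else None,
        "gamma": cfg.gamma if cfg else None,
        "rng_seed": cfg.rng_seed if cfg else None,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return directory


def read_batch(directory: str | Path) -> list[TimeStateMatrix]:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    seed_node = "?"
    if manifest_path.exists():
        seed_node = json.loads(manifest_path.read_text(encoding="utf-8")).get("seed_node") or "?"
    return [
        read_time_state_csv(p, seed_node=seed_node)
        for p in sorted(directory.glob("run_*.csv"))
    ]
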