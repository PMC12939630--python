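"""Second-level fusion across seed nodes and the end-to-end reconstruction.

Evidence matrices produced independently from several seed nodes (each
the local observation perspective of one epidemic source) are fused
sequentially with Dempster's rule: the first seed's matrices initialize
the global belief, and each further seed is folded in elementwise per
node pair.  Because the combination rule is commutative and associative,
the seed order affects the result only at floating-point level.

The final adjacency is decided per pair by thresholding the fused support
mass: an edge is declared iff global m({T}) strictly exceeds theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import evidence as ev
from .evidence import ConflictMode, EvidenceMatrices
from .graphio import Graph
from .sir import SIRConfig, TimeStateMatrix, simulate_batch

__all__ = [
    "ReconstructionConfig", "ReconstructionResult",
    "inter_node_fuse", "decide_adjacency",
    "reconstruct_pipeline", "reconstruct_from_data",
]


@dataclass(frozen=True)
class ReconstructionConfig:
    """Full parameterization of one reconstruction run.

    seed_nodes : ordered epidemic source labels (defaults to the first
        three node labels when built via :meth:`with_defaults`).
    sir : propagation parameters (beta, gamma, rng_seed).
    replicates : number of independent SIR runs per seed node.
    theta : decision threshold on the fused support mass, in (0, 1).
    conflict_mode : policy for total-conflict cells during fusion.
    """

    seed_nodes: tuple[str, ...]
    sir: SIRConfig
    replicates: int = 50
    theta: float = 0.7
    conflict_mode: ConflictMode = "warn-vacuous"

    def __post_init__(self) -> None:
        seeds = tuple(str(s) for s in self.seed_nodes)
        object.__setattr__(self, "seed_nodes", seeds)
        if len(set(seeds)) != len(seeds) or not seeds:
            raise ValueError("seed_nodes must be non-empty and distinct")
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must be in (0, 1), got {self.theta}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")

    @classmethod
    def with_defaults(
        cls,
        g: Graph,
        seed_nodes: Sequence[str] | None = None,
        beta: float = 0.5,
        gamma: float = 1.0,
        replicates: int = 50,
        theta: float = 0.7,
        rng_seed: int = 0,
        conflict_mode: ConflictMode = "warn-vacuous",
    ) -> "ReconstructionConfig":
        seeds = tuple(seed_nodes) if seed_nodes else g.nodes[:3]
        return cls(seeds, SIRConfig(beta=beta, gamma=gamma, rng_seed=rng_seed),
                   replicates=replicates, theta=theta, conflict_mode=conflict_mode)


@dataclass(frozen=True)
class ReconstructionResult:
    """Decided adjacency plus the evidence that produced it."""

    adjacency: np.ndarray
    nodes: tuple[str, ...]
    global_evidence: EvidenceMatrices
    per_seed_evidence: tuple[EvidenceMatrices, ...]
    config: "ReconstructionConfig | None"
    warnings_log: tuple[str, ...] = field(default=())

    def predicted_edges(self) -> list[tuple[str, str]]:
        out = []
        for i, j in zip(*np.nonzero(np.triu(self.adjacency))):
            out.append((self.nodes[i], self.nodes[j]))
        return out

    def as_graph(self) -> Graph:
        return Graph(self.nodes, self.predicted_edges())


def inter_node_fuse(
    sources: Sequence[EvidenceMatrices],
    conflict_mode: ConflictMode = "warn-vacuous",
) -> EvidenceMatrices:
    """Left-fold Dempster fusion of per-seed evidence into a global belief.

    The first source initializes the global matrices; each subsequent
    source s is combined elementwise: per pair, the conflict
    K = T_g F_s + F_g T_s is removed and the intersecting products
    renormalized by 1 - K.  Fusing with an all-vacuous source is a no-op.
    """
    if not sources:
        raise ValueError("need at least one evidence source")
    nodes = sources[0].nodes
    bt = sources[0].bpa_t.copy()
    bf = sources[0].bpa_f.copy()
    btf = sources[0].bpa_tf.copy()
    for src in sources[1:]:
        if src.nodes != nodes:
            raise ValueError("evidence sources have mismatched node order")
        k = bt * src.bpa_f + bf * src.bpa_t
        num_t = bt * src.bpa_t + bt * src.bpa_tf + btf * src.bpa_t
        num_f = bf * src.bpa_f + bf * src.bpa_tf + btf * src.bpa_f
        num_tf = btf * src.bpa_tf
        bt, bf, btf = ev._apply_conflict(num_t, num_f, num_tf, 1.0 - k, conflict_mode)
    diag = np.eye(len(nodes), dtype=bool)
    bt[diag], bf[diag], btf[diag] = 0.0, 0.0, 1.0
    return EvidenceMatrices(bt, bf, btf, nodes, source="global")


def decide_adjacency(global_evidence: EvidenceMatrices, theta: float) -> np.ndarray:
    """Threshold the fused support mass: edge iff m({T}) > theta (strict)."""
    a = (global_evidence.bpa_t > theta).astype(np.int64)
    np.fill_diagonal(a, 0)
    return a


def _per_seed_evidence(
    batches: Sequence[Sequence[TimeStateMatrix]],
    seed_nodes: Sequence[str],
    conflict_mode: ConflictMode,
) -> tuple[list[EvidenceMatrices], list[str]]:
    per_seed: list[EvidenceMatrices] = []
    log: list[str] = []
    for seed, batch in zip(seed_nodes, batches):
        mc = ev.count_transitions(batch)
        if mc.values.max() == 0:
            msg = f"seed {seed}: no propagation events observed; contributing vacuous evidence"
            warnings.warn(msg, UserWarning, stacklevel=3)
            log.append(msg)
            per_seed.append(ev.vacuous_evidence(mc.nodes, source=str(seed)))
            continue
        mr = ev.normalize_counts(mc)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ev.TotalConflictWarning)
            per_seed.append(ev.intra_node_fuse(mr, conflict_mode, source=str(seed)))
        log.extend(f"seed {seed}: {w.message}" for w in caught)
    return per_seed, log


def reconstruct_from_data(
    batches: Sequence[Sequence[TimeStateMatrix]],
    seed_nodes: Sequence[str],
    theta: float = 0.7,
    conflict_mode: ConflictMode = "warn-vacuous",
    config: ReconstructionConfig | None = None,
) -> ReconstructionResult:
    """Reconstruct a topology from pre-recorded time-state batches.

    ``batches[s]`` holds the replicate matrices recorded from
    ``seed_nodes[s]``.  Used when the propagation data come from files
    rather than from the built-in simulator.
    """
    if len(batches) != len(seed_nodes) or not batches:
        raise ValueError("need one non-empty batch per seed node")
    per_seed, log = _per_seed_evidence(batches, seed_nodes, conflict_mode)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ev.TotalConflictWarning)
        fused = inter_node_fuse(per_seed, conflict_mode)
    log.extend(f"inter-node: {w.message}" for w in caught)
    adjacency = decide_adjacency(fused, theta)
    return ReconstructionResult(
        adjacency=adjacency,
        nodes=per_seed[0].nodes,
        global_evidence=fused,
        per_seed_evidence=tuple(per_seed),
        config=config,
        warnings_log=tuple(log),
    )


def reconstruct_pipeline(g: Graph, cfg: ReconstructionConfig) -> ReconstructionResult:
    """End-to-end reconstruction: simulate, extract evidence, fuse, decide.

    For each configured seed node, run ``replicates`` independent SIR
    simulations, tally direct-transmission counts, normalize, and perform
    intra-node fusion; then fuse across seeds and threshold at theta.
    Fully reproducible from the config (all randomness flows from
    ``cfg.sir.rng_seed``).
    """
    for s in cfg.seed_nodes:
        g.index_of(s)  # validate early
    batches = [simulate_batch(g, s, cfg.sir, cfg.replicates) for s in cfg.seed_nodes]
    result = reconstruct_from_data(
        batches, cfg.seed_nodes, theta=cfg.theta, conflict_mode=cfg.conflict_mode,
    )
    return ReconstructionResult(
        adjacency=result.adjacency,
        nodes=result.nodes,
        global_evidence=result.global_evidence,
        per_seed_evidence=result.per_seed_evidence,
        config=cfg,
        warnings_log=result.warnings_log,
    )
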