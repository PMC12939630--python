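"""Evidence construction and Dempster-Shafer mass algebra on the edge frame.

For each candidate edge the frame of discernment is the two-hypothesis set
{T = edge exists, F = edge absent}.  A basic probability assignment (BPA)
allocates unit mass over {T}, {F} and the uncertain set {T, F}.

The pipeline from one seed node's simulation batch is:

1. ``count_transitions`` — tally the direct-transmission pattern
   (i infectious and j healthy at t; i healthy and j infectious at t + 1)
   over all replicates into a count matrix MC.
2. ``normalize_counts``  — scale by the global maximum to the association
   matrix MR in [0, 1] and record its off-diagonal extrema
   (Rmax, Rmin, Rmid = midpoint).
3. ``initial_belief``    — map an association strength x to a mass triple
   via its absolute deviations from Rmax / Rmin / Rmid:
   Summ = |x-Rmax| + |x-Rmin| + |x-Rmid|, m_T = |x-Rmin| / Summ,
   m_F = |x-Rmax| / Summ, m_TF = |x-Rmid| / Summ.
4. ``intra_node_fuse``   — for every unordered pair (i, j), combine the
   directional evidence from MR(i, j) and MR(j, i) by Dempster's rule to
   give one symmetric mass triple per pair.

Note that this belief mapping assigns the *largest* uncertainty mass at
the extremes x = Rmin and x = Rmax and zero uncertainty at the midpoint;
it is applied exactly as defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .sir import TimeStateMatrix

__all__ = [
    "MassFunction", "VACUOUS", "BeliefContext", "CountMatrix",
    "AssociationMatrix", "EvidenceMatrices", "TotalConflictWarning",
    "TotalConflictError", "count_transitions", "normalize_counts",
    "belief_context", "initial_belief", "dempster_combine",
    "belief_of", "plausibility_of", "intra_node_fuse", "vacuous_evidence",
]

_CONFLICT_EPS = 1e-12

ConflictMode = Literal["warn-vacuous", "strict"]


class TotalConflictWarning(UserWarning):
    """Two evidence bodies were in total conflict (K = 1); result is vacuous."""


class TotalConflictError(ValueError):
    """Raised in strict mode when evidence is in total conflict."""


class MassFunction(NamedTuple):
    """BPA triple (m({T}), m({F}), m({T,F})) on the single-edge frame."""

    m_t: float
    m_f: float
    m_tf: float

    def validate(self, tol: float = 1e-9) -> "MassFunction":
        if min(self) < -tol:
            raise ValueError(f"negative mass in {self}")
        if abs(sum(self) - 1.0) > tol:
            raise ValueError(f"masses must sum to 1, got {sum(self)}")
        return self


#: Total ignorance: all mass on {T, F}.  Neutral element of combination.
VACUOUS = MassFunction(0.0, 0.0, 1.0)


class BeliefContext(NamedTuple):
    """Off-diagonal extrema of an association matrix.

    ``degenerate`` is set when Rmax == Rmin, in which case every belief
    triple collapses to the vacuous mass (no contrast to assign belief).
    """

    rmax: float
    rmin: float
    rmid: float
    degenerate: bool = False


@dataclass(frozen=True)
class CountMatrix:
    """N x N tally of observed direct-transmission patterns i -> j."""

    values: np.ndarray
    nodes: tuple[str, ...]
    replicates: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int64)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.nodes):
            raise ValueError("count matrix must be square and match node list")
        if (v < 0).any() or np.diag(v).any():
            raise ValueError("count matrix must be non-negative with zero diagonal")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class AssociationMatrix:
    """Counts normalized by their global maximum, with belief context."""

    values: np.ndarray
    nodes: tuple[str, ...]
    context: BeliefContext


@dataclass(frozen=True)
class EvidenceMatrices:
    """Three symmetric N x N mass matrices (support / opposition / uncertainty).

    Off-diagonal triples sum to 1; the diagonal carries the vacuous triple
    (0, 0, 1) by convention.
    """

    bpa_t: np.ndarray
    bpa_f: np.ndarray
    bpa_tf: np.ndarray
    nodes: tuple[str, ...]
    source: str = "global"

    def mass_at(self, i: int, j: int) -> MassFunction:
        return MassFunction(float(self.bpa_t[i, j]), float(self.bpa_f[i, j]),
                            float(self.bpa_tf[i, j]))


# ---------------------------------------------------------------------------
# evidence extraction from simulation output
# ---------------------------------------------------------------------------


def count_transitions(batch: Sequence[TimeStateMatrix]) -> CountMatrix:
    """Tally direct-transmission patterns over a batch of time-state matrices.

    MC(i, j) counts, over all replicates and consecutive step pairs
    (t, t+1), the events where node i is infectious and node j healthy at
    t while at t + 1 node i is healthy and node j infectious — the
    signature of i having transmitted to j and then recovered.
    """
    if not batch:
        raise ValueError("empty batch")
    nodes = batch[0].nodes
    n = len(nodes)
    mc = np.zeros((n, n), dtype=np.int64)
    for ts in batch:
        if ts.nodes != nodes:
            raise ValueError("inconsistent node order across batch")
        x = ts.values
        if x.shape[0] < 2:
            continue
        a, b = x[:-1], x[1:]
        senders = (a == 1) & (b == 0)       # infectious at t, healthy at t+1
        receivers = (a == 0) & (b == 1)     # healthy at t, infectious at t+1
        mc += senders.astype(np.int64).T @ receivers.astype(np.int64)
    np.fill_diagonal(mc, 0)  # pattern cannot fire for i == j; defensive
    return CountMatrix(mc, nodes, len(batch))


def normalize_counts(mc: CountMatrix) -> AssociationMatrix:
    """Scale counts by the global maximum into [0, 1] association strengths."""
    peak = int(mc.values.max())
    if peak == 0:
        raise ValueError("no propagation events observed (all-zero count matrix)")
    mr = mc.values / peak
    return AssociationMatrix(mr, mc.nodes, belief_context(mr))


def belief_context(mr: np.ndarray | AssociationMatrix) -> BeliefContext:
    """Extrema of the off-diagonal association strengths.

    The diagonal is structurally zero (a node cannot transmit to itself)
    and is excluded so it cannot distort the contrast range.
    """
    values = mr.values if isinstance(mr, AssociationMatrix) else np.asarray(mr, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes for a belief context")
    off = values[~np.eye(n, dtype=bool)]
    rmax, rmin = float(off.max()), float(off.min())
    return BeliefContext(rmax, rmin, (rmax + rmin) / 2.0, degenerate=(rmax == rmin))


def initial_belief(x: float, ctx: BeliefContext) -> MassFunction:
    """Map association strength x to a mass triple by deviation from extrema.

    A degenerate context (or Summ = 0) yields the vacuous mass: with no
    contrast in the data, total ignorance is the faithful representation.
    """
    if ctx.degenerate:
        return VACUOUS
    if not ctx.rmin - 1e-12 <= x <= ctx.rmax + 1e-12:
        raise ValueError(f"x={x} outside belief context range [{ctx.rmin}, {ctx.rmax}]")
    summ = abs(x - ctx.rmax) + abs(x - ctx.rmin) + abs(x - ctx.rmid)
    if summ == 0.0:
        return VACUOUS
    return MassFunction(
        abs(x - ctx.rmin) / summ,
        abs(x - ctx.rmax) / summ,
        abs(x - ctx.rmid) / summ,
    )


# ---------------------------------------------------------------------------
# Dempster algebra on the two-hypothesis frame
# ---------------------------------------------------------------------------


def dempster_combine(
    m1: MassFunction,
    m2: MassFunction,
    conflict_mode: ConflictMode = "warn-vacuous",
) -> MassFunction:
    """Dempster's orthogonal combination specialized to the edge frame.

    K = m1_T m2_F + m1_F m2_T is the conflict mass; the remaining products
    land on {T}, {F} or {T,F} by subset intersection and are renormalized
    by 1 - K.  Total conflict (K = 1) cannot be renormalized: by default a
    warning is emitted and the vacuous mass returned, so one pathological
    pair cannot abort a whole reconstruction; ``strict`` raises instead.
    """
    k = m1.m_t * m2.m_f + m1.m_f * m2.m_t
    denom = 1.0 - k
    if denom < _CONFLICT_EPS:
        if conflict_mode == "strict":
            raise TotalConflictError(f"total conflict (K={k}) between {m1} and {m2}")
        warnings.warn("total conflict (K=1): returning vacuous mass", TotalConflictWarning,
                      stacklevel=2)
        return VACUOUS
    # grouping a + (b + c) keeps the combination bitwise commutative
    return MassFunction(
        (m1.m_t * m2.m_t + (m1.m_t * m2.m_tf + m1.m_tf * m2.m_t)) / denom,
        (m1.m_f * m2.m_f + (m1.m_f * m2.m_tf + m1.m_tf * m2.m_f)) / denom,
        (m1.m_tf * m2.m_tf) / denom,
    )


_PROPOSITIONS = {
    frozenset({"T"}): lambda m: (m.m_t, m.m_t + m.m_tf),
    frozenset({"F"}): lambda m: (m.m_f, m.m_f + m.m_tf),
    frozenset({"T", "F"}): lambda m: (m.m_t + m.m_f + m.m_tf,
                                      m.m_t + m.m_f + m.m_tf),
}


def _bel_pl(m: MassFunction, proposition) -> tuple[float, float]:
    key = frozenset(proposition)
    if key not in _PROPOSITIONS:
        raise ValueError(f"invalid proposition {proposition!r}; expected a subset of {{T, F}}")
    return _PROPOSITIONS[key](m)


def belief_of(m: MassFunction, proposition) -> float:
    """Belief Bel(A): total mass committed to subsets of A (lower bound)."""
    return _bel_pl(m, proposition)[0]


def plausibility_of(m: MassFunction, proposition) -> float:
    """Plausibility Pl(A): total mass not contradicting A (upper bound)."""
    return _bel_pl(m, proposition)[1]


# ---------------------------------------------------------------------------
# first-level (intra-node) fusion
# ---------------------------------------------------------------------------


def _apply_conflict(num_t, num_f, num_tf, denom, conflict_mode: ConflictMode):
    """Renormalize elementwise, routing K=1 cells through the conflict policy."""
    bad = denom < _CONFLICT_EPS
    if bad.any():
        if conflict_mode == "strict":
            raise TotalConflictError("total conflict (K=1) for at least one node pair")
        warnings.warn(
            f"total conflict (K=1) for {int(bad.sum())} node pair cell(s): set vacuous",
            TotalConflictWarning, stacklevel=3,
        )
    safe = np.where(bad, 1.0, denom)
    t = np.where(bad, 0.0, num_t / safe)
    f = np.where(bad, 0.0, num_f / safe)
    tf = np.where(bad, 1.0, num_tf / safe)
    return t, f, tf


def intra_node_fuse(
    mr: AssociationMatrix,
    conflict_mode: ConflictMode = "warn-vacuous",
    source: str | None = None,
) -> EvidenceMatrices:
    """Fuse the two directional evidence bodies of every node pair.

    MR(i, j) and MR(j, i) are independent observations of the same
    undirected proposition "edge {i, j} exists"; each is mapped to a mass
    triple and the two are combined with Dempster's rule.  The result is
    written symmetrically, giving the seed node's local evidence matrices.
    """
    n = len(mr.nodes)
    ctx = mr.context
    if ctx.degenerate:
        ev = vacuous_evidence(mr.nodes, source or "degenerate")
        return ev
    summ = (np.abs(mr.values - ctx.rmax) + np.abs(mr.values - ctx.rmin)
            + np.abs(mr.values - ctx.rmid))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(summ > 0, np.abs(mr.values - ctx.rmin) / summ, 0.0)
        f = np.where(summ > 0, np.abs(mr.values - ctx.rmax) / summ, 0.0)
        tf = np.where(summ > 0, np.abs(mr.values - ctx.rmid) / summ, 1.0)

    # pairwise Dempster combination of (i, j) with its transpose (j, i)
    k = t * f.T + f * t.T
    # grouping a + (b + c) keeps the fused matrices bitwise symmetric
    num_t = t * t.T + (t * tf.T + tf * t.T)
    num_f = f * f.T + (f * tf.T + tf * f.T)
    num_tf = tf * tf.T
    bt, bf, btf = _apply_conflict(num_t, num_f, num_tf, 1.0 - k, conflict_mode)

    diag = np.eye(n, dtype=bool)
    bt[diag], bf[diag], btf[diag] = 0.0, 0.0, 1.0
    return EvidenceMatrices(bt, bf, btf, mr.nodes, source or "intra")


def vacuous_evidence(nodes: Sequence[str], source: str = "vacuous") -> EvidenceMatrices:
    """All-vacuous evidence: the neutral element of inter-node fusion."""
    n = len(nodes)
    return EvidenceMatrices(
        np.zeros((n, n)), np.zeros((n, n)), np.ones((n, n)),
        tuple(nodes), source,
    )
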