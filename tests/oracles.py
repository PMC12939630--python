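"""Independent reference implementations used only as test oracles.

These deliberately do NOT share code with the package: the power-set
combiner enumerates subsets generically, and the belief mapping is
re-derived in exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product

T = frozenset({"T"})
F = frozenset({"F"})
TF = frozenset({"T", "F"})
EMPTY = frozenset()


def mass_dict(m_t, m_f, m_tf) -> dict[frozenset, Fraction]:
    return {T: Fraction(m_t), F: Fraction(m_f), TF: Fraction(m_tf)}


def combine_powerset(m1: dict[frozenset, Fraction], m2: dict[frozenset, Fraction]):
    """Generic Dempster combination by explicit power-set enumeration.

    Returns (combined mass dict, conflict K).  Raises ZeroDivisionError on
    total conflict.
    """
    joint: dict[frozenset, Fraction] = {}
    conflict = Fraction(0)
    for (a, ma), (b, mb) in product(m1.items(), m2.items()):
        inter = a & b
        if inter == EMPTY:
            conflict += ma * mb
        else:
            joint[inter] = joint.get(inter, Fraction(0)) + ma * mb
    denom = 1 - conflict
    return {s: v / denom for s, v in joint.items()}, conflict


def initial_belief_fractions(x, rmax, rmin, rmid) -> tuple[Fraction, Fraction, Fraction]:
    """Exact rational evaluation of the deviation-based belief mapping."""
    x, rmax, rmin, rmid = map(Fraction, (x, rmax, rmin, rmid))
    summ = abs(x - rmax) + abs(x - rmin) + abs(x - rmid)
    if summ == 0:
        return Fraction(0), Fraction(0), Fraction(1)
    return abs(x - rmin) / summ, abs(x - rmax) / summ, abs(x - rmid) / summ
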