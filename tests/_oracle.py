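"""Brute-force oracles, independent of the package's closed forms.

`subtree_distribution` enumerates the exact joint distribution of
(observed descendant count, pairs created per generation) for a single
gene entering a chain of events, by direct convolution of child outcomes
-- no moment factorization, no multinomial shortcuts.  Intended for tiny
instances only.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, Sequence, Tuple

State = Tuple[int, Tuple[int, ...]]  # (leaf count, pairs per generation idx..)


def subtree_distribution(events: Sequence, idx: int = 0) -> Dict[State, float]:
    """Exact outcome distribution of one gene entering ``events[idx:]``.

    Keys are ``(m, pairs)`` where ``m`` is the number of observed
    descendants and ``pairs[j]`` the number of surviving pairs whose most
    recent common ancestor was replaced at event ``idx + j``.
    """
    if idx == len(events):
        return {(1, ()): 1.0}
    child = subtree_distribution(events, idx + 1)
    dist: Dict[State, float] = {}
    u = events[idx].survival.u
    for k, uk in enumerate(u):
        if uk == 0.0:
            continue
        # convolve k iid child subtrees, tracking sum of leaves S,
        # sum of squared leaves Q (for same-generation pair counting),
        # and the summed deeper pair vector.
        states: Dict[Tuple[int, int, Tuple[int, ...]], float] = {(0, 0, None): 1.0}  # type: ignore
        for _ in range(k):
            new: Dict = {}
            for (S, Q, pv), p in states.items():
                for (mc, pc), q in child.items():
                    merged = pc if pv is None else tuple(a + b for a, b in zip(pv, pc))
                    key = (S + mc, Q + mc * mc, merged)
                    new[key] = new.get(key, 0.0) + p * q
            states = new
        for (S, Q, pv), p in states.items():
            deeper = pv if pv is not None else tuple(0 for _ in range(len(events) - idx - 1))
            here = (S * S - Q) // 2
            key = (S, (here,) + deeper)
            dist[key] = dist.get(key, 0.0) + uk * p
    return dist


def oracle_expectations(schedule) -> Tuple[float, Tuple[float, ...], float]:
    """(E(M_n), E(N_1..N_{n-1}), E(M*)) by exhaustive enumeration.

    Root families are independent, so expectations scale with M1 and the
    unpaired count is M1 times the probability that a family is reduced
    to a single observed gene.
    """
    events = schedule.wgd_events
    dist = subtree_distribution(events)
    e_m = sum(p * m for (m, _), p in dist.items())
    n_ev = len(events)
    e_pairs = [0.0] * n_ev
    p_single = 0.0
    for (m, pv), p in dist.items():
        for j in range(n_ev):
            e_pairs[j] += p * pv[j]
        if m == 1:
            p_single += p
    m1 = schedule.M1
    return m1 * e_m, tuple(m1 * x for x in e_pairs), m1 * p_single
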