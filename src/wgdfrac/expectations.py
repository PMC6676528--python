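"""Closed-form expected gene and homolog-pair counts.

All expectations are products of per-event moments.  A gene entering
event ``i`` leaves ``mu_i`` expected copies for the next generation, and
an event with survival law ``u`` creates ``sum C(k,2) u_k`` expected
surviving sibling pairs per gene.  A pair whose most recent common
ancestor was replaced at generation ``i`` (an *i-pair*) then grows as the
product of the squared means of all later events, because the two sides
of the pair fractionate independently.

The multinomial enumeration over full histories (the probability law of
the survivor-count tables) is retained here as well: it is exact but
combinatorial, and serves as an oracle for the product formulas on small
instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .schedule import (
    EventSchedule,
    Event,
    SpeciationScenario,
    SurvivalDistribution,
    ValidationError,
)

__all__ = [
    "PairCountSummary",
    "expected_gene_count",
    "expected_paralog_pairs",
    "expected_unpaired",
    "expected_ortholog_pairs",
    "scenario_expected_unpaired",
    "history_probability",
    "enumerate_histories",
    "constant_doubling_pair_count",
]


@dataclass(frozen=True)
class PairCountSummary:
    """Expected (or realized) homolog pair counts per origin event.

    ``origins`` are generation indices of the pair-creating events,
    oldest first; ``pairs[j]`` is the count of pairs whose most recent
    common ancestor was replaced at ``origins[j]``.  ``unpaired`` counts
    observed genes with no surviving partner, and ``total_genes`` the
    observed population size (for a scenario, summed over both genomes).
    """

    kind: str  # "paralog" | "ortholog"
    origins: Tuple[int, ...]
    times: Tuple[float, ...]
    pairs: Tuple[float, ...]
    unpaired: Optional[float] = None
    total_genes: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("paralog", "ortholog"):
            raise ValidationError(f"kind must be 'paralog' or 'ortholog', got {self.kind!r}")
        if len(self.origins) != len(self.pairs) or len(self.origins) != len(self.times):
            raise ValidationError("origins, times and pairs must align")
        if any(p < 0 for p in self.pairs):
            raise ValidationError("pair counts must be >= 0")
        if self.unpaired is not None and self.unpaired < 0:
            raise ValidationError("unpaired count must be >= 0")

    @property
    def by_origin(self) -> Dict[int, float]:
        return dict(zip(self.origins, self.pairs))

    @property
    def total_pairs(self) -> float:
        return float(sum(self.pairs))

    def to_frame(self) -> pd.DataFrame:
        """Tab-separated report layout: one row per origin event."""
        return pd.DataFrame(
            {
                "origin_event": list(self.origins),
                "time_My": list(self.times),
                "expected_pairs": list(self.pairs),
                "kind": [self.kind] * len(self.origins),
            }
        )


# -- population size and paralog pairs ----------------------------------------


def expected_gene_count(schedule: EventSchedule) -> float:
    """E(M_n): expected observed population size, M1 times the product of
    the per-event survivor means."""
    out = float(schedule.M1)
    for e in schedule.wgd_events:
        out *= e.survival.mean
    return out


def expected_paralog_pairs(schedule: EventSchedule) -> PairCountSummary:
    """Expected i-pair counts E(N_i) for every WGD of a schedule.

    ``E(N_i) = M1 * prod_{j<i} mu_j * (sum_{k>=2} C(k,2) u_k^{(i)})
    * prod_{j>i} mu_j**2``.  For all-doubling schedules with ``u_0 = 0``
    this reduces to the familiar ``u_2``/(1+u_2) product form, and for
    all-tripling schedules to the (3u_3 + u_2)/(1 + 2u_3 + u_2) form.
    """
    wgds = schedule.wgd_events
    if not wgds:
        return PairCountSummary("paralog", (), (), (), expected_unpaired(schedule), float(schedule.M1))
    mus = [e.survival.mean for e in wgds]
    pairs = []
    for i, e in enumerate(wgds):
        before = math.prod(mus[:i])
        after = math.prod(m * m for m in mus[i + 1 :])
        pairs.append(schedule.M1 * before * e.survival.pair_factor * after)
    return PairCountSummary(
        "paralog",
        tuple(range(1, len(wgds) + 1)),
        tuple(e.time for e in wgds),
        tuple(pairs),
        unpaired=expected_unpaired(schedule),
        total_genes=expected_gene_count(schedule),
    )


def expected_unpaired(schedule: EventSchedule) -> float:
    """E(M*): expected observed genes with no surviving partner.

    Equals ``M1 * prod u_1^{(i)}`` -- the expected number of root lineages
    that pass through every event as a single copy.  Exact whenever every
    event has ``u_0 = 0``; with lineage extinction allowed it is a lower
    bound, because a gene can also lose its partners to extinct
    side-branches.
    """
    out = float(schedule.M1)
    for e in schedule.wgd_events:
        out *= e.survival.u[1]
    return out


# -- ortholog pairs ------------------------------------------------------------


def _branch_amplification(branch) -> float:
    out = 1.0
    for e in branch.wgd_events:
        out *= e.survival.mean
    return out


def expected_ortholog_pairs(scenario: SpeciationScenario) -> PairCountSummary:
    """Expected cross-genome i-pair counts E(O_i), i = 1..s.

    The constants are derived from the event structure rather than hard
    coded.  Writing ``q_X`` for the marginal probability that genome X
    retains a gene through the first post-speciation interval and
    ``amp_X`` for the product of survivor means of the branch WGDs:

    * an i-pair existing at speciation (i < s) yields
      ``2 * q_A amp_A * q_B amp_B`` expected cross pairs (two ordered
      genome assignments of its two sides), hence
      ``E(O_i) = 2 N_i^{(s)} q_A q_B amp_A amp_B``;
    * each gene present at speciation yields an s-pair iff both genomes
      retain it: ``E(O_s) = M_s * B * amp_A amp_B`` with ``B`` the
      both-copy retention probability.

    With per-branch copy survivals ``u^X(s)`` this reproduces the 1/2 and
    1/4 amplification-product constants of the independent doubling
    model, and with a coupled speciation survival law it reproduces the
    0.5 / u_2 constants of the speciation-as-event form.
    """
    s = scenario.s
    pre = scenario.pre_events
    mus = [e.survival.mean for e in pre]
    qa, qb = scenario.copy_retention
    amp_a = _branch_amplification(scenario.branch_a)
    amp_b = _branch_amplification(scenario.branch_b)
    cross_amp = qa * amp_a * qb * amp_b

    pairs: List[float] = []
    for i, e in enumerate(pre):  # origin generations 1..s-1
        before = math.prod(mus[:i])
        after = math.prod(m * m for m in mus[i + 1 :])
        n_i_at_s = scenario.M1 * before * e.survival.pair_factor * after
        pairs.append(2.0 * n_i_at_s * cross_amp)
    m_s = scenario.M1 * math.prod(mus)
    pairs.append(m_s * scenario.both_retention * amp_a * amp_b)

    total = m_s * (qa * amp_a + qb * amp_b)  # expected genes over both genomes
    return PairCountSummary(
        "ortholog",
        tuple(range(1, s + 1)),
        tuple(e.time for e in pre) + (scenario.speciation.time,),
        tuple(pairs),
        unpaired=scenario_expected_unpaired(scenario),
        total_genes=total,
    )


def _composed_gf(events: Sequence[Event], x: float) -> Tuple[float, float]:
    """Value and derivative of the composed generating function
    f_1(f_2(...f_k(x))) of a chain of events, innermost last."""
    val, der = x, 1.0
    for e in reversed(events):
        der = e.survival.gf_prime(val) * der
        val = e.survival.gf(val)
    return val, der


def scenario_expected_unpaired(scenario: SpeciationScenario) -> float:
    """Expected observed genes with no cross-genome (ortholog) partner.

    A gene in genome A is unpaired exactly when its whole root family
    left no descendant in genome B.  With ``G`` the generating function
    of the family size at speciation, the expected count is::

        M1 * [ alpha_A G'(c_B) amp_A  +  alpha_B G'(c_A) amp_B ]

    where ``c_X`` is the per-gene probability of leaving no copy in
    genome X, ``alpha_X`` the probability of keeping an X-copy while
    leaving no other-genome copy, and ``amp_X`` the branch amplification.
    Assumes branch events have ``u_0 = 0`` (no loss after the first
    post-speciation interval)."""
    pre = scenario.pre_events
    if scenario.mode == "independent":
        qa, qb = scenario.copy_retention
        alpha_a, c_b = qa * (1.0 - qb), 1.0 - qb
        alpha_b, c_a = qb * (1.0 - qa), 1.0 - qa
    else:
        u = scenario.speciation.survival.u  # type: ignore[union-attr]
        alpha_a = alpha_b = u[1] / 2.0
        c_a = c_b = u[0] + u[1] / 2.0
    amp_a = _branch_amplification(scenario.branch_a)
    amp_b = _branch_amplification(scenario.branch_b)
    _, d_at_cb = _composed_gf(pre, c_b)
    _, d_at_ca = _composed_gf(pre, c_a)
    return scenario.M1 * (alpha_a * d_at_cb * amp_a + alpha_b * d_at_ca * amp_b)


# -- history enumeration (exact oracle) ----------------------------------------

HistoryTable = Sequence[Sequence[int]]


def history_probability(schedule: EventSchedule, a: HistoryTable) -> float:
    """Probability of one full survivor-count history.

    ``a[i-1][j]`` is the number of genes at generation ``i`` of which
    exactly ``j`` copies survive to generation ``i+1``.  The probability
    is the product over generations of the multinomial term
    ``C(M_i; a_0..a_r) * prod_j u_j^{a_j}`` (all survivor classes,
    including ``j = 0``).  Summed over all consistent histories this
    yields one.
    """
    wgds = schedule.wgd_events
    if len(a) != len(wgds):
        raise ValidationError(f"history table needs one row per WGD ({len(wgds)}), got {len(a)}")
    m = schedule.M1
    prob = 1.0
    for event, row in zip(wgds, a):
        r = event.survival.r
        row = [int(x) for x in row]
        if len(row) != r + 1 or any(x < 0 for x in row):
            raise ValidationError(f"history row {row} incompatible with ploidy {r}")
        if sum(row) != m:
            raise ValidationError(f"history row {row} sums to {sum(row)}, expected M_i={m}")
        coef = math.factorial(m)
        for x in row:
            coef //= math.factorial(x)
        term = float(coef)
        for j, x in enumerate(row):
            if x:
                term *= event.survival.u[j] ** x
        prob *= term
        m = sum(j * x for j, x in enumerate(row))
    return prob


def _compositions(total: int, parts: int) -> Iterator[Tuple[int, ...]]:
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def enumerate_histories(
    schedule: EventSchedule,
) -> Iterator[Tuple[Tuple[Tuple[int, ...], ...], float, int]]:
    """Yield every survivor-count history with its probability and final
    population size M_n.  Exponential in the schedule size; intended for
    small instances and oracle tests."""
    wgds = schedule.wgd_events

    def rec(idx: int, m: int, acc: Tuple[Tuple[int, ...], ...]) -> Iterator:
        if idx == len(wgds):
            yield acc, history_probability(schedule, acc), m
            return
        r = wgds[idx].survival.r
        for row in _compositions(m, r + 1):
            m_next = sum(j * x for j, x in enumerate(row))
            yield from rec(idx + 1, m_next, acc + (row,))

    yield from rec(0, schedule.M1, ())


def constant_doubling_pair_count(n_events: int, i: int, u: float) -> float:
    """Closed form E(N_i) = u (1+u)**(2*n_events - i - 1) for a history of
    ``n_events`` doublings that all share pair survival ``u`` (u_0 = 0)."""
    if not 1 <= i <= n_events:
        raise ValidationError(f"origin index i={i} outside 1..{n_events}")
    return u * (1.0 + u) ** (2 * n_events - i - 1)
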