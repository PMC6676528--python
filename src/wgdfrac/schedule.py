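"""Event schedules for whole-genome multiplication and fractionation.

The population of genes in a genome evolves through a succession of
whole-genome doublings or triplings (WGD/WGT).  Immediately after an event
of ploidy ``r`` every gene has ``r`` copies; in the interval before the
next event, fractionation removes copies.  The number of copies of a gene
that survive to the next event is drawn from a *survival distribution*
``u = (u_0, ..., u_r)``, so the whole process is a discrete-generation
branching process in which the offspring distribution is reinterpreted as
a per-interval survival distribution.

This module holds the domain types shared by every other module:

* :class:`SurvivalDistribution` -- the per-event survival law,
* :class:`Event` / :class:`EventSchedule` -- an ordered series of events
  with times in millions of years (My) before present,
* :class:`Branch` / :class:`SpeciationScenario` -- a shared pre-speciation
  history followed by two independently fractionating genomes,

plus the two classical branching-process operations: offspring moments and
the probability of eventual lineage extinction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ValidationError",
    "SurvivalDistribution",
    "doubling",
    "tripling",
    "Event",
    "EventSchedule",
    "Branch",
    "SpeciationScenario",
    "derive_offspring_moments",
    "extinction_probability",
    "PROB_SUM_TOL",
]

#: tolerance within which survival probabilities must sum to one; inputs
#: inside the tolerance are renormalized, anything further off is rejected.
PROB_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """An ill-formed distribution, schedule or scenario."""


@dataclass(frozen=True)
class SurvivalDistribution:
    """Survival law of the ``r`` copies created by one genome-level event.

    ``u[k]`` is the probability that exactly ``k`` of the ``r`` copies of a
    gene survive until the next event.  With the optional
    ``no_extinction`` flag the distribution must place zero mass on
    ``k = 0`` ("no lineage extinction").

    Parameters
    ----------
    r:
        Ploidy of the event (2 for a doubling, 3 for a tripling, ...).
    u:
        Sequence of ``r + 1`` probabilities ``(u_0, ..., u_r)``.
    no_extinction:
        If true, require ``u_0 == 0``.
    """

    r: int
    u: Tuple[float, ...]
    no_extinction: bool = False

    def __post_init__(self) -> None:
        if int(self.r) != self.r or self.r < 2:
            raise ValidationError(f"ploidy r must be an integer >= 2, got {self.r!r}")
        object.__setattr__(self, "r", int(self.r))
        u = tuple(float(x) for x in self.u)
        if len(u) != self.r + 1:
            raise ValidationError(
                f"survival vector must have length r+1={self.r + 1}, got {len(u)}"
            )
        for k, x in enumerate(u):
            if not math.isfinite(x) or x < -PROB_SUM_TOL or x > 1 + PROB_SUM_TOL:
                raise ValidationError(f"u_{k}={x!r} outside [0, 1]")
        total = sum(u)
        if abs(total - 1.0) > PROB_SUM_TOL:
            raise ValidationError(
                f"survival probabilities sum to {total!r}, not 1 (tolerance {PROB_SUM_TOL})"
            )
        # renormalize only within tolerance; clip tiny negatives from user arithmetic
        u = tuple(min(max(x, 0.0), 1.0) / total for x in u)
        if self.no_extinction and u[0] != 0.0:
            raise ValidationError("no_extinction requires u_0 = 0")
        object.__setattr__(self, "u", u)

    # -- moments and generating function ------------------------------------

    @property
    def mean(self) -> float:
        """Expected number of surviving copies mu = sum k*u_k."""
        return float(sum(k * x for k, x in enumerate(self.u)))

    @property
    def variance(self) -> float:
        mu = self.mean
        return float(sum((k - mu) ** 2 * x for k, x in enumerate(self.u)))

    @property
    def pair_factor(self) -> float:
        """Expected number of surviving sibling pairs, sum C(k,2)*u_k."""
        return float(sum(math.comb(k, 2) * x for k, x in enumerate(self.u)))

    def gf(self, s: float) -> float:
        """Probability generating function f(s) = sum u_k s^k."""
        return float(sum(x * s**k for k, x in enumerate(self.u)))

    def gf_prime(self, s: float) -> float:
        return float(sum(k * x * s ** (k - 1) for k, x in enumerate(self.u) if k >= 1))


def doubling(u2: float, u0: float = 0.0) -> SurvivalDistribution:
    """Survival distribution of a WGD: both copies survive with ``u2``."""
    return SurvivalDistribution(2, (u0, 1.0 - u0 - u2, u2))


def tripling(u2: float, u3: Optional[float] = None, u0: float = 0.0) -> SurvivalDistribution:
    """Survival distribution of a WGT.

    When ``u3`` is omitted it defaults to ``u2**2``: the chance that two
    extra copies survive is taken to be the product of the individual
    chances, the same constraint used when fitting triplings.
    """
    if u3 is None:
        u3 = u2 * u2
    return SurvivalDistribution(3, (u0, 1.0 - u0 - u2 - u3, u2, u3))


EventKind = Literal["wgd", "speciation", "observation"]


@dataclass(frozen=True)
class Event:
    """A genome-level event at a given time before present (My).

    ``wgd`` events carry a survival distribution.  ``speciation`` events
    may carry an r=2 survival distribution (one copy per daughter genome;
    u_2 is then the probability that *both* genomes retain the gene
    through the following interval).  ``observation`` events carry none.
    """

    kind: EventKind
    time: float
    survival: Optional[SurvivalDistribution] = None

    def __post_init__(self) -> None:
        if self.kind not in ("wgd", "speciation", "observation"):
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if not math.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"event time must be >= 0 My before present, got {self.time!r}")
        if self.kind == "wgd" and self.survival is None:
            raise ValidationError("wgd events require a survival distribution")
        if self.kind == "observation" and self.survival is not None:
            raise ValidationError("observation events carry no survival distribution")
        if self.kind == "speciation" and self.survival is not None and self.survival.r != 2:
            raise ValidationError("speciation survival must have r=2 (one copy per daughter)")


def _check_times_decreasing(events: Sequence[Event], context: str) -> None:
    times = [e.time for e in events]
    for a, b in zip(times, times[1:]):
        if not b < a:
            raise ValidationError(f"{context}: event times must strictly decrease toward the present, got {times}")


@dataclass(frozen=True)
class EventSchedule:
    """An ordered single-genome history: WGDs, then one observation.

    Generation indices are derived: the i-th WGD happens at generation i
    (i = 1..n-1) and the observation is generation n.
    """

    M1: int
    events: Tuple[Event, ...]

    def __post_init__(self) -> None:
        if int(self.M1) != self.M1 or self.M1 < 1:
            raise ValidationError(f"M1 must be an integer >= 1, got {self.M1!r}")
        object.__setattr__(self, "M1", int(self.M1))
        events = tuple(self.events)
        if not events:
            raise ValidationError("schedule needs at least an observation event")
        if events[-1].kind != "observation":
            raise ValidationError("the last event must be the observation")
        for e in events[:-1]:
            if e.kind == "observation":
                raise ValidationError("exactly one observation event, last in the schedule")
            if e.kind == "speciation":
                raise ValidationError("speciation events belong in a SpeciationScenario")
        _check_times_decreasing(events, "schedule")
        object.__setattr__(self, "events", events)

    @property
    def wgd_events(self) -> Tuple[Event, ...]:
        return self.events[:-1]

    @property
    def n_generations(self) -> int:
        """Observation generation n (number of WGDs + 1)."""
        return len(self.events)

    @property
    def wgd_times(self) -> Tuple[float, ...]:
        return tuple(e.time for e in self.wgd_events)

    @property
    def observation_time(self) -> float:
        return self.events[-1].time

    def interval_after(self, i: int) -> Tuple[float, float]:
        """(t_i, t_{i+1}) in My before present for the i-th WGD, 1-based."""
        return (self.events[i - 1].time, self.events[i].time)


@dataclass(frozen=True)
class Branch:
    """Post-speciation history of one daughter genome.

    ``copy_survival`` is the pair-equivalent survival probability of the
    speciation-created gene copy over the interval from speciation to the
    first event of this branch; supplying it on both branches selects the
    independent-fractionation ortholog model.  Leaving it unset on both
    branches selects the coupled model driven by the speciation event's
    own survival distribution.
    """

    events: Tuple[Event, ...]
    copy_survival: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        events = tuple(self.events)
        if not events or events[-1].kind != "observation":
            raise ValidationError(f"branch {self.label or '?'} must end with an observation event")
        for e in events[:-1]:
            if e.kind != "wgd":
                raise ValidationError("branch events before observation must be wgd")
        _check_times_decreasing(events, f"branch {self.label or '?'}")
        if self.copy_survival is not None and not (0.0 <= self.copy_survival <= 1.0):
            raise ValidationError(f"copy_survival must be in [0, 1], got {self.copy_survival!r}")
        object.__setattr__(self, "events", events)

    @property
    def wgd_events(self) -> Tuple[Event, ...]:
        return self.events[:-1]


@dataclass(frozen=True)
class SpeciationScenario:
    """A shared schedule up to a speciation, then two independent genomes.

    Pre-speciation WGDs occupy generations 1..s-1 and the speciation is
    generation s = ``len(pre_events) + 1``.  Each branch then evolves and
    is observed at the present.  Two ortholog-counting models are
    supported:

    * *coupled*: the speciation event carries an r=2 survival
      distribution; ``u_2`` is the probability that both daughter genomes
      keep the gene, and a lone survivor lands in either genome with
      equal probability.
    * *independent*: each branch declares its own ``copy_survival``
      ``u^X(s)`` and the two copies survive independently, each with
      marginal probability ``(1 + u^X(s)) / 2``.
    """

    M1: int
    pre_events: Tuple[Event, ...]
    speciation: Event
    branch_a: Branch
    branch_b: Branch

    def __post_init__(self) -> None:
        if int(self.M1) != self.M1 or self.M1 < 1:
            raise ValidationError(f"M1 must be an integer >= 1, got {self.M1!r}")
        object.__setattr__(self, "M1", int(self.M1))
        pre = tuple(self.pre_events)
        for e in pre:
            if e.kind != "wgd":
                raise ValidationError("pre-speciation events must all be wgd")
        if self.speciation.kind != "speciation":
            raise ValidationError("speciation event required at the end of the shared prefix")
        _check_times_decreasing(pre + (self.speciation,), "shared prefix")
        ba, bb = self.branch_a, self.branch_b
        if not ba.label:
            ba = replace(ba, label="A")
        if not bb.label:
            bb = replace(bb, label="B")
        for br in (ba, bb):
            if br.events[0].time >= self.speciation.time:
                raise ValidationError("speciation time must exceed every post-speciation event time")
        has_copy = (ba.copy_survival is not None, bb.copy_survival is not None)
        if any(has_copy) and not all(has_copy):
            raise ValidationError("copy_survival must be given on both branches or neither")
        if all(has_copy) and self.speciation.survival is not None:
            raise ValidationError(
                "give either a speciation survival distribution (coupled model) "
                "or per-branch copy_survival (independent model), not both"
            )
        if not all(has_copy) and self.speciation.survival is None:
            # default: both copies always retained
            object.__setattr__(self, "speciation", replace(self.speciation, survival=doubling(1.0)))
        object.__setattr__(self, "pre_events", pre)
        object.__setattr__(self, "branch_a", ba)
        object.__setattr__(self, "branch_b", bb)

    # -- derived structure ---------------------------------------------------

    @property
    def s(self) -> int:
        """Generation index of the speciation event."""
        return len(self.pre_events) + 1

    @property
    def mode(self) -> str:
        return "independent" if self.branch_a.copy_survival is not None else "coupled"

    @property
    def copy_retention(self) -> Tuple[float, float]:
        """Marginal probability that the A- (resp. B-) copy survives the
        interval from speciation to the first event of its branch."""
        if self.mode == "independent":
            return (
                (1.0 + float(self.branch_a.copy_survival)) / 2.0,
                (1.0 + float(self.branch_b.copy_survival)) / 2.0,
            )
        u = self.speciation.survival.u  # type: ignore[union-attr]
        q = u[2] + u[1] / 2.0
        return (q, q)

    @property
    def both_retention(self) -> float:
        """Probability that both genomes keep a gene through the first
        post-speciation interval."""
        if self.mode == "independent":
            qa, qb = self.copy_retention
            return qa * qb
        return self.speciation.survival.u[2]  # type: ignore[union-attr]

    def pre_schedule(self) -> EventSchedule:
        """The shared prefix as a plain schedule observed at speciation."""
        obs = Event("observation", self.speciation.time)
        return EventSchedule(self.M1, self.pre_events + (obs,))


# -- operations ---------------------------------------------------------------


def derive_offspring_moments(d: SurvivalDistribution) -> Tuple[float, float]:
    """Mean and variance of the per-gene survivor count.

    Returns ``(mu, sigma2)`` with ``mu = sum k u_k`` and
    ``sigma2 = sum (k - mu)^2 u_k``.
    """
    return d.mean, d.variance


def extinction_probability(d: SurvivalDistribution) -> float:
    """Probability of eventual extinction of a single gene lineage when
    the same survival distribution applies at every generation.

    The answer is the smallest root in [0, 1] of the fixed-point equation
    ``f(s) = s`` of the generating function.  For ``r = 2`` this equals
    ``min(1, (1 - u_1)/u_2 - 1)``; extinction is certain unless
    ``u_0 < u_2``.  Roots are extracted from the companion matrix of the
    polynomial ``f(s) - s`` and polished by Newton iteration, which stays
    robust when the relevant root approaches the double root at
    criticality (mu = 1).
    """
    u = d.u
    if u[0] == 0.0:
        return 0.0
    if d.mean <= 1.0 + 1e-12:
        # subcritical or critical with u_0 > 0: extinction is certain
        return 1.0
    coeffs = list(u)
    coeffs[1] -= 1.0  # f(s) - s
    poly = np.polynomial.Polynomial(coeffs)
    roots = poly.roots()
    real = [r.real for r in roots if abs(r.imag) < 1e-9 and -1e-9 <= r.real <= 1 + 1e-9]
    if not real:  # pragma: no cover - s=1 is always a root
        return 1.0
    q = min(max(min(real), 0.0), 1.0)
    # Newton polish to the requested 1e-12 scale
    for _ in range(100):
        g = d.gf(q) - q
        gp = d.gf_prime(q) - 1.0
        if gp == 0.0:
            break
        step = g / gp
        q -= step
        if abs(step) < 1e-14:
            break
    return float(min(max(q, 0.0), 1.0))
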