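"""Inverting the pair-count expectations: survival and fractionation rates.

Component proportions from the similarity-mixture fit (optionally plus
the count of unpaired genes) are treated as a multinomial sample over
origin categories whose cell probabilities are the normalized closed-form
expected counts.  Maximizing that likelihood over the per-event pair
survival probabilities ``u`` inverts the model; a per-interval
fractionation rate then follows from the exponential survival law
``u(t) = exp(-rho t)``.

Triplings are fitted under the constraint ``u_3 = u_2**2`` (the chance
that both extra copies survive is the product of the individual chances),
and ``u_0 = 0`` is imposed throughout estimation: both constraints buy
back degrees of freedom, since a comparison offers only as many
independent proportions as it has components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .expectations import (
    expected_ortholog_pairs,
    expected_paralog_pairs,
    expected_unpaired,
    scenario_expected_unpaired,
)
from .schedule import (
    Branch,
    Event,
    EventSchedule,
    SpeciationScenario,
    SurvivalDistribution,
    ValidationError,
    doubling,
    tripling,
)

__all__ = [
    "RateEstimates",
    "SurvivalFit",
    "estimate_survival",
    "rates_from_fit",
    "fractionation_rate",
    "AmplificationFit",
    "estimate_amplification",
    "rate_consistency_report",
]


@dataclass(frozen=True)
class RateEstimates:
    """Per-interval survival probabilities and fractionation rates.

    ``u[j]`` is the pair survival over ``(t_start[j], t_end[j])`` (My
    before present, ``t_start > t_end``) and ``rho[j] = -ln(u[j]) /
    (t_start[j] - t_end[j])`` per My, exactly.
    """

    labels: Tuple[str, ...]
    t_start: Tuple[float, ...]
    t_end: Tuple[float, ...]
    u: Tuple[float, ...]
    rho: Tuple[float, ...]
    constraints: Tuple[str, ...] = ()
    loglik: Optional[float] = None

    def __post_init__(self) -> None:
        k = len(self.labels)
        if not (len(self.t_start) == len(self.t_end) == len(self.u) == len(self.rho) == k):
            raise ValidationError("rate estimate fields must align")
        for u, a, b, r in zip(self.u, self.t_start, self.t_end, self.rho):
            if not 0 < u <= 1:
                raise ValidationError(f"u={u!r} outside (0, 1]")
            if r < 0:
                raise ValidationError(f"rho={r!r} must be >= 0")
            if abs(r - fractionation_rate(u, a, b)) > 1e-9 * max(1.0, abs(r)):
                raise ValidationError("rho must equal -ln(u)/(t_start - t_end)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval": list(self.labels),
                "interval_start_My": list(self.t_start),
                "interval_end_My": list(self.t_end),
                "u_hat": list(self.u),
                "rho_hat_per_My": list(self.rho),
                "constraints": ";".join(self.constraints) or "",
                "loglik": self.loglik if self.loglik is not None else math.nan,
            }
        )


def fractionation_rate(u: float, t_start: float, t_end: float) -> float:
    """Fractionation rate per My over an interval: rho = -ln(u) / dt.

    ``t_start`` and ``t_end`` are My before present with
    ``t_start > t_end``; ``u`` is the pair survival over the interval.
    """
    if not 0 < u <= 1:
        raise ValidationError(f"survival u={u!r} must be in (0, 1]")
    dt = t_start - t_end
    if dt <= 0:
        raise ValidationError(f"zero-length or inverted interval ({t_start}, {t_end})")
    return -math.log(u) / dt


# -- survival estimation -----------------------------------------------------------


def _with_free_u(model, theta: np.ndarray):
    """Rebuild the skeleton with the free survival parameters plugged in.

    One parameter per pair-generating event: each WGD's u_2 (with
    u_3 = u_2**2 for triplings, u_0 = 0), plus the speciation u_2 for a
    coupled scenario.  Branch WGD survivals amplify every ortholog
    category equally, cancel from the proportions, and therefore stay at
    their skeleton values.
    """

    def rebuilt(e: Event, u2: float) -> Event:
        d = doubling(u2) if e.survival.r == 2 else tripling(u2)
        return replace(e, survival=d)

    if isinstance(model, SpeciationScenario):
        k = len(model.pre_events)
        pre = tuple(rebuilt(e, theta[i]) for i, e in enumerate(model.pre_events))
        if model.mode == "coupled":
            spec = replace(model.speciation, survival=doubling(theta[k]))
            return replace(model, pre_events=pre, speciation=spec)
        qa = qb = theta[k]  # shared post-speciation copy survival
        return replace(
            model,
            pre_events=pre,
            branch_a=replace(model.branch_a, copy_survival=qa),
            branch_b=replace(model.branch_b, copy_survival=qb),
        )
    events = tuple(
        rebuilt(e, theta[i]) for i, e in enumerate(model.wgd_events)
    ) + (model.events[-1],)
    return replace(model, events=events)


def _n_free(model) -> int:
    if isinstance(model, SpeciationScenario):
        return len(model.pre_events) + 1
    return len(model.wgd_events)


def _cell_expectations(model, include_unpaired: bool) -> np.ndarray:
    if isinstance(model, SpeciationScenario):
        summary = expected_ortholog_pairs(model)
        cells = list(summary.pairs)
        if include_unpaired:
            cells.append(scenario_expected_unpaired(model))
    else:
        summary = expected_paralog_pairs(model)
        cells = list(summary.pairs)
        if include_unpaired:
            cells.append(expected_unpaired(model))
    return np.asarray(cells, dtype=float)


@dataclass(frozen=True)
class SurvivalFit:
    """Maximum-likelihood survival probabilities for a skeleton model."""

    model: Union[EventSchedule, SpeciationScenario]
    u: Dict[str, float]  # per pair-generating event, keyed by label
    loglik: float
    flags: Tuple[str, ...] = ()

    @property
    def fitted_model(self):
        return _with_free_u(self.model, np.array(list(self.u.values())))


def _event_keys(model) -> List[str]:
    if isinstance(model, SpeciationScenario):
        return [f"wgd{i+1}" for i in range(len(model.pre_events))] + ["speciation"]
    return [f"wgd{i+1}" for i in range(len(model.wgd_events))]


def estimate_survival(
    observed_counts: Union[Mapping[int, float], Sequence[float]],
    skeleton: Union[EventSchedule, SpeciationScenario],
    *,
    unpaired: Optional[float] = None,
    seed: int = 0,
    n_restarts: int = 10,
) -> SurvivalFit:
    """Maximum-likelihood survival probabilities from origin-category
    counts.

    ``observed_counts`` holds one count per pair-generating event of the
    skeleton (oldest first, or keyed by origin generation); ``unpaired``
    optionally adds the no-partner gene count as an extra multinomial
    cell, which is what makes two-event comparisons identifiable.  The
    cell probabilities are the normalized expected counts of the skeleton
    with the candidate ``u`` plugged in; optimization is bounded
    quasi-Newton with seeded random restarts, guarding against the flat
    ridges this likelihood develops when components overlap.
    """
    keys = _event_keys(skeleton)
    if isinstance(observed_counts, Mapping):
        counts = [float(observed_counts[g]) for g in sorted(observed_counts)]
    else:
        counts = [float(c) for c in observed_counts]
    if len(counts) != len(keys):
        raise ValidationError(
            f"need one count per pair-generating event ({len(keys)}), got {len(counts)}"
        )
    include_unpaired = unpaired is not None
    cells = np.asarray(counts + ([float(unpaired)] if include_unpaired else []))
    if np.any(cells < 0):
        raise ValidationError("counts must be >= 0")
    n_params = _n_free(skeleton)
    n_indep = len(cells) - 1
    if n_params > n_indep:
        raise ValidationError(
            f"{n_params} free survival parameters but only {n_indep} independent "
            f"proportions; supply the unpaired-gene count or fix parameters"
        )

    def nll(theta: np.ndarray) -> float:
        try:
            expect = _cell_expectations(_with_free_u(skeleton, theta), include_unpaired)
        except ValidationError:
            return 1e12
        total = expect.sum()
        if not np.isfinite(total) or total <= 0:
            return 1e12
        p = np.maximum(expect / total, 1e-300)
        return -float(cells @ np.log(p))

    rng = np.random.default_rng(seed)
    bounds = [(1e-6, 1.0)] * n_params
    best = None
    starts = [np.full(n_params, 0.5)] + [
        rng.uniform(0.05, 0.95, size=n_params) for _ in range(max(0, n_restarts - 1))
    ]
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    flags = []
    if not best.success:
        flags.append(f"optimizer: {best.message}")
    u = {k: float(v) for k, v in zip(keys, best.x)}
    for k, e in zip(keys, getattr(skeleton, "pre_events", getattr(skeleton, "wgd_events", ()))):
        if e.survival is not None and e.survival.r == 3:
            flags.append(f"{k}: tripling constrained u3 = u2^2")
    return SurvivalFit(skeleton, u, -best.fun, tuple(flags))


def rates_from_fit(fit: SurvivalFit) -> RateEstimates:
    """Turn fitted survivals into per-interval fractionation rates.

    Each event's survival applies over the interval from that event to
    the next one (toward the present).  A coupled speciation survival in
    a scenario whose branches first differ in timing is reported once per
    branch under the model presumption of equal rates.
    """
    model = fit.fitted_model
    labels: List[str] = []
    t0: List[float] = []
    t1: List[float] = []
    us: List[float] = []
    constraints = list(fit.flags)

    if isinstance(model, SpeciationScenario):
        chain = list(model.pre_events) + [model.speciation]
        for key, e, nxt in zip(_event_keys(model)[:-1], chain[:-1], chain[1:]):
            labels.append(key)
            t0.append(e.time)
            t1.append(nxt.time)
            us.append(fit.u[key])
        u_spec = fit.u["speciation"]
        ta = model.branch_a.events[0].time
        tb = model.branch_b.events[0].time
        if ta == tb:
            labels.append("speciation")
            t0.append(model.speciation.time)
            t1.append(ta)
            us.append(u_spec)
        else:
            for lab, t in (("speciation:A", ta), ("speciation:B", tb)):
                labels.append(lab)
                t0.append(model.speciation.time)
                t1.append(t)
                us.append(u_spec)
            constraints.append("asymmetric branch intervals: same u, per-branch rho (rho_A = rho_B presumed)")
    else:
        events = list(model.events)
        for key, e, nxt in zip(_event_keys(model), events[:-1], events[1:]):
            labels.append(key)
            t0.append(e.time)
            t1.append(nxt.time)
            us.append(fit.u[key])

    rho = [fractionation_rate(u, a, b) for u, a, b in zip(us, t0, t1)]
    return RateEstimates(
        tuple(labels), tuple(t0), tuple(t1), tuple(us), tuple(rho), tuple(constraints), fit.loglik
    )


# -- amplification and consistency ---------------------------------------------------


@dataclass(frozen=True)
class AmplificationFit:
    """Least-squares through-origin slope of counts-vs-A on counts-vs-outgroup."""

    factor: float
    se: float
    n: int


def estimate_amplification(
    pair_counts_vs_a: Sequence[float], pair_counts_vs_outgroup: Sequence[float]
) -> AmplificationFit:
    """Amplification factor F_A of a lineage's post-speciation WGDs.

    A WGD in species A multiplies the expected ortholog pair count of
    every comparison against A by the same factor, so plotting counts in
    comparisons with A against the matching counts in comparisons with an
    unamplified outgroup gives a line through the origin with slope F_A.
    """
    y = np.asarray(pair_counts_vs_a, dtype=float)
    x = np.asarray(pair_counts_vs_outgroup, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValidationError("need >= 2 paired comparisons")
    if np.all(x == 0):
        raise ValidationError("all outgroup counts are zero; slope undefined")
    sxx = float(x @ x)
    slope = float(x @ y) / sxx
    resid = y - slope * x
    dof = max(x.size - 1, 1)
    se = math.sqrt(float(resid @ resid) / dof / sxx)
    return AmplificationFit(slope, se, int(x.size))


def rate_consistency_report(
    estimates: Sequence[RateEstimates], *, cv_threshold: float = 0.25
) -> pd.DataFrame:
    """Spread of fractionation-rate estimates across comparisons.

    Groups rates by interval label and reports mean, range and
    coefficient of variation; intervals whose CV exceeds the threshold
    are flagged as violating the presumption that the same rate holds
    across genomes (rho = rho_A = rho_B).
    """
    if not estimates:
        raise ValidationError("no rate estimates supplied")
    rows: Dict[str, List[float]] = {}
    for est in estimates:
        for lab, r in zip(est.labels, est.rho):
            rows.setdefault(lab, []).append(float(r))
    out = []
    for lab, vals in rows.items():
        v = np.asarray(vals)
        mean = float(v.mean())
        rng_ = float(v.max() - v.min())
        cv = float(v.std(ddof=1) / mean) if v.size > 1 and mean > 0 else 0.0
        out.append(
            {
                "interval": lab,
                "n_comparisons": v.size,
                "rho_mean": mean,
                "rho_range": rng_,
                "rho_cv": cv,
                "flagged": bool(cv > cv_threshold),
            }
        )
    return pd.DataFrame(out)
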