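"""The mutational observation model over gene-pair similarities.

A homolog pair created at time ``t`` My before present is observed not as
a labelled pair but as a sequence-similarity score ``p`` in (0, 1].
Because substitutions hit both copies independently at a roughly constant
rate, the expected similarity declines approximately exponentially with
pair age, ``p(t) = C exp(-lambda t)``.  Pairs from one event therefore
cluster around a common mean, and the observed sample is a mixture of
(truncated) normals, one component per pair-creating event, ordered
``p_1 < p_2 < ... `` from oldest to most recent.

The synthetic-data generator couples this observation model to the
branching-process simulator: it realizes pair counts per origin event,
assigns each origin its decay mean and a standard deviation from a linear
sd-vs-mean law, and samples similarities from normals truncated to
(0, 1].  Ground truth (mixture, counts, survival parameters) is returned
alongside the sample for parameter-recovery studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .expectations import PairCountSummary
from .schedule import EventSchedule, SpeciationScenario, ValidationError
from .simulator import simulate_ortholog_batch, simulate_paralog_batch

__all__ = [
    "DecayModel",
    "SdModel",
    "MixtureModel",
    "component_means_from_schedule",
    "generate_similarities",
    "synthesize_dataset",
    "SyntheticDataset",
]


@dataclass(frozen=True)
class DecayModel:
    """Exponential decay of expected similarity with pair age.

    ``mean_similarity(t) = min(amplitude * exp(-rate * t), 1)``.

    The default rate 0.009 per My corresponds to similarity loss at twice
    a typical plant nuclear substitution rate of ~4.5e-3 per site per My
    (both members of a pair mutate).  The default amplitude is 1 (a
    zero-age pair is identical); empirical fits sometimes prefer a larger
    amplitude, which can be configured.
    """

    amplitude: float = 1.0
    rate: float = 0.009  # per My

    def __post_init__(self) -> None:
        if not (self.amplitude > 0 and math.isfinite(self.amplitude)):
            raise ValidationError(f"amplitude must be > 0, got {self.amplitude!r}")
        if not (self.rate > 0 and math.isfinite(self.rate)):
            raise ValidationError(f"rate must be > 0 per My, got {self.rate!r}")

    def mean_similarity(self, t: float) -> float:
        """Expected similarity of a pair of age ``t`` My, clipped to <= 1.
        No lower clip is applied: remote events may decay below any
        detectable similarity, and that is worth seeing."""
        return min(self.amplitude * math.exp(-self.rate * t), 1.0)

    def time_for_similarity(self, p: float) -> float:
        """Invert the decay: age in My at which the mean similarity is p."""
        if not 0 < p <= self.amplitude:
            raise ValidationError(f"similarity {p!r} outside (0, amplitude]")
        return -math.log(p / self.amplitude) / self.rate


@dataclass(frozen=True)
class SdModel:
    """Linear map from a component's mean to its standard deviation.

    Components of recent events (high mean) are empirically tighter than
    old ones, so the default slope is negative: sd = 0.075 - 0.06 * mean,
    i.e. ~0.02 at mean 0.9 and ~0.05 at mean 0.4.  Only used as the
    synthesis default; inference treats each component's sd as free.
    """

    intercept: float = 0.075
    slope: float = -0.06

    def sd(self, mean: float) -> float:
        s = self.intercept + self.slope * mean
        if s <= 0:
            raise ValidationError(
                f"sd model yields non-positive sd {s!r} at mean {mean!r}"
            )
        return s


@dataclass(frozen=True)
class MixtureModel:
    """Ordered similarity-mixture components over (0, 1].

    Means strictly increase (oldest event first); weights sum to one;
    ``counts`` are the (expected or realized) pair counts per component.
    """

    means: Tuple[float, ...]
    sds: Tuple[float, ...]
    weights: Tuple[float, ...]
    counts: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        k = len(self.means)
        if len(self.sds) != k or len(self.weights) != k:
            raise ValidationError("means, sds and weights must align")
        if self.counts is not None and len(self.counts) != k:
            raise ValidationError("counts must align with components")
        if any(not 0 < m < 1 for m in self.means):
            raise ValidationError(f"component means must lie in (0, 1): {self.means}")
        if any(not s > 0 for s in self.sds):
            raise ValidationError("component sds must be > 0")
        if any(b <= a for a, b in zip(self.means, self.means[1:])):
            raise ValidationError(f"component means must strictly increase: {self.means}")
        if any(w < 0 for w in self.weights) or abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("weights must be >= 0 and sum to 1")
        if self.counts is not None and any(c < 0 or int(c) != c for c in self.counts):
            raise ValidationError("counts must be non-negative integers")

    @property
    def n_components(self) -> int:
        return len(self.means)

    def to_frame(self) -> pd.DataFrame:
        d = {
            "mean": list(self.means),
            "sd": list(self.sds),
            "weight": list(self.weights),
        }
        d["count"] = list(self.counts) if self.counts is not None else [math.nan] * len(self.means)
        return pd.DataFrame(d)


def component_means_from_schedule(
    model: Union[EventSchedule, SpeciationScenario], decay: DecayModel = DecayModel()
) -> Tuple[Tuple[int, ...], Tuple[float, ...], Tuple[float, ...]]:
    """Mean similarity of each pair-generating event's component.

    Returns ``(origins, times, means)`` ordered oldest event first, so
    means strictly increase.  For a scenario the pair-generating events
    are the pre-speciation WGDs and the speciation itself (branch WGDs
    amplify ortholog counts but create only within-genome paralogs).
    Events at identical times would make components indistinguishable and
    are rejected.
    """
    if isinstance(model, SpeciationScenario):
        origins = tuple(range(1, model.s + 1))
        times = tuple(e.time for e in model.pre_events) + (model.speciation.time,)
    else:
        origins = tuple(range(1, len(model.wgd_events) + 1))
        times = model.wgd_times
    if len(set(times)) != len(times):
        raise ValidationError(f"pair-generating events share a time, components indistinguishable: {times}")
    means = tuple(decay.mean_similarity(t) for t in times)
    return origins, times, means


def _truncnorm_sample(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_similarities(
    mixture: MixtureModel, n_pairs: int, seed: Union[int, np.random.Generator]
) -> np.ndarray:
    """Draw ``n_pairs`` similarities from the mixture: a component chosen
    by weight, then a normal truncated to (0, 1].  Seeded and
    reproducible."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(int(n_pairs), list(mixture.weights))
    chunks = [
        _truncnorm_sample(rng, m, s, c)
        for m, s, c in zip(mixture.means, mixture.sds, counts)
        if c > 0
    ]
    values = np.concatenate(chunks) if chunks else np.zeros(0)
    rng.shuffle(values)
    return values


@dataclass(frozen=True)
class SyntheticDataset:
    """A synthetic gene-pair similarity table with its ground truth."""

    pairs: pd.DataFrame  # gene_id_1, gene_id_2, similarity, origin_event
    mixture: MixtureModel
    counts: PairCountSummary
    model: Union[EventSchedule, SpeciationScenario]
    unpaired: int

    @property
    def similarities(self) -> np.ndarray:
        return self.pairs["similarity"].to_numpy()


def synthesize_dataset(
    model: Union[EventSchedule, SpeciationScenario],
    decay: DecayModel = DecayModel(),
    sd_model: SdModel = SdModel(),
    *,
    seed: Union[int, np.random.Generator],
    target_pairs: Optional[int] = None,
    scale_m1: bool = True,
) -> SyntheticDataset:
    """Simulate pair counts and dress them in similarity scores.

    The branching process is realized once with ``M1`` root genes; if
    ``target_pairs`` is given and ``scale_m1`` is true, ``M1`` is rescaled
    so the expected total pair count approximates the target.  Each
    realized pair inherits the component mean of its origin event (via
    the decay model) and a standard deviation from the sd model, then a
    similarity truncated to (0, 1].  The stored component counts equal
    the simulator's pair counts exactly.
    """
    from dataclasses import replace as _replace

    from .expectations import expected_ortholog_pairs, expected_paralog_pairs

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    is_scenario = isinstance(model, SpeciationScenario)
    if target_pairs is not None and scale_m1:
        exp = expected_ortholog_pairs(model) if is_scenario else expected_paralog_pairs(model)
        per_root = exp.total_pairs / model.M1
        if per_root <= 0:
            raise ValidationError("model produces no pairs in expectation")
        model = _replace(model, M1=max(1, round(target_pairs / per_root)))

    if is_scenario:
        batch = simulate_ortholog_batch(model, 1, rng)
    else:
        batch = simulate_paralog_batch(model, 1, rng)
    counts = PairCountSummary(
        batch.kind,
        batch.origins,
        batch.times,
        tuple(float(x) for x in batch.pairs[0]),
        unpaired=float(batch.unpaired[0]),
        total_genes=float(batch.total_genes[0]),
    )

    origins, times, means = component_means_from_schedule(model, decay)
    sds = tuple(sd_model.sd(m) for m in means)
    realized = [int(counts.by_origin.get(o, 0)) for o in origins]

    rows: List[pd.DataFrame] = []
    for o, m, s, c in zip(origins, means, sds, realized):
        if c == 0:
            continue
        sims = _truncnorm_sample(rng, m, s, c)
        idx = np.arange(c)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id_1": [f"g{o}_{j}a" for j in idx],
                    "gene_id_2": [f"g{o}_{j}b" for j in idx],
                    "similarity": sims,
                    "origin_event": o,
                }
            )
        )
    if rows:
        pairs = pd.concat(rows, ignore_index=True)
        pairs = pairs.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31 - 1))).reset_index(
            drop=True
        )
    else:
        pairs = pd.DataFrame(columns=["gene_id_1", "gene_id_2", "similarity", "origin_event"])

    total = sum(realized)
    if total == 0:
        raise ValidationError("simulation realized no pairs; increase M1 or survival probabilities")
    keep = [j for j, c in enumerate(realized) if c > 0]
    mixture = MixtureModel(
        tuple(means[j] for j in keep),
        tuple(sds[j] for j in keep),
        tuple(realized[j] / total for j in keep) if total else (),
        counts=tuple(realized[j] for j in keep),
    )
    return SyntheticDataset(pairs, mixture, counts, model, int(counts.unpaired or 0))
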