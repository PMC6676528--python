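"""Monte-Carlo realization of the fractionation branching process.

Two layers share one sampling model:

* :func:`simulate_schedule` / :func:`simulate_scenario` build a single
  :class:`GeneTree` that can be inspected, counted
  (:func:`count_pairs`) and exported to Newick;
* :func:`simulate_paralog_batch` / :func:`simulate_ortholog_batch` run
  many independent replicates through flat numpy arrays and return
  per-replicate pair counts.  These are the oracle used to check every
  closed-form expectation, and the engine behind the synthetic-data
  generator.

Survivor counts are drawn directly from the categorical survival law of
each event (not by thinning independent per-copy Bernoullis): the law is
a survival distribution, and which of the ``r`` progeny survive is
irrelevant to pair counting by most recent common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .expectations import PairCountSummary
from .schedule import Branch, Event, EventSchedule, SpeciationScenario, ValidationError

__all__ = [
    "GeneTree",
    "simulate_schedule",
    "simulate_scenario",
    "count_pairs",
    "to_newick",
    "BatchPairCounts",
    "simulate_paralog_batch",
    "simulate_ortholog_batch",
]


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValidationError("a seed is mandatory: simulations must be reproducible")
    return np.random.default_rng(seed)


def _survivor_draw(rng: np.random.Generator, event: Event, size: int) -> np.ndarray:
    u = np.asarray(event.survival.u)
    return rng.choice(len(u), size=size, p=u)


@dataclass
class _Section:
    """One contiguous stretch of generations of a tree or batch.

    ``parents[g]`` maps each gene of level ``g+1`` to its parent index in
    level ``g``; ``sizes[g]`` is the population of level ``g``.  Level 0
    of the shared section holds the roots; level 0 of a branch section
    holds the surviving speciation copies, whose indices into the
    speciation population are in ``base``.
    """

    sizes: List[int] = field(default_factory=list)
    parents: List[np.ndarray] = field(default_factory=list)
    base: Optional[np.ndarray] = None


@dataclass
class GeneTree:
    """A realized gene forest (one replicate).

    For a plain schedule only ``shared`` is populated; for a speciation
    scenario the two daughter genomes continue in ``branches['A']`` and
    ``branches['B']``.  Leaf genes live in the last level of the last
    section of their genome.
    """

    model: Union[EventSchedule, SpeciationScenario]
    shared: _Section
    branches: Dict[str, _Section] = field(default_factory=dict)

    @property
    def is_scenario(self) -> bool:
        return bool(self.branches)

    @property
    def n_leaves(self) -> int:
        if not self.is_scenario:
            return self.shared.sizes[-1]
        return sum(sec.sizes[-1] for sec in self.branches.values())


def _run_section(
    rng: np.random.Generator, events: Tuple[Event, ...], n_start: int
) -> _Section:
    sec = _Section(sizes=[n_start])
    m = n_start
    for e in events:
        k = _survivor_draw(rng, e, m)
        sec.parents.append(np.repeat(np.arange(m), k))
        m = int(k.sum())
        sec.sizes.append(m)
    return sec


def simulate_schedule(schedule: EventSchedule, seed: Union[int, np.random.Generator]) -> GeneTree:
    """One realization of the paralog process; identical seeds give
    identical trees."""
    rng = _rng(seed)
    return GeneTree(schedule, _run_section(rng, schedule.wgd_events, schedule.M1))


def _speciation_split(
    rng: np.random.Generator, scenario: SpeciationScenario, m: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean masks (has_a, has_b) over the speciation population."""
    if scenario.mode == "independent":
        qa, qb = scenario.copy_retention
        return rng.random(m) < qa, rng.random(m) < qb
    k = _survivor_draw(rng, scenario.speciation, m)
    coin = rng.random(m) < 0.5
    has_a = (k == 2) | ((k == 1) & coin)
    has_b = (k == 2) | ((k == 1) & ~coin)
    return has_a, has_b


def simulate_scenario(scenario: SpeciationScenario, seed: Union[int, np.random.Generator]) -> GeneTree:
    """One realization of the speciation process: a shared pre-speciation
    forest, a copy of every surviving gene into each daughter genome, and
    independent post-speciation evolution of the two genomes."""
    rng = _rng(seed)
    shared = _run_section(rng, scenario.pre_events, scenario.M1)
    m_s = shared.sizes[-1]
    has_a, has_b = _speciation_split(rng, scenario, m_s)
    tree = GeneTree(scenario, shared)
    for label, mask, branch in (
        ("A", has_a, scenario.branch_a),
        ("B", has_b, scenario.branch_b),
    ):
        base = np.flatnonzero(mask)
        sec = _run_section(rng, branch.wgd_events, len(base))
        sec.base = base
        tree.branches[label] = sec
    return tree


# -- counting -------------------------------------------------------------------


def _descend(sec: _Section, leaf_values: np.ndarray) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    """Backward pass: per-level descendant totals and per-level sums of
    squared (or product) child contributions, for pair counting."""
    desc = [np.zeros(0)] * len(sec.sizes)
    desc[-1] = leaf_values.astype(float)
    child_sq = [np.zeros(0)] * (len(sec.sizes) - 1)
    for g in range(len(sec.sizes) - 2, -1, -1):
        par = sec.parents[g]
        desc[g] = np.bincount(par, weights=desc[g + 1], minlength=sec.sizes[g])
        child_sq[g] = np.bincount(par, weights=desc[g + 1] ** 2, minlength=sec.sizes[g])
    return desc, child_sq


def _descend_cross(
    sec: _Section, leaf_a: np.ndarray, leaf_b: np.ndarray
) -> Tuple[List[np.ndarray], List[np.ndarray], List[np.ndarray]]:
    da = [np.zeros(0)] * len(sec.sizes)
    db = [np.zeros(0)] * len(sec.sizes)
    cross = [np.zeros(0)] * (len(sec.sizes) - 1)
    da[-1], db[-1] = leaf_a.astype(float), leaf_b.astype(float)
    for g in range(len(sec.sizes) - 2, -1, -1):
        par = sec.parents[g]
        da[g] = np.bincount(par, weights=da[g + 1], minlength=sec.sizes[g])
        db[g] = np.bincount(par, weights=db[g + 1], minlength=sec.sizes[g])
        cross[g] = np.bincount(par, weights=da[g + 1] * db[g + 1], minlength=sec.sizes[g])
    return da, db, cross


def count_pairs(tree: GeneTree) -> PairCountSummary:
    """Observed pair counts grouped by origin generation.

    Paralog trees: pairs of leaves whose most recent common ancestor was
    replaced at generation i, plus the count of unpaired leaves (root
    families reduced to a single leaf).  Scenario trees: cross-genome
    (ortholog) pairs grouped by origin, where a family leaf-less in one
    genome leaves its other-genome leaves unpaired.
    """
    if not tree.is_scenario:
        schedule: EventSchedule = tree.model  # type: ignore[assignment]
        sec = tree.shared
        leaves = np.ones(sec.sizes[-1])
        desc, child_sq = _descend(sec, leaves)
        pairs = []
        for g in range(len(sec.parents)):  # event generation g+1
            pairs.append(float(((desc[g] ** 2 - child_sq[g]) / 2.0).sum()))
        unpaired = float((desc[0] == 1).sum())
        return PairCountSummary(
            "paralog",
            tuple(range(1, len(sec.parents) + 1)),
            tuple(e.time for e in schedule.wgd_events),
            tuple(pairs),
            unpaired=unpaired,
            total_genes=float(sec.sizes[-1]),
        )

    scenario: SpeciationScenario = tree.model  # type: ignore[assignment]
    m_s = tree.shared.sizes[-1]
    per_copy: Dict[str, np.ndarray] = {}
    for label, sec in tree.branches.items():
        desc, _ = _descend(sec, np.ones(sec.sizes[-1]))
        at_spec = np.zeros(m_s)
        if len(sec.base):
            at_spec[sec.base] = desc[0] if len(desc[0]) else np.zeros(len(sec.base))
        per_copy[label] = at_spec
    da_s, db_s = per_copy["A"], per_copy["B"]

    da, db, cross = _descend_cross(tree.shared, da_s, db_s)
    pairs = []
    for g in range(len(tree.shared.parents)):
        pairs.append(float((da[g] * db[g] - cross[g]).sum()))
    pairs.append(float((da_s * db_s).sum()))  # s-pairs: one copy in each genome
    unpaired = float((da[0] * (db[0] == 0)).sum() + (db[0] * (da[0] == 0)).sum())
    return PairCountSummary(
        "ortholog",
        tuple(range(1, scenario.s + 1)),
        tuple(e.time for e in scenario.pre_events) + (scenario.speciation.time,),
        tuple(pairs),
        unpaired=unpaired,
        total_genes=float(da_s.sum() + db_s.sum()),
    )


# -- newick export ---------------------------------------------------------------


def to_newick(tree: GeneTree) -> str:
    """Serialize a realized tree as a Newick forest (one line per root
    family), with branch lengths equal to inter-event intervals in My and
    leaves labelled ``genome:gene<index>``."""
    from Bio import Phylo
    from Bio.Phylo.Newick import Clade, Tree

    def section_times(events: Tuple[Event, ...], start: float, end: float) -> List[float]:
        return [start] + [e.time for e in events] + [end]

    if not tree.is_scenario:
        schedule: EventSchedule = tree.model  # type: ignore[assignment]
        times = [e.time for e in schedule.events]
        clades = _section_clades(tree.shared, times, lambda g, i: f"S:gene{i}")
    else:
        scenario: SpeciationScenario = tree.model  # type: ignore[assignment]
        pre_times = [e.time for e in scenario.pre_events] + [scenario.speciation.time]
        branch_clades: Dict[str, List[Optional[Clade]]] = {}
        for label, sec in tree.branches.items():
            br = scenario.branch_a if label == "A" else scenario.branch_b
            times = [scenario.speciation.time] + [e.time for e in br.events]
            leaf_clades = _section_clades(sec, times, lambda g, i, lb=label: f"{lb}:gene{i}")
            spec_level: List[Optional[Clade]] = [None] * tree.shared.sizes[-1]
            for j, idx in enumerate(sec.base if sec.base is not None else []):
                spec_level[idx] = leaf_clades[j]
            branch_clades[label] = spec_level
        merged: List[Clade] = []
        for i in range(tree.shared.sizes[-1]):
            kids = [c for c in (branch_clades["A"][i], branch_clades["B"][i]) if c is not None]
            node = Clade(branch_length=None, clades=kids)
            merged.append(node)
        clades = _collapse_shared(tree.shared, pre_times, merged)

    out = StringIO()
    Phylo.write([Tree(root=c, rooted=True) for c in clades], out, "newick")
    return out.getvalue()


def _section_clades(sec: _Section, times: List[float], leaf_name) -> List["object"]:
    from Bio.Phylo.Newick import Clade

    n_levels = len(sec.sizes)
    level: List[Clade] = [
        Clade(name=leaf_name(n_levels - 1, i), branch_length=None) for i in range(sec.sizes[-1])
    ]
    for g in range(n_levels - 2, -1, -1):
        dt = times[g] - times[g + 1]
        for c in level:
            c.branch_length = dt
        parents = [Clade(clades=[]) for _ in range(sec.sizes[g])]
        for child_idx, par_idx in enumerate(sec.parents[g]):
            parents[par_idx].clades.append(level[child_idx])
        level = parents
    return level


def _collapse_shared(sec: _Section, times: List[float], leaf_nodes: List["object"]):
    from Bio.Phylo.Newick import Clade

    level = leaf_nodes
    for g in range(len(sec.sizes) - 2, -1, -1):
        dt = times[g] - times[g + 1]
        for c in level:
            c.branch_length = dt
        parents = [Clade(clades=[]) for _ in range(sec.sizes[g])]
        for child_idx, par_idx in enumerate(sec.parents[g]):
            parents[par_idx].clades.append(level[child_idx])
        level = parents
    return level


# -- vectorized batches -----------------------------------------------------------


@dataclass
class BatchPairCounts:
    """Per-replicate pair counts from a vectorized simulation.

    ``pairs`` has shape (replicates, origins).  ``mean_summary`` averages
    into a :class:`PairCountSummary`; ``sem`` gives the Monte-Carlo
    standard error of each origin's mean.
    """

    kind: str
    origins: Tuple[int, ...]
    times: Tuple[float, ...]
    pairs: np.ndarray
    total_genes: np.ndarray
    unpaired: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.pairs.shape[0]

    def mean_summary(self) -> PairCountSummary:
        return PairCountSummary(
            self.kind,
            self.origins,
            self.times,
            tuple(self.pairs.mean(axis=0)),
            unpaired=float(self.unpaired.mean()),
            total_genes=float(self.total_genes.mean()),
        )

    def sem(self) -> np.ndarray:
        return self.pairs.std(axis=0, ddof=1) / np.sqrt(self.n_replicates)

    def sem_unpaired(self) -> float:
        return float(self.unpaired.std(ddof=1) / np.sqrt(self.n_replicates))

    def sem_total(self) -> float:
        return float(self.total_genes.std(ddof=1) / np.sqrt(self.n_replicates))


def _forward(
    rng: np.random.Generator, events: Tuple[Event, ...], rep: np.ndarray
) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    """Flat forward pass over all replicates at once.  Returns per-level
    replicate ids and parent pointers."""
    reps = [rep]
    parents: List[np.ndarray] = []
    for e in events:
        k = _survivor_draw(rng, e, len(reps[-1]))
        parents.append(np.repeat(np.arange(len(reps[-1])), k))
        reps.append(np.repeat(reps[-1], k))
    return reps, parents


def simulate_paralog_batch(
    schedule: EventSchedule, n_replicates: int, seed: Union[int, np.random.Generator]
) -> BatchPairCounts:
    """Simulate ``n_replicates`` independent paralog forests and count
    i-pairs, observed genes and unpaired genes in each."""
    rng = _rng(seed)
    n_rep = int(n_replicates)
    rep0 = np.repeat(np.arange(n_rep), schedule.M1)
    reps, parents = _forward(rng, schedule.wgd_events, rep0)

    n_events = len(parents)
    desc = np.ones(len(reps[-1]))
    pair_cols = [np.zeros(n_rep)] * n_events
    for g in range(n_events - 1, -1, -1):
        size = len(reps[g])
        up = np.bincount(parents[g], weights=desc, minlength=size)
        sq = np.bincount(parents[g], weights=desc**2, minlength=size)
        per_gene = (up**2 - sq) / 2.0
        pair_cols[g] = np.bincount(reps[g], weights=per_gene, minlength=n_rep)
        desc = up
    total = np.bincount(reps[-1], minlength=n_rep).astype(float)
    unpaired = np.bincount(rep0, weights=(desc == 1), minlength=n_rep)
    pairs = np.column_stack(pair_cols) if n_events else np.zeros((n_rep, 0))
    return BatchPairCounts(
        "paralog",
        tuple(range(1, n_events + 1)),
        tuple(e.time for e in schedule.wgd_events),
        pairs,
        total,
        unpaired,
    )


def simulate_ortholog_batch(
    scenario: SpeciationScenario, n_replicates: int, seed: Union[int, np.random.Generator]
) -> BatchPairCounts:
    """Simulate ``n_replicates`` independent speciation scenarios and
    count cross-genome pairs by origin generation (1..s), total observed
    genes (both genomes) and genes with no ortholog partner."""
    rng = _rng(seed)
    n_rep = int(n_replicates)
    rep0 = np.repeat(np.arange(n_rep), scenario.M1)
    reps, parents = _forward(rng, scenario.pre_events, rep0)
    m_s = len(reps[-1])

    has_a, has_b = _speciation_split(rng, scenario, m_s)

    per_copy: Dict[str, np.ndarray] = {}
    for mask, branch in ((has_a, scenario.branch_a), (has_b, scenario.branch_b)):
        base = np.flatnonzero(mask)
        b_reps, b_parents = _forward(rng, branch.wgd_events, reps[-1][base])
        desc = np.ones(len(b_reps[-1]))
        for g in range(len(b_parents) - 1, -1, -1):
            desc = np.bincount(b_parents[g], weights=desc, minlength=len(b_reps[g]))
        at_spec = np.zeros(m_s)
        at_spec[base] = desc
        per_copy[branch.label] = at_spec
    da, db = per_copy["A"], per_copy["B"]

    n_pre = len(parents)
    pair_cols = [np.zeros(n_rep)] * (n_pre + 1)
    pair_cols[n_pre] = np.bincount(reps[-1], weights=da * db, minlength=n_rep)
    total = np.bincount(reps[-1], weights=da + db, minlength=n_rep)
    cur_a, cur_b = da, db
    for g in range(n_pre - 1, -1, -1):
        size = len(reps[g])
        up_a = np.bincount(parents[g], weights=cur_a, minlength=size)
        up_b = np.bincount(parents[g], weights=cur_b, minlength=size)
        cross = np.bincount(parents[g], weights=cur_a * cur_b, minlength=size)
        pair_cols[g] = np.bincount(reps[g], weights=up_a * up_b - cross, minlength=n_rep)
        cur_a, cur_b = up_a, up_b
    unpaired = np.bincount(
        rep0, weights=cur_a * (cur_b == 0) + cur_b * (cur_a == 0), minlength=n_rep
    )
    pairs = np.column_stack(pair_cols)
    return BatchPairCounts(
        "ortholog",
        tuple(range(1, scenario.s + 1)),
        tuple(e.time for e in scenario.pre_events) + (scenario.speciation.time,),
        pairs,
        total,
        unpaired,
    )
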