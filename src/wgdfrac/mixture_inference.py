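"""Recovering the similarity mixture: local modes, then constrained EM.

Unconstrained normal-mixture decomposition is unreliable on homolog
similarity data: overlapping, non-normal tails invite spurious extra
components.  The estimation strategy here is therefore anchored: the
component means are identified first as local modes of the (binned,
smoothed) similarity histogram -- possibly reconciled across several
genome comparisons that share events -- and a maximum-likelihood EM then
estimates only the standard deviations and mixing weights with the means
held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import find_peaks
from scipy.stats import norm

from .schedule import ValidationError
from .similarity import MixtureModel

__all__ = [
    "ModeSearchConfig",
    "ModeResult",
    "find_local_modes",
    "FitResult",
    "fit_constrained_mixture",
    "AlignmentResult",
    "shared_mode_alignment",
]


@dataclass(frozen=True)
class ModeSearchConfig:
    """Binning and peak-picking parameters for local-mode detection.

    The bin width trades precision against spurious modes: wide bins give
    smooth histograms whose modes are imprecisely located, narrow bins
    locate modes well but proliferate noise peaks.  Defaults: 0.01
    similarity units per bin, a 5-bin moving-average smoothing window,
    and a minimum peak prominence of 5% of the tallest smoothed bin.
    """

    bin_width: float = 0.01
    window: int = 5
    min_prominence: float = 0.05
    n_components: Optional[Tuple[int, int]] = None  # inclusive (lo, hi) bounds

    def __post_init__(self) -> None:
        if not 0 < self.bin_width <= 0.1:
            raise ValidationError(f"bin width must be in (0, 0.1], got {self.bin_width!r}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValidationError(f"smoothing window must be odd and >= 1, got {self.window!r}")
        if not 0 <= self.min_prominence <= 1:
            raise ValidationError("min_prominence is a fraction of the peak height")
        if self.n_components is not None:
            lo, hi = self.n_components
            if lo < 0 or hi < lo:
                raise ValidationError(f"bad component-count bounds {self.n_components!r}")


@dataclass(frozen=True)
class ModeResult:
    """Ordered local modes with prominence scores and diagnostics."""

    locations: Tuple[float, ...]
    prominences: Tuple[float, ...]
    bin_centers: np.ndarray
    smoothed: np.ndarray
    diagnostic: str = ""

    @property
    def n_modes(self) -> int:
        return len(self.locations)


def find_local_modes(sample: Sequence[float], config: ModeSearchConfig = ModeSearchConfig()) -> ModeResult:
    """Locate candidate component means as local modes of the smoothed
    similarity histogram.

    Returns bin-center locations ordered by similarity.  Adjacent
    equal-height bins (plateaus) resolve to the leftmost bin.  If
    ``config.n_components`` bounds are given and more modes are found,
    only the most prominent are kept; finding fewer than the lower bound
    is reported in the diagnostic rather than forced.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 100:
        raise ValidationError(f"mode detection needs >= 100 observations, got {x.size}")
    n_bins = int(round(1.0 / config.bin_width))
    hist, edges = np.histogram(x, bins=n_bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    if config.window > 1:
        kernel = np.ones(config.window) / config.window
        smoothed = np.convolve(hist.astype(float), kernel, mode="same")
        # edge correction: renormalize by the effective kernel mass
        mass = np.convolve(np.ones_like(hist, dtype=float), kernel, mode="same")
        smoothed = smoothed / mass
    else:
        smoothed = hist.astype(float)

    prom_abs = config.min_prominence * smoothed.max() if smoothed.max() > 0 else 0.0
    peaks, props = find_peaks(smoothed, prominence=max(prom_abs, 1e-12), plateau_size=1)
    # leftmost bin wins on plateaus
    locs = props.get("left_edges", peaks)
    proms = props["prominences"]

    order = np.argsort(locs)
    locs, proms = locs[order], proms[order]
    diagnostic = ""
    if len(locs) == 0:
        diagnostic = "no local modes above the prominence threshold"
    if config.n_components is not None and len(locs) > 0:
        lo, hi = config.n_components
        if len(locs) > hi:
            keep = np.sort(np.argsort(proms)[::-1][:hi])
            locs, proms = locs[keep], proms[keep]
            diagnostic = f"kept the {hi} most prominent of {len(order)} modes"
        elif len(locs) < lo:
            diagnostic = f"found {len(locs)} modes, fewer than the requested minimum {lo}"
    return ModeResult(
        tuple(float(centers[i]) for i in locs),
        tuple(float(p) for p in proms),
        centers,
        smoothed,
        diagnostic,
    )


@dataclass(frozen=True)
class FitResult:
    mixture: MixtureModel
    loglik: float
    n_iter: int
    converged: bool
    flags: Tuple[str, ...] = ()
    loglik_trace: Tuple[float, ...] = ()


def fit_constrained_mixture(
    sample: Sequence[float],
    fixed_means: Sequence[float],
    init_sds: Optional[Sequence[float]] = None,
    init_weights: Optional[Sequence[float]] = None,
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
    sd_floor: float = 1e-4,
    background: bool = False,
    refine_means_within: Optional[float] = None,
) -> FitResult:
    """Maximum-likelihood sds and weights of a normal mixture whose means
    are held fixed (EM).

    The log-likelihood is non-decreasing across iterations; convergence
    is declared when the gain drops below ``tol`` (default 1e-8) or after
    ``max_iter`` iterations.  A component whose sd collapses below
    ``sd_floor`` is floored and flagged.  With ``background=True`` an
    extra uniform component over (0, 1] absorbs unstructured noise.  With
    ``refine_means_within=delta`` the means may drift, but never more
    than ``delta`` from their anchors (off by default).

    Per-component expected counts are ``weight * len(sample)``, rounded.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot fit a mixture to an empty sample")
    if np.any((x <= 0) | (x > 1)):
        raise ValidationError("similarities must lie in (0, 1]")
    means = np.asarray(fixed_means, dtype=float)
    if means.size == 0 or np.any(np.diff(means) <= 0):
        raise ValidationError("fixed means must be non-empty and strictly increasing")
    k = means.size
    anchors = means.copy()

    sds = np.asarray(init_sds, dtype=float) if init_sds is not None else np.full(k, 0.03)
    if sds.size != k or np.any(sds <= 0):
        raise ValidationError("init_sds must be positive and align with means")
    n_free = k + (1 if background else 0)
    if init_weights is not None:
        w = np.asarray(init_weights, dtype=float)
        if background:
            w = np.append(w * (1 - 1.0 / (n_free + 1)), 1.0 / (n_free + 1))
        if w.size != n_free or abs(w.sum() - 1) > 1e-9 or np.any(w < 0):
            raise ValidationError("init_weights must be a probability vector over components")
    else:
        w = np.full(n_free, 1.0 / n_free)

    flags: List[str] = []
    trace: List[float] = []
    prev = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        dens = np.empty((x.size, n_free))
        dens[:, :k] = norm.pdf(x[:, None], loc=means[None, :], scale=sds[None, :])
        if background:
            dens[:, k] = 1.0  # uniform over (0, 1]
        weighted = dens * w[None, :]
        totals = weighted.sum(axis=1)
        totals = np.maximum(totals, 1e-300)
        ll = float(np.log(totals).sum())
        trace.append(ll)
        if ll - prev < tol and n_iter > 1:
            converged = True
            break
        prev = ll
        resp = weighted / totals[:, None]
        nk = resp.sum(axis=0)
        w = nk / x.size
        for j in range(k):
            if nk[j] <= 0:
                continue
            if refine_means_within is not None:
                m = float(resp[:, j] @ x / nk[j])
                means[j] = np.clip(m, anchors[j] - refine_means_within, anchors[j] + refine_means_within)
            var = float(resp[:, j] @ (x - means[j]) ** 2 / nk[j])
            sds[j] = math.sqrt(max(var, 0.0))
            if sds[j] < sd_floor:
                sds[j] = sd_floor
                if f"component {j} sd floored" not in flags:
                    flags.append(f"component {j} sd floored")

    comp_w = w[:k]
    counts = tuple(int(round(float(cw) * x.size)) for cw in comp_w)
    weights = tuple(float(cw) for cw in w)
    if background:
        flags.append(f"uniform background weight {w[k]:.4f}")
        mixture = MixtureModel(tuple(means), tuple(sds), tuple((comp_w / comp_w.sum()).tolist()), counts)
    else:
        mixture = MixtureModel(tuple(means), tuple(sds), weights, counts)
    return FitResult(mixture, trace[-1], n_iter, converged, tuple(flags), tuple(trace))


@dataclass(frozen=True)
class AlignmentResult:
    """Consensus component means shared across genome comparisons."""

    consensus: Tuple[float, ...]
    assignments: Tuple[Tuple[Tuple[float, int], ...], ...]  # per sample: (mode, cluster)
    cluster_sizes: Tuple[int, ...]
    flags: Tuple[str, ...] = ()


def shared_mode_alignment(
    samples: Sequence[Sequence[float]],
    config: ModeSearchConfig = ModeSearchConfig(),
    threshold: float = 0.02,
) -> AlignmentResult:
    """Reconcile per-sample local modes across comparisons that share
    events.

    Modes from all samples are pooled and single-linkage clustered with
    the given similarity-distance threshold; each cluster's consensus
    mean is the median of its members.  A sample contributing two modes
    to one cluster is flagged (ambiguous), never merged away.
    """
    if len(samples) < 2:
        raise ValidationError("shared-mode alignment needs at least two samples")
    per_sample_modes = [find_local_modes(s, config).locations for s in samples]
    pooled = [(m, si) for si, modes in enumerate(per_sample_modes) for m in modes]
    if not pooled:
        return AlignmentResult((), tuple(() for _ in samples), (), ("no modes found",))
    values = np.array([m for m, _ in pooled])
    if values.size == 1:
        labels = np.array([1])
    else:
        z = linkage(values[:, None], method="single")
        labels = fcluster(z, t=threshold, criterion="distance")

    flags: List[str] = []
    consensus: List[float] = []
    sizes: List[int] = []
    cluster_ids = sorted(set(labels), key=lambda c: float(np.median(values[labels == c])))
    remap = {c: i for i, c in enumerate(cluster_ids)}
    for c in cluster_ids:
        members = values[labels == c]
        consensus.append(float(np.median(members)))
        sizes.append(int(members.size))
        samples_in = [si for (m, si), lb in zip(pooled, labels) if lb == c]
        dup = {si for si in samples_in if samples_in.count(si) > 1}
        if dup:
            flags.append(f"cluster at {consensus[-1]:.3f} holds multiple modes from sample(s) {sorted(dup)}")
    assignments: List[Tuple[Tuple[float, int], ...]] = []
    for si in range(len(samples)):
        assignments.append(
            tuple((m, remap[lb]) for (m, sj), lb in zip(pooled, labels) if sj == si)
        )
    return AlignmentResult(tuple(consensus), tuple(assignments), tuple(sizes), tuple(flags))
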