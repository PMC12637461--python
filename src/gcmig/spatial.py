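"""Follicle-sharing statistics, well-mixed nulls and spatial locality.

Stage 1 of the pipeline: how many follicles does each lineage span, is the
arrangement compatible with a fully mixed tonsil, and are related cells in
different follicles closer together than unrelated ones?
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from gcmig.repertoire import (
    FollicleMap,
    RepertoireError,
    follicle_map_from_records,
)


@dataclass
class FollicleCountHistogram:
    """Lineages per distinct-follicle count, with sqrt(n) counting errors."""

    counts: dict            # k -> number of lineages
    errors: dict            # k -> sqrt(count)
    p_geom: Optional[float] = None

    @property
    def n_lineages(self) -> int:
        return sum(self.counts.values())


@dataclass
class ShuffleResult:
    observed_k_counts: dict                 # k -> lineage count
    shuffled_k_counts: list                 # per-rep dicts
    shuffled_mean: dict                     # k -> mean over reps
    shuffled_sem: dict                      # k -> SEM over reps
    observed_sizes_by_k: dict               # k -> list of per-lineage UMI counts
    shuffled_size_hists: dict               # k -> {size: (mean, sem)} over reps


@dataclass
class DistanceDistribution:
    related: np.ndarray                     # normalized related cross-follicle distances
    background: np.ndarray                  # normalized unrelated cross-follicle distances
    normalizer: float                       # median intra-follicle distance (micrometres)
    tail_fraction: float = float("nan")     # related pairs >= background median
    empty: bool = False

    @property
    def related_median(self) -> float:
        return float(np.median(self.related)) if len(self.related) else float("nan")

    @property
    def background_median(self) -> float:
        return float(np.median(self.background)) if len(self.background) else float("nan")


# ---------------------------------------------------------------------------

def follicle_count_histogram(records) -> FollicleCountHistogram:
    """Distribution of distinct-follicle counts over intrafollicular lineages."""
    follicles: dict[int, set] = {}
    for rec in records:
        if rec.lineage_id is None:
            raise RepertoireError("lineage_id not assigned")
        if rec.intrafollicular:
            follicles.setdefault(rec.lineage_id, set()).add(rec.follicle_id)
    if not follicles:
        raise RepertoireError("no intrafollicular records")
    counts: dict[int, int] = {}
    for fset in follicles.values():
        k = len(fset)
        counts[k] = counts.get(k, 0) + 1
    errors = {k: math.sqrt(n) for k, n in counts.items()}
    return FollicleCountHistogram(counts=dict(sorted(counts.items())),
                                  errors=errors)


def fit_truncated_geometric(hist: FollicleCountHistogram, k_max: int = 4) -> float:
    """Conditional MLE of p for P(k | k <= k_max) ∝ p^(k-1) (1-p).

    Fitted to the first ``k_max`` bins only, matching the exponential region
    of the follicle-count distribution. Bounded scalar search on p ∈ [0, 1).
    """
    data = {k: n for k, n in hist.counts.items() if 1 <= k <= k_max and n > 0}
    if not data:
        raise RepertoireError(f"no histogram mass at k <= {k_max}")
    total = sum(data.values())
    sum_km1 = sum((k - 1) * n for k, n in data.items())
    if sum_km1 == 0:
        return 0.0  # all mass at k=1: degenerate MLE

    def nll(p: float) -> float:
        z = 1.0 - p ** k_max  # normalizer of the truncated law
        return -(sum_km1 * math.log(p) + total * math.log1p(-p)
                 - total * math.log(z))

    res = minimize_scalar(nll, bounds=(1e-12, 1 - 1e-12), method="bounded",
                          options={"xatol": 1e-12})
    hist.p_geom = float(res.x)
    return hist.p_geom


# ---------------------------------------------------------------------------

def well_mixed_shuffle(records, n_reps: int = 100, seed=0) -> ShuffleResult:
    """Shuffle follicle labels among intrafollicular UMIs (sizes preserved).

    Tabulates, for the observed data and every shuffle, the number of
    lineages per follicle count k and the per-lineage UMI-count distribution
    conditioned on k.
    """
    rng = np.random.default_rng(seed)
    intra = [r for r in records if r.intrafollicular]
    if not intra:
        raise RepertoireError("no intrafollicular records")
    lineage = np.array([r.lineage_id for r in intra])
    follicle = np.array([r.follicle_id for r in intra])

    def tabulate(foll: np.ndarray):
        k_of: dict[int, set] = {}
        size_of: dict[int, int] = {}
        for lid, fid in zip(lineage, foll):
            k_of.setdefault(int(lid), set()).add(int(fid))
            size_of[int(lid)] = size_of.get(int(lid), 0) + 1
        k_counts: dict[int, int] = {}
        sizes_by_k: dict[int, list] = {}
        for lid, fset in k_of.items():
            k = len(fset)
            k_counts[k] = k_counts.get(k, 0) + 1
            sizes_by_k.setdefault(k, []).append(size_of[lid])
        return k_counts, sizes_by_k

    obs_k, obs_sizes = tabulate(follicle)
    shuffled_k: list = []
    shuffled_sizes: list = []
    for _ in range(n_reps):
        perm = rng.permutation(len(follicle))
        k_counts, sizes_by_k = tabulate(follicle[perm])
        shuffled_k.append(k_counts)
        shuffled_sizes.append(sizes_by_k)

    all_k = sorted(set(obs_k) | {k for rep in shuffled_k for k in rep})
    mean, sem = {}, {}
    for k in all_k:
        vals = np.array([rep.get(k, 0) for rep in shuffled_k], dtype=float)
        if n_reps:
            mean[k] = float(vals.mean())
            sem[k] = float(vals.std(ddof=0) / math.sqrt(n_reps))

    size_hists: dict = {}
    for k in all_k:
        size_values = sorted({s for rep in shuffled_sizes
                              for s in rep.get(k, [])})
        hist = {}
        for s in size_values:
            per_rep = np.array([rep.get(k, []).count(s) for rep in shuffled_sizes],
                               dtype=float)
            hist[s] = (float(per_rep.mean()),
                       float(per_rep.std(ddof=0) / math.sqrt(max(n_reps, 1))))
        size_hists[k] = hist

    return ShuffleResult(
        observed_k_counts=dict(sorted(obs_k.items())),
        shuffled_k_counts=shuffled_k,
        shuffled_mean=mean,
        shuffled_sem=sem,
        observed_sizes_by_k={k: sorted(v) for k, v in obs_sizes.items()},
        shuffled_size_hists=size_hists,
    )


# ---------------------------------------------------------------------------

def related_pair_distances(
    records,
    min_root_div: float = 0.0,
    clonal_only: bool = False,
    background_cap: int = 1_000_000,
    seed=0,
    cross_section_only: bool = False,
    fmap: Optional[FollicleMap] = None,
) -> DistanceDistribution:
    """Normalized XY distances of same-lineage pairs in different follicles.

    Distances are divided by the median distance between UMIs in the same
    follicle. The background is all cross-follicle pairs regardless of
    lineage (seeded subsample above ``background_cap``); ``tail_fraction``
    is the fraction of related pairs at or beyond the background median.
    With ``clonal_only`` the related set is restricted to pairs of identical
    V sequences with root divergence at least ``min_root_div``.
    """
    rng = np.random.default_rng(seed)
    intra = [r for r in records if r.intrafollicular]
    if len(intra) < 2:
        return DistanceDistribution(np.array([]), np.array([]),
                                    float("nan"), empty=True)
    if fmap is None or math.isnan(fmap.intra_median):
        fmap = follicle_map_from_records(intra)
    norm = fmap.intra_median

    xy = np.array([(r.x, r.y) for r in intra])
    foll = np.array([r.follicle_id for r in intra])
    sect = np.array([r.section for r in intra])

    # related pairs, per lineage (vectorized over each lineage's pair set)
    seq_ids: dict[str, int] = {}
    seq_code = np.array([seq_ids.setdefault(r.v_sequence, len(seq_ids))
                         for r in intra])
    rootdiv = np.array([r.root_divergence if r.root_divergence is not None else 0.0
                        for r in intra])
    by_lineage: dict[int, list] = {}
    for i, rec in enumerate(intra):
        by_lineage.setdefault(rec.lineage_id, []).append(i)
    rel = []
    for members in by_lineage.values():
        if len(members) < 2:
            continue
        m = np.array(members)
        aa, bb = np.triu_indices(len(m), k=1)
        i, j = m[aa], m[bb]
        mask = foll[i] != foll[j]
        if cross_section_only:
            mask &= sect[i] != sect[j]
        if clonal_only:
            mask &= (seq_code[i] == seq_code[j]) & (rootdiv[i] >= min_root_div)
        elif min_root_div > 0:
            mask &= (rootdiv[i] >= min_root_div) & (rootdiv[j] >= min_root_div)
        i, j = i[mask], j[mask]
        if len(i):
            rel.append(np.sqrt(((xy[i] - xy[j]) ** 2).sum(axis=1)))
    related = (np.concatenate(rel) if rel else np.array([])) / norm

    background = _background_distances(xy, foll, sect, cross_section_only,
                                       background_cap, rng) / norm
    if len(related) == 0 or len(background) == 0:
        return DistanceDistribution(related, background, norm, empty=True)
    bg_median = float(np.median(background))
    tail = float((related >= bg_median).mean())
    return DistanceDistribution(related, background, norm, tail_fraction=tail)


def _background_distances(xy, foll, sect, cross_section_only, cap, rng):
    n = len(xy)
    n_pairs = n * (n - 1) // 2
    if n_pairs <= cap:
        ii, jj = np.triu_indices(n, k=1)
    else:
        ii = rng.integers(0, n, size=cap)
        jj = rng.integers(0, n, size=cap)
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
    mask = foll[ii] != foll[jj]
    if cross_section_only:
        mask &= sect[ii] != sect[jj]
    ii, jj = ii[mask], jj[mask]
    return np.sqrt(((xy[ii] - xy[jj]) ** 2).sum(axis=1))


def edge_filter(records, fmap: FollicleMap, percentile: float = 80.0):
    """Robustness filter: drop records in the outer distance-to-centroid
    percentile of their follicle (approximate edge-of-follicle control)."""
    by_follicle: dict[int, list] = {}
    for rec in records:
        if rec.intrafollicular:
            by_follicle.setdefault(rec.follicle_id, []).append(rec)
    keep = [r for r in records if not r.intrafollicular]
    for fid, members in by_follicle.items():
        cx, cy = fmap.centroids[fid]
        d = np.array([math.hypot(r.x - cx, r.y - cy) for r in members])
        cutoff = np.percentile(d, percentile)
        keep.extend(r for r, di in zip(members, d) if di <= cutoff)
    return keep
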