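"""Divergence-clock analyses: divergence distributions, the pairwise
migration-vs-divergence curve, clonal-burst multifollicularity, and the
relation between lineage age and terminal differentiation.

Somatic hypermutations accumulate roughly uniformly per division, so the V
gene divergence of a cell from its germline ancestor serves as a molecular
clock against which migration is measured.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import rankdata

from gcmig.repertoire import RepertoireError, pairwise_divergence

#: Sentinel for an unidentifiable (infinite) migration scale.
BETA_INF = float("inf")

_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _valid_mask(mat: np.ndarray) -> np.ndarray:
    return np.isin(mat, _ACGT_CODES)


@dataclass
class PairwiseCurve:
    beta: float
    intercept_excess: float              # migration probability among near-zero pairs
    n_pairs: int
    bin_edges: np.ndarray
    bin_prob: np.ndarray                 # P(different follicle) per bin
    bin_err: np.ndarray                  # counting error sqrt(k)/n
    bin_n: np.ndarray


@dataclass
class BurstGroup:
    lineage_id: int
    v_sequence: str
    size: int
    follicles: frozenset
    root_div: float

    @property
    def multifollicular(self) -> bool:
        return len(self.follicles) > 1


@dataclass
class BurstResult:
    groups: list
    p_burst: Optional[float]
    aggregate_multifollicular: float
    size_curve: dict                     # size -> (fraction multifollicular, n groups)
    empty: bool = False


@dataclass
class AscTrend:
    pairs: list                          # (median intrafollicular root_div, ASC fraction)
    correlation: Optional[float]
    degenerate: bool = False


# ---------------------------------------------------------------------------

def fit_exponential_divergence(divs: Sequence[float]) -> float:
    """MLE scale of an exponential divergence distribution (the sample mean)."""
    arr = np.asarray(list(divs), dtype=float)
    if arr.size == 0:
        raise RepertoireError("no divergence values")
    if (arr < 0).any():
        raise RepertoireError("divergences must be non-negative")
    alpha = float(arr.mean())
    if alpha == 0:
        warnings.warn("all divergences are zero: degenerate exponential fit")
    return alpha


# ---------------------------------------------------------------------------

def _unique_sequences(records):
    """Per lineage: unique intrafollicular V sequences with a modal follicle.

    A sequence observed in several follicles is assigned its most frequent
    follicle (smallest id on ties); the pairwise curve treats each unique
    sequence as one clone.
    """
    per_lineage: dict[int, dict] = {}
    for rec in records:
        if not rec.intrafollicular:
            continue
        if rec.lineage_id is None:
            raise RepertoireError("lineage_id not assigned")
        seqs = per_lineage.setdefault(rec.lineage_id, {})
        counts = seqs.setdefault(rec.v_sequence, {})
        counts[rec.follicle_id] = counts.get(rec.follicle_id, 0) + 1
    out: dict[int, list] = {}
    for lid, seqs in per_lineage.items():
        entries = []
        for seq, counts in seqs.items():
            follicle = min(counts, key=lambda f: (-counts[f], f))
            entries.append((seq, follicle))
        entries.sort(key=lambda t: t[0])
        out[lid] = entries
    return out


def pairwise_migration_curve(
    records,
    near_zero_edge: float = 0.005,
    bin_width: float = 0.005,
    pair_cap_per_lineage: int = 10_000,
    seed=0,
    method: str = "mle",
) -> PairwiseCurve:
    """Different-follicle probability of same-lineage clone pairs vs divergence.

    Every pair of distinct unique V(D)J sequences within a lineage
    contributes (x = pairwise divergence, y = different-follicle indicator).
    The migration scale beta is the Bernoulli MLE of y ~ 1 - exp(-x/beta)
    (``method="mle"``) or a weighted least-squares fit on the binned curve
    (``method="binned"``). ``intercept_excess`` is the raw migration
    probability among pairs with x below ``near_zero_edge``.
    """
    rng = np.random.default_rng(seed)
    uniques = _unique_sequences(records)
    xs, ys = [], []
    for lid in sorted(uniques):
        entries = uniques[lid]
        n = len(entries)
        if n < 2:
            continue
        n_pairs = n * (n - 1) // 2
        if n_pairs > pair_cap_per_lineage:
            ii = rng.integers(0, n, size=pair_cap_per_lineage)
            jj = rng.integers(0, n, size=pair_cap_per_lineage)
            keep = ii != jj
            ii, jj = ii[keep], jj[keep]
        else:
            ii, jj = np.triu_indices(n, k=1)
        mat = np.frombuffer("".join(s for s, _ in entries).encode("ascii"),
                            dtype=np.uint8).reshape(n, -1)
        valid = _valid_mask(mat)
        foll = np.array([f for _, f in entries])
        for lo in range(0, len(ii), 20_000):  # bounded memory
            a, b = ii[lo:lo + 20_000], jj[lo:lo + 20_000]
            both = valid[a] & valid[b]
            comparable = both.sum(axis=1)
            with np.errstate(invalid="ignore"):
                div = ((mat[a] != mat[b]) & both).sum(axis=1) / comparable
            ok = comparable > 0
            xs.append(div[ok])
            ys.append((foll[a] != foll[b])[ok].astype(float))
    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
    else:
        x = np.array([])
        y = np.array([])
    if x.size == 0:
        raise RepertoireError("no same-lineage pairs of distinct sequences")

    edges = np.arange(0.0, max(x.max() + bin_width, bin_width * 2), bin_width)
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    bin_n = np.bincount(idx, minlength=len(edges) - 1)
    bin_k = np.bincount(idx, weights=y, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        bin_prob = np.where(bin_n > 0, bin_k / bin_n, np.nan)
        bin_err = np.where(bin_n > 0, np.sqrt(np.maximum(bin_k, 1)) / bin_n, np.nan)

    beta = _fit_beta(x, y, edges, bin_prob, bin_n, method)
    near = x < near_zero_edge
    intercept = float(y[near].mean()) if near.any() else float("nan")
    return PairwiseCurve(beta=beta, intercept_excess=intercept,
                         n_pairs=int(x.size), bin_edges=edges,
                         bin_prob=bin_prob, bin_err=bin_err, bin_n=bin_n)


def _fit_beta(x, y, edges, bin_prob, bin_n, method) -> float:
    if y.sum() == 0:
        warnings.warn("no migrated pairs: migration scale unidentifiable")
        return BETA_INF
    lo, hi = 1e-6, 10.0
    if y.min() == 1.0:
        warnings.warn("all pairs migrated: migration scale at lower search bound")
        return lo
    if method == "mle":
        def nll(beta: float) -> float:
            z = x / beta
            p = -np.expm1(-z)
            return float(-(y * np.log(p) - (1 - y) * z).sum())
    elif method == "binned":
        centers = (edges[:-1] + edges[1:]) / 2
        ok = bin_n > 0

        def nll(beta: float) -> float:
            pred = -np.expm1(-centers[ok] / beta)
            return float((bin_n[ok] * (bin_prob[ok] - pred) ** 2).sum())
    else:
        raise RepertoireError(f"unknown beta fit method {method!r}")
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


# ---------------------------------------------------------------------------

def clonal_burst_analysis(records, min_root_div: float = 0.01) -> BurstResult:
    """Multifollicularity of clonal groups (identical diverged V sequences).

    A clonal burst group is a V sequence at least ``min_root_div`` diverged
    from its germline that appears at least twice in the intrafollicular
    space. Fits a per-UMI migration probability p under the model
    P(multifollicular | size s) = 1 - (1-p)^s.
    """
    by_key: dict = {}
    for rec in records:
        if not rec.intrafollicular:
            continue
        if rec.root_divergence is None:
            raise RepertoireError(f"{rec.umi_id}: root_divergence required")
        key = (rec.lineage_id, rec.v_sequence)
        by_key.setdefault(key, []).append(rec)
    groups = []
    for (lid, seq), members in by_key.items():
        if len(members) < 2:
            continue
        rd = members[0].root_divergence
        if rd < min_root_div:
            continue
        groups.append(BurstGroup(
            lineage_id=lid, v_sequence=seq, size=len(members),
            follicles=frozenset(m.follicle_id for m in members),
            root_div=rd))
    if not groups:
        return BurstResult(groups=[], p_burst=None,
                           aggregate_multifollicular=float("nan"),
                           size_curve={}, empty=True)
    sizes = np.array([g.size for g in groups])
    multi = np.array([g.multifollicular for g in groups], dtype=float)
    aggregate = float(multi.mean())
    size_curve = {}
    for s in sorted(set(sizes)):
        mask = sizes == s
        size_curve[int(s)] = (float(multi[mask].mean()), int(mask.sum()))

    if multi.sum() == 0:
        p_burst = 0.0
    elif multi.min() == 1.0:
        p_burst = _burst_mle(sizes, multi)  # still defined; bounded below 1
    else:
        p_burst = _burst_mle(sizes, multi)
    return BurstResult(groups=groups, p_burst=p_burst,
                       aggregate_multifollicular=aggregate,
                       size_curve=size_curve)


def _burst_mle(sizes, multi) -> float:
    def nll(p: float) -> float:
        log_q = math.log1p(-p)
        p_multi = -np.expm1(sizes * log_q)
        return float(-(multi * np.log(p_multi)
                       + (1 - multi) * sizes * log_q).sum())

    res = minimize_scalar(nll, bounds=(1e-12, 1 - 1e-9), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


# ---------------------------------------------------------------------------

def asc_age_trend(records) -> AscTrend:
    """Lineage age (median intrafollicular divergence) vs ASC fraction.

    The rank correlation is computed internally as a rank transform followed
    by a product-moment correlation (ties get average ranks).
    """
    intra: dict[int, list] = {}
    n_asc: dict[int, int] = {}
    for rec in records:
        if rec.lineage_id is None:
            raise RepertoireError("lineage_id not assigned")
        if rec.intrafollicular:
            if rec.root_divergence is None:
                raise RepertoireError(f"{rec.umi_id}: root_divergence required")
            intra.setdefault(rec.lineage_id, []).append(rec.root_divergence)
        elif rec.compartment == "ASC":
            n_asc[rec.lineage_id] = n_asc.get(rec.lineage_id, 0) + 1
    pairs = []
    for lid, divs in sorted(intra.items()):
        asc = n_asc.get(lid, 0)
        pairs.append((float(np.median(divs)), asc / (asc + len(divs))))
    if len(pairs) < 3:
        return AscTrend(pairs=pairs, correlation=None, degenerate=True)
    ages = rankdata([p[0] for p in pairs])
    fracs = rankdata([p[1] for p in pairs])
    if np.std(ages) == 0 or np.std(fracs) == 0:
        return AscTrend(pairs=pairs, correlation=0.0, degenerate=True)
    corr = float(np.corrcoef(ages, fracs)[0, 1])
    return AscTrend(pairs=pairs, correlation=corr)
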