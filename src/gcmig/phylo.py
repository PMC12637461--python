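"""Lineage trees, parsimony follicle labelling and migration-rate estimation.

Trees are rooted at the germline ancestor and carry branch lengths in
substitutions per site; their total branch length ("clock time" T) is the
denominator of all migration rates. Internal follicle labels are assigned by
minimum-change parsimony (Sankoff dynamic programming with uniform costs,
which is exact on arbitrary-arity trees); every branch whose endpoint labels
differ is one migration event.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from gcmig.repertoire import EXTRAFOLLICULAR, RepertoireError, pairwise_divergence
from gcmig.tree import LineageTree, Node


class PhyloError(ValueError):
    pass


@dataclass
class MigrationEvent:
    """One inferred follicle change on a tree branch."""

    lineage_id: Optional[int]
    branch_id: int
    parent_label: int
    child_label: int
    depth: float            # root-to-branch-midpoint divergence
    branch_length: float
    is_early: bool


@dataclass
class RateEstimates:
    m_global: float                       # sum(N) / sum(T)
    n_events: dict                        # lineage_id -> N
    total_divergence: dict                # lineage_id -> T
    per_lineage: dict                     # lineage_id -> N/T, only N >= 1
    curve: Optional[dict] = None          # binned mean N vs T with Poisson envelope


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

GERMLINE_NAME = "__germline__"


def collapse_identical(records) -> list[tuple[str, str, int, int]]:
    """Collapse intrafollicular records to unique (v_sequence, follicle) leaves.

    Returns tuples (representative umi_id, v_sequence, follicle_id, weight)
    sorted canonically. Identical sequences observed in different follicles
    stay separate so every leaf has a single follicle label.
    """
    groups: dict = {}
    for rec in records:
        if not rec.intrafollicular:
            continue
        key = (rec.v_sequence, rec.follicle_id)
        if key in groups:
            groups[key][1] += 1
            if rec.umi_id < groups[key][0]:
                groups[key][0] = rec.umi_id
        else:
            groups[key] = [rec.umi_id, 1]
    out = [(v[0], key[0], key[1], v[1]) for key, v in groups.items()]
    out.sort(key=lambda t: t[0])
    return out


def build_tree(
    records=None,
    mode: str = "nj",
    newick: Optional[str] = None,
    genealogy: Optional[LineageTree] = None,
    lineage_id: Optional[int] = None,
) -> Optional[LineageTree]:
    """Build a rooted, leaf-labelled lineage tree.

    Modes:

    - ``"nj"`` — neighbor joining on pairwise divergences with the germline
      included as outgroup; the tree is rooted at the germline attachment
      point and the germline leaf removed. Negative branch lengths clamp to 0.
    - ``"newick"`` — import a user tree (leaf names are umi_ids); labels are
      taken from ``records``. A leaf named ``germline`` (or
      :data:`GERMLINE_NAME`) is used for rooting and removed.
    - ``"true"`` — use a generator genealogy; extrafollicular leaves are
      pruned and unary chains collapsed.

    Returns ``None`` (lineage skipped) when fewer than two genetically
    distinct intrafollicular sequences are available.
    """
    if mode == "true":
        if genealogy is None:
            raise PhyloError("mode 'true' requires a genealogy")
        return _prepare_true_tree(genealogy, lineage_id)
    if records is None:
        raise PhyloError(f"mode {mode!r} requires records")
    leaves = collapse_identical(records)
    if len({seq for _, seq, _, _ in leaves}) < 2:
        return None
    if mode == "nj":
        germline = next((r.germline_v for r in records if r.germline_v), None)
        if not germline:
            raise PhyloError("germline sequence required for rooting")
        return _build_nj(leaves, germline, lineage_id)
    if mode == "newick":
        if newick is None:
            raise PhyloError("mode 'newick' requires a newick string")
        return _import_newick(newick, records, lineage_id)
    raise PhyloError(f"unknown tree mode {mode!r}")


def _build_nj(leaves, germline: str, lineage_id) -> LineageTree:
    from skbio import DistanceMatrix
    from skbio.tree import nj

    names = [umi for umi, _, _, _ in leaves] + [GERMLINE_NAME]
    seqs = [seq for _, seq, _, _ in leaves] + [germline]
    n = len(names)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_divergence(seqs[i], seqs[j])
            dmat[i, j] = dmat[j, i] = d
    if n == 2:  # one distinct sequence plus germline cannot happen (checked), but be safe
        raise PhyloError("need at least two distinct sequences")
    sk = nj(DistanceMatrix(dmat, names))
    germ = next(t for t in sk.tips() if t.name == GERMLINE_NAME)
    parent = germ.parent
    if parent.parent is not None:
        sk = sk.root_at(parent)
        germ = next(t for t in sk.tips() if t.name == GERMLINE_NAME)
    tree = LineageTree.from_skbio(sk, lineage_id)
    root = tree.root
    root.children = [c for c in root.children
                     if not (c.is_leaf and c.name == GERMLINE_NAME)]
    for node in tree.preorder():
        if node.length < 0:
            node.length = 0.0
    _attach_labels(tree, leaves)
    return tree


def _import_newick(newick: str, records, lineage_id) -> LineageTree:
    tree = LineageTree.from_newick(newick, lineage_id)
    germ = next((n for n in tree.leaves()
                 if n.name in (GERMLINE_NAME, "germline")), None)
    if germ is not None and germ.parent is not None:
        germ.parent.children.remove(germ)
    by_umi = {rec.umi_id: rec for rec in records}
    leaves = []
    for leaf in tree.leaves():
        rec = by_umi.get(leaf.name)
        if rec is None:
            raise PhyloError(f"tree leaf {leaf.name!r} not found in records")
        leaves.append((leaf.name, rec.v_sequence, rec.follicle_id, 1))
    _attach_labels(tree, leaves)
    return tree


def _attach_labels(tree: LineageTree, leaves) -> None:
    info = {umi: (follicle, weight) for umi, _, follicle, weight in leaves}
    for leaf in tree.leaves():
        if leaf.name not in info:
            raise PhyloError(f"no follicle label for leaf {leaf.name!r}")
        leaf.label, leaf.weight = info[leaf.name]


def _prepare_true_tree(genealogy: LineageTree, lineage_id) -> Optional[LineageTree]:
    tree = genealogy.copy()
    # iteratively drop extrafollicular leaves, then collapse unary chains
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder()):
            if node.parent is None:
                continue
            if node.is_leaf and (node.label == EXTRAFOLLICULAR or node.name is None):
                node.parent.children.remove(node)
                changed = True
    _collapse_unary(tree.root)
    if tree.n_leaves() < 2:
        return None
    tree.lineage_id = lineage_id if lineage_id is not None else genealogy.lineage_id
    return tree


def _collapse_unary(root: Node) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        for i, child in enumerate(list(node.children)):
            while len(child.children) == 1 and child.name is None:
                gchild = child.children[0]
                gchild.length += child.length
                gchild.parent = node
                node.children[i] = gchild
                child = gchild
            stack.append(child)


# ---------------------------------------------------------------------------
# Parsimony labelling
# ---------------------------------------------------------------------------

def parsimony_labels(tree: LineageTree):
    """Minimum-change follicle labelling of internal nodes.

    Sankoff dynamic programming with uniform transition cost (exact for any
    arity). The root label is chosen among minimum-cost states by leaf
    majority, then smallest follicle id; the top-down pass prefers the
    parent's label whenever it attains the child's minimum. Returns
    ``(labels, n_migrations)`` where labels maps every node to a follicle id
    and ``n_migrations`` is the number of label-changing branches (the
    parsimony minimum). Internal node ``label`` attributes are set in place.
    """
    for leaf in tree.leaves():
        if leaf.label is None:
            raise PhyloError(f"unlabelled leaf {leaf.name!r}")
    states = sorted({leaf.label for leaf in tree.leaves()})
    index = {s: i for i, s in enumerate(states)}
    k = len(states)
    leaf_count = {s: 0 for s in states}
    for leaf in tree.leaves():
        leaf_count[leaf.label] += 1

    INF = float("inf")
    cost: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            c = np.full(k, INF)
            c[index[node.label]] = 0.0
            cost[node] = c
        else:
            c = np.zeros(k)
            for child in node.children:
                cc = cost[child]
                best = cc.min()
                # transition cost: min(cc[s], best + 1) for each parent state s
                c += np.minimum(cc, best + 1.0)
            cost[node] = c

    def tie_break(candidates):
        # most leaves, then smallest id (rank in the sorted state list)
        return max(candidates, key=lambda s: (leaf_count[s], -index[s]))

    root_cost = cost[tree.root]
    best = root_cost.min()
    root_label = tie_break([states[i] for i in range(k)
                            if root_cost[i] == best])
    labels: dict[Node, int] = {}
    tree.root.label = root_label if not tree.root.is_leaf else tree.root.label
    labels[tree.root] = tree.root.label

    stack = list(tree.root.children)
    parent_of = {c: tree.root for c in tree.root.children}
    n_changes = 0
    while stack:
        node = stack.pop()
        parent_label = labels[parent_of[node]]
        if node.is_leaf:
            labels[node] = node.label
        else:
            c = cost[node]
            cmin = c.min()
            pi = index[parent_label]
            if c[pi] == cmin:
                labels[node] = parent_label
            else:
                labels[node] = tie_break([states[i] for i in range(k)
                                          if c[i] == cmin])
            node.label = labels[node]
        if labels[node] != parent_label:
            n_changes += 1
        for child in node.children:
            parent_of[child] = node
            stack.append(child)
    assert n_changes == int(best), "top-down pass must realise the minimum cost"
    return labels, n_changes


# ---------------------------------------------------------------------------
# Migration events and rates
# ---------------------------------------------------------------------------

def extract_migrations(tree: LineageTree,
                       early_threshold: float = 0.01) -> list[MigrationEvent]:
    """One event per label-changing branch; depth = root-to-midpoint divergence."""
    depths = tree.depths()
    events = []
    for branch_id, node in enumerate(tree.branches()):
        if node.parent.label != node.label:
            mid = depths[node.parent] + node.length / 2.0
            events.append(MigrationEvent(
                lineage_id=tree.lineage_id,
                branch_id=branch_id,
                parent_label=node.parent.label,
                child_label=node.label,
                depth=mid,
                branch_length=node.length,
                is_early=mid < early_threshold,
            ))
    return events


def estimate_rates(trees: Sequence[LineageTree],
                   events: Optional[dict] = None,
                   n_bins: int = 12) -> RateEstimates:
    """Global and per-lineage migration rates from labelled trees.

    ``events`` maps lineage_id to its MigrationEvent list; when omitted the
    trees must already carry parsimony labels and events are extracted here.
    ``m_global`` is the Poisson MLE of the through-origin line N = m T.
    """
    if not trees:
        raise PhyloError("no trees")
    n_events: dict = {}
    total_T: dict = {}
    for tree in trees:
        lid = tree.lineage_id
        if events is not None:
            n_events[lid] = len(events[lid])
        else:
            _, n = parsimony_labels(tree)
            n_events[lid] = n
        total_T[lid] = tree.total_divergence
    sum_T = sum(total_T.values())
    if sum_T <= 0:
        raise PhyloError("total divergence is zero")
    sum_N = sum(n_events.values())
    m_global = sum_N / sum_T
    per_lineage = {lid: n_events[lid] / total_T[lid]
                   for lid in n_events
                   if n_events[lid] >= 1 and total_T[lid] > 0}
    curve = _binned_curve(n_events, total_T, m_global, n_bins)
    return RateEstimates(m_global=m_global, n_events=n_events,
                         total_divergence=total_T, per_lineage=per_lineage,
                         curve=curve)


def _binned_curve(n_events, total_T, m_global, n_bins):
    T = np.array([total_T[lid] for lid in sorted(total_T)])
    N = np.array([n_events[lid] for lid in sorted(total_T)], dtype=float)
    if len(T) < 2:
        return None
    upper = np.quantile(T, 0.95)  # dense region
    edges = np.linspace(0, max(upper, T.min() + 1e-9), n_bins + 1)
    centers, means, errs, counts = [], [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (T >= lo) & (T < hi)
        if mask.sum() == 0:
            continue
        centers.append((lo + hi) / 2)
        means.append(float(N[mask].mean()))
        errs.append(float(N[mask].std(ddof=0) / np.sqrt(mask.sum())))
        counts.append(int(mask.sum()))
    centers = np.array(centers)
    expected = m_global * centers
    return {
        "T_center": centers.tolist(),
        "mean_N": means,
        "sem_N": errs,
        "n": counts,
        "poisson_mean": expected.tolist(),
        "poisson_sd": np.sqrt(expected).tolist(),
    }


def stratify_rates(
    trees: Sequence[LineageTree],
    events: dict,
    by: str = "size",
    bins: Optional[Sequence[float]] = None,
    early_filter: bool = False,
):
    """Migration rate stratified by lineage size or by event depth.

    Size strata average per-lineage rates N/T (including zero-event trees).
    Depth strata divide the events falling in each depth bin by the total
    branch length residing in that bin, apportioning each branch to bins by
    overlap, so that bin lengths sum to T exactly.
    """
    if by == "size":
        sizes, rates = [], []
        for tree in trees:
            T = tree.total_divergence
            if T <= 0:
                continue
            evs = events[tree.lineage_id]
            if early_filter:
                evs = [e for e in evs if not e.is_early]
            sizes.append(sum(leaf.weight for leaf in tree.leaves()))
            rates.append(len(evs) / T)
        sizes = np.array(sizes)
        rates = np.array(rates)
        if bins is None:
            bins = [2, 4, 8, 16, 32, 64, 1e9]
        out = []
        for lo, hi in zip(bins[:-1], bins[1:]):
            mask = (sizes >= lo) & (sizes < hi)
            if mask.sum() == 0:
                out.append({"bin_lo": lo, "bin_hi": hi, "n": 0,
                            "rate": None, "se": None})
                continue
            out.append({
                "bin_lo": lo, "bin_hi": hi, "n": int(mask.sum()),
                "rate": float(rates[mask].mean()),
                "se": float(rates[mask].std(ddof=0) / np.sqrt(mask.sum())),
            })
        return out
    if by == "depth":
        if bins is None:
            bins = np.arange(0.0, 0.125, 0.0125)
        bins = np.asarray(bins, dtype=float)
        length_in_bin = np.zeros(len(bins))  # last entry: overflow above bins[-1]
        events_in_bin = np.zeros(len(bins))
        for tree in trees:
            depths = tree.depths()
            for node in tree.branches():
                d0, d1 = depths[node.parent], depths[node]
                _apportion(d0, d1, bins, length_in_bin)
            evs = events[tree.lineage_id]
            if early_filter:
                evs = [e for e in evs if not e.is_early]
            for ev in evs:
                idx = int(np.searchsorted(bins, ev.depth, side="right")) - 1
                events_in_bin[min(max(idx, 0), len(bins) - 1)] += 1
        out = []
        for i in range(len(bins)):
            lo = bins[i]
            hi = bins[i + 1] if i + 1 < len(bins) else float("inf")
            if length_in_bin[i] <= 0:
                out.append({"bin_lo": float(lo), "bin_hi": float(hi),
                            "length": 0.0, "events": 0, "rate": None, "se": None})
                continue
            rate = events_in_bin[i] / length_in_bin[i]
            out.append({
                "bin_lo": float(lo), "bin_hi": float(hi),
                "length": float(length_in_bin[i]),
                "events": int(events_in_bin[i]),
                "rate": float(rate),
                "se": float(np.sqrt(events_in_bin[i]) / length_in_bin[i]),
            })
        return out
    raise PhyloError(f"unknown stratification {by!r}")


def _apportion(d0: float, d1: float, bins: np.ndarray, acc: np.ndarray) -> None:
    """Add the overlap of the depth interval [d0, d1] with each bin to acc.

    The last bin is open-ended so the total branch length is conserved.
    """
    if d1 <= d0:
        return
    for i in range(len(bins)):
        lo = bins[i]
        hi = bins[i + 1] if i + 1 < len(bins) else float("inf")
        overlap = min(d1, hi) - max(d0, lo)
        if overlap > 0:
            acc[i] += overlap
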