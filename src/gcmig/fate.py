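"""Post-migration fates: subtree diversification and follicle composition.

Cutting a labelled lineage tree at every migration branch yields
single-follicle subtrees; the divergence of subtrees that immediately follow
a migration measures how much migrants diversify in their new follicle, and
is compared against trees whose migration events have been shuffled along
the branches. Separately, cells whose follicle differs from their tree's
root label are classified as migrants to quantify each follicle's migrant
composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from gcmig.tree import LineageTree, Node


class FateError(ValueError):
    pass


@dataclass
class SubtreeRecord:
    lineage_id: Optional[int]
    label: int
    divergence: float        # sum of branch lengths strictly inside the subtree
    n_leaves: int
    follows_migration: bool


@dataclass
class FollicleComposition:
    follicle_id: int
    n_umis: int
    migrant_umi_fraction: float
    migrant_lineage_fraction: float
    top_lineage_frequency: float
    top_migrant_frequency: float


@dataclass
class ShuffleOutcome:
    n_events: int
    n_reps: int
    observed_divergences: np.ndarray         # post-migration subtree divergences
    shuffled_divergences: list               # per-rep arrays
    observed_zero_fraction: float
    shuffled_zero_fractions: np.ndarray


# ---------------------------------------------------------------------------

def decompose_subtrees(tree: LineageTree) -> list[SubtreeRecord]:
    """Cut the tree at every label-changing branch into single-follicle parts.

    The cut branch's own length belongs to neither adjacent component, so
    component divergences plus cut-branch lengths sum to the tree total
    exactly. A component whose rootward attachment is a cut branch follows a
    migration.
    """
    comp_of: dict[Node, int] = {tree.root: 0}
    divergence = [0.0]
    leaves = [0]
    label = [tree.root.label]
    follows = [False]
    for node in tree.preorder():
        for child in node.children:
            if child.label != node.label:
                comp_of[child] = len(divergence)
                divergence.append(0.0)
                leaves.append(0)
                label.append(child.label)
                follows.append(True)
            else:
                comp = comp_of[node]
                comp_of[child] = comp
                divergence[comp] += child.length
        if node.is_leaf:
            leaves[comp_of[node]] += 1
    return [SubtreeRecord(tree.lineage_id, label[i], divergence[i],
                          leaves[i], follows[i])
            for i in range(len(divergence))]


def _component_divergences(tree: LineageTree, cut: set) -> list[float]:
    """Divergences of components created by cutting the given branches.

    Returns one divergence per component whose attachment branch is cut
    (i.e. components that follow a migration)."""
    comp_of: dict[Node, int] = {tree.root: 0}
    divergence = [0.0]
    follows = [False]
    for node in tree.preorder():
        for child in node.children:
            if child in cut:
                comp_of[child] = len(divergence)
                divergence.append(0.0)
                follows.append(True)
            else:
                comp = comp_of[node]
                comp_of[child] = comp
                divergence[comp] += child.length
    return [d for d, f in zip(divergence, follows) if f]


def shuffle_migrations(tree: LineageTree, n_events: int, n_reps: int = 100,
                       seed=0, allow_multiple: bool = False) -> ShuffleOutcome:
    """Place ``n_events`` migration points uniformly along the tree's length.

    Branches are chosen with probability proportional to their length (at
    most one event per branch unless ``allow_multiple``); the post-migration
    component divergences are recomputed per rep. The observed side is filled
    in by the caller via :func:`observed_post_migration`.
    """
    if n_events < 1:
        raise FateError("n_events must be >= 1")
    branches = tree.branches()
    lengths = np.array([b.length for b in branches])
    positive = int((lengths > 0).sum())
    if not allow_multiple and n_events > positive:
        raise FateError(
            f"cannot place {n_events} events on {positive} positive-length branches")
    if lengths.sum() <= 0:
        raise FateError("tree has zero total length")
    weights = lengths / lengths.sum()
    rng = np.random.default_rng(seed)
    shuffled: list = []
    zero_fracs = np.empty(n_reps)
    for rep in range(n_reps):
        if allow_multiple:
            chosen = rng.choice(len(branches), size=n_events, p=weights)
        else:
            chosen_set: set = set()
            while len(chosen_set) < n_events:
                draw = int(rng.choice(len(branches), p=weights))
                chosen_set.add(draw)
            chosen = list(chosen_set)
        # uniform position within the branch (the divergence bookkeeping
        # excludes the cut branch entirely, so the position is informational)
        rng.random(len(chosen))
        cut = {branches[i] for i in chosen}
        divs = np.array(_component_divergences(tree, cut))
        shuffled.append(divs)
        zero_fracs[rep] = float((divs == 0).mean()) if len(divs) else float("nan")
    observed = observed_post_migration(tree)
    obs_zero = float((observed == 0).mean()) if len(observed) else float("nan")
    return ShuffleOutcome(
        n_events=n_events, n_reps=n_reps,
        observed_divergences=observed,
        shuffled_divergences=shuffled,
        observed_zero_fraction=obs_zero,
        shuffled_zero_fractions=zero_fracs,
    )


def observed_post_migration(tree: LineageTree) -> np.ndarray:
    """Divergences of subtrees that immediately follow an observed migration."""
    recs = decompose_subtrees(tree)
    return np.array([r.divergence for r in recs if r.follows_migration])


# ---------------------------------------------------------------------------

def classify_migrant_leaves(tree: LineageTree,
                            min_migration_root_div: float = 0.0) -> dict:
    """Map each leaf name to a migrant flag.

    A leaf is a migrant when its follicle differs from the tree's root label
    and at least one label-changing branch on its root path has a migration
    depth (root-to-branch-midpoint divergence) of at least
    ``min_migration_root_div``.
    """
    depths = tree.depths()
    out: dict = {}

    def walk(node: Node, qualifying_change: bool):
        for child in node.children:
            change = qualifying_change
            if child.label != node.label:
                mid = depths[node] + child.length / 2.0
                if mid >= min_migration_root_div:
                    change = True
            if child.is_leaf:
                out[child.name] = change and child.label != tree.root.label
            else:
                walk(child, change)

    if tree.root.is_leaf:
        out[tree.root.name] = False
    walk(tree.root, False)
    return out


def migrant_composition(records, trees: Sequence[LineageTree],
                        min_migration_root_div: float = 0.0
                        ) -> list[FollicleComposition]:
    """Migrant UMI/lineage fractions and top-lineage frequencies per follicle.

    Frequencies are over intrafollicular UMIs only. Lineages without trees
    are never migrants. A lineage counts as a migrant in a follicle when at
    least one of its UMIs there is classified as a migrant.
    """
    # migrant UMI weight per (lineage, follicle), via collapsed tree leaves
    migrant_weight: dict = {}
    for tree in trees:
        flags = classify_migrant_leaves(tree, min_migration_root_div)
        for leaf in tree.leaves():
            if flags.get(leaf.name):
                key = (tree.lineage_id, leaf.label)
                migrant_weight[key] = migrant_weight.get(key, 0) + leaf.weight

    umis: dict[int, dict[int, int]] = {}   # follicle -> lineage -> n_umis
    for rec in records:
        if not rec.intrafollicular:
            continue
        umis.setdefault(rec.follicle_id, {})
        umis[rec.follicle_id][rec.lineage_id] = \
            umis[rec.follicle_id].get(rec.lineage_id, 0) + 1

    out = []
    for fid in sorted(umis):
        counts = umis[fid]
        n_total = sum(counts.values())
        if n_total == 0:
            continue
        migrant_lineages = {lid for lid in counts
                            if migrant_weight.get((lid, fid), 0) > 0}
        migrant_umis = sum(min(migrant_weight.get((lid, fid), 0), counts[lid])
                           for lid in migrant_lineages)
        top = max(counts.values())
        top_migrant = max((counts[lid] for lid in migrant_lineages), default=0)
        out.append(FollicleComposition(
            follicle_id=fid,
            n_umis=n_total,
            migrant_umi_fraction=migrant_umis / n_total,
            migrant_lineage_fraction=len(migrant_lineages) / len(counts),
            top_lineage_frequency=top / n_total,
            top_migrant_frequency=top_migrant / n_total,
        ))
    return out
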