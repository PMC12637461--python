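"""Agent-based synthetic tonsil generator with ground-truth genealogies.

Lineages grow by synchronous binary divisions inside follicles. Each daughter
cell independently acquires Poisson-distributed substitutions (the
hypermutation clock), migrates to another follicle with a fixed per-division
probability (destinations biased towards nearby follicles through an
exponential distance kernel), may enter a clonal burst (several divisions with
hypermutation switched off) and may terminally differentiate into an
extrafollicular antibody-secreting cell. Sampled cells are emitted as
:class:`~gcmig.repertoire.UmiRecord` rows; the full genealogy, every true
migration event and the realized per-division rates are retained as ground
truth so each downstream inference stage can be validated by parameter
recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from gcmig.repertoire import (
    EXTRAFOLLICULAR,
    FollicleMap,
    UmiRecord,
    write_repertoire_table,
)
from gcmig.tree import LineageTree, Node

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass
class SimParams:
    """Generator parameters. All probabilities are per cell per generation
    unless stated otherwise; ``migration_prob`` is per daughter per division."""

    n_follicles: int = 15
    arena_size: float = 1500.0
    n_lineages: int = 100
    generations: int = 14
    division_prob: float = 0.5
    shm_per_division: float = 0.0025   # expected substitutions/site/division
    migration_prob: float = 0.05       # per-daughter hop probability q
    locality_scale: float = 150.0      # micrometres; destination kernel exp(-d/scale)
    burst_prob: float = 0.0
    burst_divisions: int = 3
    asc_prob: float = 0.02
    pre_gc_expansion: int = 1
    sample_prob: float = 0.15
    v_length: int = 300
    carrying_capacity: Optional[int] = 300  # live cells per follicle (per lineage); None = off
    follicle_radius: float = 50.0
    n_sections: int = 6
    rate_cv: float = 0.0     # per-lineage gamma CV on migration_prob
    fitness_cv: float = 0.0  # per-lineage gamma CV on division_prob (off by default)
    min_generations: Optional[int] = None  # when set, lineage ages vary uniformly
                                           # in [min_generations, generations]

    def validate(self) -> None:
        for name in ("division_prob", "shm_per_division", "migration_prob",
                     "burst_prob", "asc_prob", "sample_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.generations < 1:
            raise SimulationError("generations must be >= 1")
        if self.n_follicles < 1:
            raise SimulationError("n_follicles must be >= 1")
        if self.pre_gc_expansion < 1:
            raise SimulationError("pre_gc_expansion must be >= 1")
        if self.v_length < 1:
            raise SimulationError("v_length must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrueMigration:
    lineage_id: int
    node_id: int        # genealogy node whose creating division migrated
    source: int
    destination: int
    generation: int
    on_pruned_tree: bool = False


@dataclass
class SimTruth:
    """Generator-side ground truth for validating the inference stages."""

    genealogies: dict = field(default_factory=dict)   # lineage_id -> LineageTree
    events: list = field(default_factory=list)        # list[TrueMigration]
    founder_follicles: dict = field(default_factory=dict)
    germlines: dict = field(default_factory=dict)     # lineage_id -> germline V string
    n_divisions: dict = field(default_factory=dict)
    n_migrations: dict = field(default_factory=dict)
    n_events_pruned: dict = field(default_factory=dict)

    def realized_rate(self, lineage_id: int) -> float:
        """Realized migrations per division for one lineage."""
        d = self.n_divisions[lineage_id]
        return self.n_migrations[lineage_id] / d if d else float("nan")


@dataclass
class SimResult:
    records: list
    follicle_map: FollicleMap
    truth: SimTruth
    params: SimParams


# ---------------------------------------------------------------------------
# Follicle geometry
# ---------------------------------------------------------------------------

def make_follicle_map(
    n_follicles: int,
    arena_size: float,
    seed,
    min_separation: Optional[float] = None,
    radius: float = 50.0,
) -> FollicleMap:
    """Place follicle centroids uniformly with minimum-separation rejection."""
    if n_follicles < 1:
        raise SimulationError("n_follicles must be >= 1")
    rng = np.random.default_rng(seed)
    if min_separation is None:
        min_separation = 3.0 * radius
    lo, hi = radius, arena_size - radius
    if hi <= lo:
        raise SimulationError("arena_size too small for follicle radius")
    for _ in range(50):  # restarts
        pts: list = []
        failed = False
        for _ in range(n_follicles):
            for _ in range(200):  # per-point retries
                cand = rng.uniform(lo, hi, size=2)
                if all(math.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_separation
                       for p in pts):
                    pts.append(tuple(cand))
                    break
            else:
                failed = True
                break
        if not failed:
            centroids = {i: pts[i] for i in range(n_follicles)}
            return FollicleMap(
                follicle_ids=list(range(n_follicles)),
                centroids=centroids,
                radius=radius,
            )
    raise SimulationError(
        "could not place follicles with the requested separation; "
        "increase arena_size or reduce n_follicles")


def _destination_cdfs(fmap: FollicleMap, locality_scale: float,
                      uniform: bool) -> np.ndarray:
    """Row s: cumulative destination law for a migrant leaving follicle s."""
    ids = fmap.follicle_ids
    n = len(ids)
    if n == 1:
        raise SimulationError("migration requires at least 2 follicles")
    w = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                continue
            w[i, j] = 1.0 if uniform else math.exp(-fmap.distance(a, b) / locality_scale)
    w /= w.sum(axis=1, keepdims=True)
    return np.cumsum(w, axis=1)


# ---------------------------------------------------------------------------
# Single-lineage simulation
# ---------------------------------------------------------------------------

class _Genealogy:
    """Append-only node store for one lineage's full cell genealogy."""

    def __init__(self):
        self.parent: list[int] = []
        self.muts: list[int] = []      # substitutions on the edge from parent
        self.follicle: list[int] = []
        self.generation: list[int] = []

    def new_node(self, parent: int, muts: int, follicle: int, gen: int) -> int:
        self.parent.append(parent)
        self.muts.append(muts)
        self.follicle.append(follicle)
        self.generation.append(gen)
        return len(self.parent) - 1


def _apply_mutations(seq: np.ndarray, count: int, rng) -> None:
    sites = rng.integers(0, seq.size, size=count)
    shifts = rng.integers(1, 4, size=count)
    seq[sites] = (seq[sites] + shifts) % 4


def simulate_lineage(
    params: SimParams,
    fmap: FollicleMap,
    seed,
    lineage_id: int = 0,
    uniform_destinations: bool = False,
    dest_cdf: Optional[np.ndarray] = None,
):
    """Simulate one lineage; returns (records, genealogy tree, events, stats).

    ``stats`` is a dict with realized division/migration counts and the
    founder follicles. The genealogy tree is pruned to the sampled leaves
    (unary chains collapsed, branch lengths in substitutions/site) and rooted
    at the unmutated germline ancestor.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    L = params.v_length
    ids = fmap.follicle_ids
    n_fol = len(ids)
    if dest_cdf is None and n_fol > 1:
        dest_cdf = _destination_cdfs(fmap, params.locality_scale,
                                     uniform_destinations)
    id_index = {fid: i for i, fid in enumerate(ids)}

    q = params.migration_prob
    if params.rate_cv > 0:
        shape = 1.0 / params.rate_cv ** 2
        q = min(1.0, q * rng.gamma(shape, 1.0 / shape))
    p_div = params.division_prob
    if params.fitness_cv > 0:
        shape = 1.0 / params.fitness_cv ** 2
        p_div = min(1.0, p_div * rng.gamma(shape, 1.0 / shape))

    germline = rng.integers(0, 4, size=L).astype(np.uint8)
    gen_log = _Genealogy()
    events: list[TrueMigration] = []
    n_divisions = 0
    n_migrations = 0

    def sample_destination(src: int) -> int:
        u = rng.random()
        j = int(np.searchsorted(dest_cdf[id_index[src]], u, side="right"))
        return ids[min(j, n_fol - 1)]

    def spawn_daughters(live_nodes, live_foll, live_seq, zero_shm: bool, gen: int):
        """Divide every cell in the arrays; returns daughter arrays."""
        nonlocal n_divisions, n_migrations
        k = len(live_nodes)
        n_divisions += k
        d_parent = np.repeat(live_nodes, 2)
        d_foll = np.repeat(live_foll, 2)
        d_seq = np.repeat(live_seq, 2, axis=0)
        if zero_shm or params.shm_per_division == 0:
            mut_counts = np.zeros(2 * k, dtype=np.int64)
        else:
            mut_counts = rng.poisson(params.shm_per_division * L, size=2 * k)
            for j in np.nonzero(mut_counts)[0]:
                _apply_mutations(d_seq[j], int(mut_counts[j]), rng)
        mig_mask = rng.random(2 * k) < q
        d_nodes = np.empty(2 * k, dtype=np.int64)
        for j in range(2 * k):
            src = int(d_foll[j])
            dst = src
            if mig_mask[j] and n_fol > 1:
                dst = sample_destination(src)
            node = gen_log.new_node(int(d_parent[j]), int(mut_counts[j]), dst, gen)
            d_nodes[j] = node
            if dst != src:
                n_migrations += 1
                events.append(TrueMigration(lineage_id, node, src, dst, gen))
            d_foll[j] = dst
        return d_nodes, d_foll, d_seq

    # founders: root is the unmutated germline ancestor
    founder_follicles = [ids[rng.integers(0, n_fol)]
                         for _ in range(params.pre_gc_expansion)]
    root = gen_log.new_node(-1, 0, founder_follicles[0], 0)
    if params.pre_gc_expansion == 1:
        live_nodes = np.array([root], dtype=np.int64)
        live_foll = np.array([founder_follicles[0]], dtype=np.int64)
        live_seq = germline[None, :].copy()
    else:
        founders = [gen_log.new_node(root, 0, f, 0) for f in founder_follicles]
        live_nodes = np.array(founders, dtype=np.int64)
        live_foll = np.array(founder_follicles, dtype=np.int64)
        live_seq = np.repeat(germline[None, :], params.pre_gc_expansion, axis=0)

    asc_nodes: list[int] = []
    asc_seqs: list[np.ndarray] = []

    n_generations = params.generations
    if params.min_generations is not None:
        n_generations = int(rng.integers(params.min_generations,
                                         params.generations + 1))

    for gen in range(1, n_generations + 1):
        n = len(live_nodes)
        if n == 0:
            break
        # terminal differentiation
        asc_mask = rng.random(n) < params.asc_prob
        for j in np.nonzero(asc_mask)[0]:
            asc_nodes.append(int(live_nodes[j]))
            asc_seqs.append(live_seq[j].copy())
        keep = ~asc_mask
        live_nodes, live_foll, live_seq = (
            live_nodes[keep], live_foll[keep], live_seq[keep])
        n = len(live_nodes)
        if n == 0:
            break
        # clonal-burst entry
        if params.burst_prob > 0:
            burst_mask = rng.random(n) < params.burst_prob
        else:
            burst_mask = np.zeros(n, dtype=bool)
        div_mask = ~burst_mask & (rng.random(n) < p_div)

        parts = [(live_nodes[~burst_mask & ~div_mask],
                  live_foll[~burst_mask & ~div_mask],
                  live_seq[~burst_mask & ~div_mask])]
        if div_mask.any():
            parts.append(spawn_daughters(
                live_nodes[div_mask], live_foll[div_mask], live_seq[div_mask],
                zero_shm=False, gen=gen))
        if burst_mask.any():
            b_nodes = live_nodes[burst_mask]
            b_foll = live_foll[burst_mask]
            b_seq = live_seq[burst_mask]
            for _ in range(params.burst_divisions):
                b_nodes, b_foll, b_seq = spawn_daughters(
                    b_nodes, b_foll, b_seq, zero_shm=True, gen=gen)
            parts.append((b_nodes, b_foll, b_seq))
        live_nodes = np.concatenate([p[0] for p in parts])
        live_foll = np.concatenate([p[1] for p in parts])
        live_seq = np.concatenate([p[2] for p in parts], axis=0)

        # per-follicle carrying capacity with uniform culling
        cap = params.carrying_capacity
        if cap is not None:
            keep_idx = []
            for fid in ids:
                where = np.nonzero(live_foll == fid)[0]
                if len(where) > cap:
                    where = rng.permutation(where)[:cap]
                keep_idx.append(where)
            keep_idx = np.sort(np.concatenate(keep_idx))
            live_nodes, live_foll, live_seq = (
                live_nodes[keep_idx], live_foll[keep_idx], live_seq[keep_idx])

    # detection sampling
    n_live, n_asc = len(live_nodes), len(asc_nodes)
    detect = rng.random(n_live + n_asc) < params.sample_prob
    sampled: list[tuple[int, np.ndarray, int, bool]] = []  # node, seq, follicle, is_asc
    for j in range(n_live):
        if detect[j]:
            sampled.append((int(live_nodes[j]), live_seq[j], int(live_foll[j]), False))
    for j in range(n_asc):
        if detect[n_live + j]:
            sampled.append((asc_nodes[j], asc_seqs[j], EXTRAFOLLICULAR, True))

    records, node_to_umi = _emit_records(
        sampled, germline, fmap, params, rng, lineage_id)
    tree, pruned_nodes = _prune_genealogy(
        gen_log, [s[0] for s in sampled], node_to_umi, L, lineage_id)
    n_pruned = 0
    for ev in events:
        ev.on_pruned_tree = ev.node_id in pruned_nodes
        n_pruned += ev.on_pruned_tree
    stats = {
        "founder_follicles": founder_follicles,
        "n_divisions": n_divisions,
        "n_migrations": n_migrations,
        "n_events_pruned": n_pruned,
        "germline": _seq_to_str(germline),
        "q_realized": q,
    }
    return records, tree, events, stats


def _seq_to_str(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def _emit_records(sampled, germline, fmap, params, rng, lineage_id):
    """Build UmiRecords for sampled cells; returns (records, node->umi map)."""
    jlen = int(rng.choice([36, 39, 42, 45, 48, 51]))
    junction = _seq_to_str(rng.integers(0, 4, size=jlen).astype(np.uint8))
    v_call = f"IGHV{1 + rng.integers(0, 7)}-{1 + rng.integers(0, 9)}"
    j_call = f"IGHJ{1 + rng.integers(0, 6)}"
    germline_str = _seq_to_str(germline)
    lo, hi = 0.0, params.arena_size
    records = []
    node_to_umi: dict[int, str] = {}
    for k, (node, seq, follicle, is_asc) in enumerate(sampled):
        umi_id = f"L{lineage_id:04d}U{k:05d}"
        node_to_umi[node] = umi_id
        if is_asc:
            x, y = _extrafollicular_point(fmap, params, rng)
        else:
            cx, cy = fmap.centroids[follicle]
            x = float(np.clip(cx + rng.normal(0, params.follicle_radius / 2), lo, hi))
            y = float(np.clip(cy + rng.normal(0, params.follicle_radius / 2), lo, hi))
        vseq = _seq_to_str(seq)
        records.append(UmiRecord(
            umi_id=umi_id,
            sequence=vseq + junction,
            v_sequence=vseq,
            germline_v=germline_str,
            v_call=v_call,
            j_call=j_call,
            junction=junction,
            follicle_id=EXTRAFOLLICULAR if is_asc else follicle,
            compartment="ASC" if is_asc else "GC",
            x=x,
            y=y,
            section=int(rng.integers(0, params.n_sections)),
            lineage_id=lineage_id,
            root_divergence=float((seq != germline).mean()),
        ))
    return records, node_to_umi


def _extrafollicular_point(fmap, params, rng):
    lo, hi = 0.0, params.arena_size
    for _ in range(100):
        x, y = rng.uniform(lo, hi, size=2)
        if all(math.hypot(x - cx, y - cy) > fmap.radius
               for cx, cy in fmap.centroids.values()):
            return float(x), float(y)
    return float(x), float(y)  # dense arena fallback


def _prune_genealogy(gen_log, sampled_nodes, node_to_umi, v_length, lineage_id):
    """Prune the full genealogy to sampled leaves, collapsing unary chains.

    Returns the pruned :class:`LineageTree` (root = germline ancestor) and
    the set of genealogy node ids lying on retained root-to-leaf paths.
    """
    keep: set[int] = set()
    for node in sampled_nodes:
        cur = node
        while cur != -1 and cur not in keep:
            keep.add(cur)
            cur = gen_log.parent[cur]
    if not sampled_nodes:
        return None, keep

    children: dict[int, list[int]] = {}
    for node in keep:
        p = gen_log.parent[node]
        if p != -1 and p in keep:
            children.setdefault(p, []).append(node)

    sampled_set = set(sampled_nodes)

    def build(node_id: int, muts_acc: int) -> Node:
        kids = children.get(node_id, [])
        # collapse unary, unsampled chains
        while len(kids) == 1 and node_id not in sampled_set:
            child = kids[0]
            muts_acc += gen_log.muts[child]
            node_id = child
            kids = children.get(node_id, [])
        node = Node(
            name=node_to_umi.get(node_id),
            length=muts_acc / v_length,
            label=gen_log.follicle[node_id],
        )
        for child in kids:
            node.add(build(child, gen_log.muts[child]))
        return node

    root_node = build(0, 0)
    return LineageTree(root_node, lineage_id), keep


# ---------------------------------------------------------------------------
# Whole-tonsil simulation
# ---------------------------------------------------------------------------

def simulate_tonsil(params: SimParams, seed,
                    uniform_destinations: bool = False) -> SimResult:
    """Simulate ``n_lineages`` independent lineages in one shared arena.

    Deterministic per seed: the follicle map and each lineage draw from
    independent child streams of the same seed sequence, so the re-entry
    variant at the same seed shares the map, founders and genealogy structure.
    """
    params.validate()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(params.n_lineages + 1)
    fmap = make_follicle_map(params.n_follicles, params.arena_size,
                             children[0], radius=params.follicle_radius)
    dest_cdf = None
    if params.n_follicles > 1:
        dest_cdf = _destination_cdfs(fmap, params.locality_scale,
                                     uniform_destinations)
    truth = SimTruth()
    all_records = []
    for lid in range(params.n_lineages):
        records, tree, events, stats = simulate_lineage(
            params, fmap, children[lid + 1], lineage_id=lid,
            uniform_destinations=uniform_destinations, dest_cdf=dest_cdf)
        all_records.extend(records)
        if tree is not None:
            truth.genealogies[lid] = tree
        truth.events.extend(events)
        truth.founder_follicles[lid] = stats["founder_follicles"]
        truth.germlines[lid] = stats["germline"]
        truth.n_divisions[lid] = stats["n_divisions"]
        truth.n_migrations[lid] = stats["n_migrations"]
        truth.n_events_pruned[lid] = stats["n_events_pruned"]
    if not all_records:
        raise SimulationError(
            "no cells sampled; increase sample_prob or generations")
    return SimResult(all_records, fmap, truth, params)


def reentry_variant(params: SimParams, seed) -> SimResult:
    """Memory re-entry null: destinations uniform over the other follicles."""
    return simulate_tonsil(params, seed, uniform_destinations=True)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def write_simulation(result: SimResult, outdir, truth: bool = True) -> None:
    """Write the repertoire table, follicle map, params and (optionally) truth."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_repertoire_table(result.records, os.path.join(outdir, "repertoire.tsv"))
    with open(os.path.join(outdir, "follicle_map.tsv"), "w", encoding="utf-8") as fh:
        fh.write("follicle_id\tx\ty\n")
        for fid in result.follicle_map.follicle_ids:
            x, y = result.follicle_map.centroids[fid]
            fh.write(f"{fid}\t{x!r}\t{y!r}\n")
    with open(os.path.join(outdir, "params.txt"), "w", encoding="utf-8") as fh:
        for key, val in result.params.to_dict().items():
            fh.write(f"{key}={val}\n")
    if truth:
        with open(os.path.join(outdir, "true_events.tsv"), "w", encoding="utf-8") as fh:
            fh.write("lineage_id\tnode_id\tsource\tdestination\tgeneration\ton_pruned_tree\n")
            for ev in result.truth.events:
                fh.write(f"{ev.lineage_id}\t{ev.node_id}\t{ev.source}\t"
                         f"{ev.destination}\t{ev.generation}\t{int(ev.on_pruned_tree)}\n")
        with open(os.path.join(outdir, "genealogies.nwk"), "w", encoding="utf-8") as fh:
            for lid in sorted(result.truth.genealogies):
                fh.write(result.truth.genealogies[lid].to_newick() + "\n")
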