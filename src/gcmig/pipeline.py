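"""Pipeline orchestration: run the analysis stages in dependency order.

Produces per-stage TSV/JSON artifacts plus a manifest recording the config
hash, seeds and record counts, so identical configs reproduce identical
summaries byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from gcmig import clock, fate, homogeneity, phylo, spatial
from gcmig.repertoire import (
    assign_root_divergences,
    cluster_lineages,
    follicle_map_from_records,
    lineage_summaries,
    read_repertoire_table,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    input: str = ""
    outdir: str = "gcmig_out"
    trees_file: Optional[str] = None       # newick import (lineage_id<TAB>newick)
    tree_mode: str = "nj"                  # nj | newick
    stages: tuple = ("cluster", "spatial", "clock", "trees", "homogeneity", "fate")
    junction_identity_min: float = 0.85
    clonal_min_root_div: float = 0.01
    early_threshold: float = 0.01
    near_zero_edge: float = 0.005
    short_branch_threshold: float = 0.002
    min_migration_root_div: float = 0.0
    shuffle_reps: int = 100
    n_boot: int = 100
    cv_grid: tuple = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5)
    seed_spatial: int = 1
    seed_clock: int = 2
    seed_homogeneity: int = 3
    seed_fate: int = 4

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        cfg = cls()
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if not hasattr(cfg, key):
                    raise PipelineError("config", f"unknown key {key!r}")
                current = getattr(cfg, key)
                if isinstance(current, tuple):
                    parsed = tuple(type(current[0])(v) for v in value.split(","))
                elif isinstance(current, bool):
                    parsed = value.strip().lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    parsed = int(value)
                elif isinstance(current, float):
                    parsed = float(value)
                else:
                    parsed = value.strip()
                setattr(cfg, key, parsed)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(path: str, payload) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest = {"config_hash": config.config_hash(),
                "config": asdict(config), "stages": {}}

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    try:
        records = read_repertoire_table(config.input)
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc
    manifest["n_records"] = len(records)

    if "cluster" in config.stages:
        try:
            if any(r.lineage_id is None for r in records):
                n_missing = cluster_lineages(
                    records, junction_identity_min=config.junction_identity_min)
            else:
                n_missing = 0
            assign_root_divergences(records)
            lineages = lineage_summaries(records)
            manifest["stages"]["cluster"] = {
                "n_lineages": len(lineages),
                "n_missing_junction": n_missing,
            }
        except Exception as exc:
            raise PipelineError("cluster", str(exc)) from exc
    else:
        lineages = lineage_summaries(records)

    fmap = follicle_map_from_records(records)

    if "spatial" in config.stages:
        try:
            hist = spatial.follicle_count_histogram(records)
            p_geom = spatial.fit_truncated_geometric(hist)
            shuffle = spatial.well_mixed_shuffle(
                records, n_reps=config.shuffle_reps, seed=config.seed_spatial)
            dist = spatial.related_pair_distances(
                records, seed=config.seed_spatial, fmap=fmap)
            clonal_dist = spatial.related_pair_distances(
                records, min_root_div=config.clonal_min_root_div,
                clonal_only=True, seed=config.seed_spatial, fmap=fmap)
            _write_tsv(out("follicle_count_histogram.tsv"),
                       ["k", "n_lineages", "error", "shuffled_mean", "shuffled_sem"],
                       [[k, hist.counts[k], hist.errors[k],
                         shuffle.shuffled_mean.get(k, 0.0),
                         shuffle.shuffled_sem.get(k, 0.0)]
                        for k in sorted(hist.counts)])
            _write_json(out("spatial_summary.json"), {
                "p_geom": p_geom,
                "intra_median_um": dist.normalizer,
                "related_median": dist.related_median,
                "background_median": dist.background_median,
                "tail_fraction": dist.tail_fraction,
                "clonal_related_median": clonal_dist.related_median,
                "clonal_tail_fraction": clonal_dist.tail_fraction,
                "n_related_pairs": int(len(dist.related)),
            })
            manifest["stages"]["spatial"] = {"p_geom": p_geom,
                                             "tail_fraction": dist.tail_fraction}
        except Exception as exc:
            raise PipelineError("spatial", str(exc)) from exc

    if "clock" in config.stages:
        try:
            intra_divs = [r.root_divergence for r in records if r.intrafollicular]
            asc_divs = [r.root_divergence for r in records
                        if r.compartment == "ASC"]
            alpha = clock.fit_exponential_divergence(intra_divs)
            curve = clock.pairwise_migration_curve(
                records, near_zero_edge=config.near_zero_edge,
                seed=config.seed_clock)
            burst = clock.clonal_burst_analysis(
                records, min_root_div=config.clonal_min_root_div)
            trend = clock.asc_age_trend(records)
            _write_tsv(out("pairwise_curve.tsv"),
                       ["x_lo", "x_hi", "p_diff_follicle", "err", "n_pairs"],
                       [[curve.bin_edges[i], curve.bin_edges[i + 1],
                         curve.bin_prob[i], curve.bin_err[i], curve.bin_n[i]]
                        for i in range(len(curve.bin_n))])
            _write_json(out("clock_fits.json"), {
                "alpha": alpha,
                "asc_median_divergence": (float(np.median(asc_divs))
                                          if asc_divs else None),
                "beta": None if np.isinf(curve.beta) else curve.beta,
                "intercept_excess": curve.intercept_excess,
                "n_pairs": curve.n_pairs,
                "p_burst": burst.p_burst,
                "aggregate_burst_multifollicular": burst.aggregate_multifollicular,
                "n_burst_groups": len(burst.groups),
                "asc_age_rank_correlation": trend.correlation,
            })
            manifest["stages"]["clock"] = {"alpha": alpha, "beta": curve.beta,
                                           "p_burst": burst.p_burst}
        except Exception as exc:
            raise PipelineError("clock", str(exc)) from exc

    trees = []
    events: dict = {}
    if "trees" in config.stages or "homogeneity" in config.stages \
            or "fate" in config.stages:
        try:
            newicks = {}
            if config.tree_mode == "newick":
                if not config.trees_file:
                    raise ValueError("tree_mode 'newick' requires trees_file")
                with open(config.trees_file, "r", encoding="utf-8") as fh:
                    for line in fh:
                        lid, _, nwk = line.strip().partition("\t")
                        newicks[int(lid)] = nwk
            by_lineage: dict[int, list] = {}
            for rec in records:
                by_lineage.setdefault(rec.lineage_id, []).append(rec)
            skipped = 0
            for lid in sorted(by_lineage):
                if config.tree_mode == "newick" and lid not in newicks:
                    skipped += 1
                    continue
                tree = phylo.build_tree(
                    by_lineage[lid], mode=config.tree_mode,
                    newick=newicks.get(lid), lineage_id=lid)
                if tree is None:
                    skipped += 1
                    continue
                phylo.parsimony_labels(tree)
                events[lid] = phylo.extract_migrations(
                    tree, early_threshold=config.early_threshold)
                trees.append(tree)
            if not trees:
                raise ValueError("no lineage had >=2 distinct intrafollicular sequences")
            rates = phylo.estimate_rates(trees, events)
            _write_tsv(out("migration_events.tsv"),
                       ["lineage_id", "branch_id", "parent_label", "child_label",
                        "depth", "branch_length", "is_early"],
                       [[e.lineage_id, e.branch_id, e.parent_label, e.child_label,
                         e.depth, e.branch_length, int(e.is_early)]
                        for evs in events.values() for e in evs])
            with open(out("trees.nwk"), "w", encoding="utf-8") as fh:
                for tree in trees:
                    fh.write(f"{tree.lineage_id}\t{tree.to_newick()}\n")
            size_strata = phylo.stratify_rates(trees, events, by="size")
            depth_strata = phylo.stratify_rates(trees, events, by="depth")
            _write_json(out("rates.json"), {
                "m_global": rates.m_global,
                "n_trees": len(trees),
                "n_skipped": skipped,
                "per_lineage": {str(k): v for k, v in rates.per_lineage.items()},
                "curve": rates.curve,
                "size_strata": size_strata,
                "depth_strata": depth_strata,
            })
            manifest["stages"]["trees"] = {"n_trees": len(trees),
                                           "m_global": rates.m_global}
        except Exception as exc:
            raise PipelineError("trees", str(exc)) from exc

    if "homogeneity" in config.stages:
        try:
            hom = homogeneity.poisson_resample(
                rates, n_boot=config.n_boot, seed=config.seed_homogeneity)
            burst = clock.clonal_burst_analysis(
                records, min_root_div=config.clonal_min_root_div)
            filtered = homogeneity.burst_filter(
                rates, events, burst,
                short_branch_threshold=config.short_branch_threshold)
            hom_f = homogeneity.poisson_resample(
                filtered, n_boot=config.n_boot,
                seed=config.seed_homogeneity, burst_filtered=True)
            cvb = homogeneity.cv_upper_bound(
                rates, cv_grid=config.cv_grid, seed=config.seed_homogeneity)
            n_lineages_intra = sum(
                1 for lin in lineage_summaries(records).values()
                if lin.n_umis_intra > 0)
            pred = homogeneity.predict_follicle_counts(
                rates, n_treeless=n_lineages_intra - len(trees),
                m_hat=hom.m_refit, n_boot=config.n_boot,
                seed=config.seed_homogeneity)
            _write_tsv(out("predicted_follicle_counts.tsv"),
                       ["k", "mean", "sem"],
                       [[k, v[0], v[1]] for k, v in sorted(pred.items())])
            _write_json(out("homogeneity.json"), {
                "m_refit": hom.m_refit,
                "coverage_2sd": hom.coverage(),
                "m_refit_burst_filtered": hom_f.m_refit,
                "coverage_2sd_burst_filtered": hom_f.coverage(),
                "cv_upper": cvb.cv_upper,
                "cv_table": cvb.table,
                "grid": hom.grid,
                "observed_survival": hom.observed_survival,
                "envelope_mean": hom.envelope_mean,
                "envelope_sd": hom.envelope_sd,
            })
            manifest["stages"]["homogeneity"] = {
                "m_refit": hom.m_refit, "cv_upper": cvb.cv_upper}
        except Exception as exc:
            raise PipelineError("homogeneity", str(exc)) from exc

    if "fate" in config.stages:
        try:
            sub_rows = []
            zero_obs, zero_shuf = [], []
            rng = np.random.default_rng(config.seed_fate)
            for tree in trees:
                recs = fate.decompose_subtrees(tree)
                for r in recs:
                    sub_rows.append([r.lineage_id, r.label, r.divergence,
                                     r.n_leaves, int(r.follows_migration)])
                n_ev = len(events[tree.lineage_id])
                if n_ev >= 1:
                    try:
                        sh = fate.shuffle_migrations(
                            tree, n_ev, n_reps=config.shuffle_reps,
                            seed=rng.integers(2 ** 63))
                    except fate.FateError:
                        continue
                    if not np.isnan(sh.observed_zero_fraction):
                        zero_obs.append(sh.observed_zero_fraction)
                        zero_shuf.append(float(sh.shuffled_zero_fractions.mean()))
            _write_tsv(out("subtrees.tsv"),
                       ["lineage_id", "follicle", "divergence", "n_leaves",
                        "follows_migration"], sub_rows)
            comp = fate.migrant_composition(
                records, trees,
                min_migration_root_div=config.min_migration_root_div)
            _write_tsv(out("follicle_composition.tsv"),
                       ["follicle_id", "n_umis", "migrant_umi_fraction",
                        "migrant_lineage_fraction", "top_lineage_frequency",
                        "top_migrant_frequency"],
                       [[c.follicle_id, c.n_umis, c.migrant_umi_fraction,
                         c.migrant_lineage_fraction, c.top_lineage_frequency,
                         c.top_migrant_frequency] for c in comp])
            manifest["stages"]["fate"] = {
                "n_subtrees": len(sub_rows),
                "zero_fraction_observed": (float(np.mean(zero_obs))
                                           if zero_obs else None),
                "zero_fraction_shuffled": (float(np.mean(zero_shuf))
                                           if zero_shuf else None),
            }
        except Exception as exc:
            raise PipelineError("fate", str(exc)) from exc

    _write_json(out("manifest.json"), manifest)
    return manifest


def _write_tsv(path: str, header, rows) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
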