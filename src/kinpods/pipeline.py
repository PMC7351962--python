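"""One-command orchestration of the full kin-structure analysis.

Stages, in order: parse genotypes and groups → drop individuals typed at
fewer than six loci → allele frequencies from the survivors → pairwise
relatedness matrices (both estimators) → ML relationship classification →
per-group mtDNA lineage and relationship-category proportions → group
relatedness summaries → within/between-matriline permutation contrast
(groups with ≥ 2 haplotypes) → PO exclusion and sibship frequency tests
(groups with more than 14 genotyped members) → relatedness networks on the
≥ 7-loci subset → behavioural diversity D. Every stochastic step draws its
seed deterministically from the run seed, so a repeated run produces a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import behaviour as _behaviour
from . import classify as _classify
from . import group_tests as _gt
from . import io as _io
from . import networks as _net
from . import relatedness as _rel
from .core import compute_allele_frequencies, filter_min_loci
from .errors import (
    ArgumentError,
    CalibrationError,
    InsufficientDataError,
    KinpodsError,
    PipelineError,
    UndefinedEstimateError,
    UntestableError,
)

ESTIMATORS = ("r_QG", "M_xy")


@dataclass
class PipelineConfig:
    """All tunables for a run; flat so it round-trips through YAML cleanly."""

    min_loci: int = 6
    network_min_loci: int = 7
    min_shared_loci: int = 6
    error_rate: float = 0.0           # classification error model
    po_exclusion_error_rate: float = 0.0
    n_permutations: int = 50_000      # matriline contrast
    sibship_n_sim: int = 1_000        # threshold calibration dyads/category
    sibship_n_randomizations: int = 100
    sibship_min_group: int = 15       # groups with > 14 genotyped members
    network_mode: str = "auto_percolation"
    manual_threshold: Optional[float] = None
    behaviour_mode: str = "unbiased"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_seed(base: int, stage: int, index: int = 0) -> int:
    # stable small-int derivation; keeps derived seeds below 2**31
    return (base * 1_000_003 + stage * 10_007 + index * 101) % (2**31 - 1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    return obj


def run_full_analysis(genotype_path, groups_path,
                      config: Optional[PipelineConfig] = None) -> dict:
    """Run every analysis stage and return the machine-readable report."""
    cfg = config or PipelineConfig()
    report: Dict = {"meta": {"seed": cfg.seed, "config": _jsonable(asdict(cfg))}}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except KinpodsError as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrap

    records = stage("parse_genotypes")(_io.parse_genotype_table, genotype_path)
    groups = stage("parse_groups")(_io.parse_groups_csv, groups_path)
    if not records:
        raise ArgumentError("empty genotype dataset")
    report["meta"]["n_individuals"] = len(records)

    passing = stage("filter_min_loci")(filter_min_loci, records, cfg.min_loci)
    report["meta"]["n_passing_min_loci"] = len(passing)
    report["meta"]["n_dropped_min_loci"] = len(records) - len(passing)
    if len(passing) < 2:
        raise PipelineError("stage 'filter_min_loci': fewer than 2 individuals pass")

    freqs = stage("allele_frequencies")(compute_allele_frequencies, passing)
    report["allele_frequencies"] = _jsonable(freqs.as_dict())

    matrices = {
        est: stage("relatedness")(
            _rel.relatedness_matrix, passing, est, freqs, cfg.min_shared_loci
        )
        for est in ESTIMATORS
    }
    calls = stage("classification")(
        _classify.classify_all_pairs, passing, freqs, cfg.error_rate,
        cfg.min_shared_loci,
    )
    call_by_pair = {frozenset((c.id1, c.id2)): c for c in calls}
    by_id = {r.id: r for r in passing}

    # sibship thresholds are calibrated once per estimator from the
    # reference frequencies and shared by every tested group
    thresholds: Dict[str, object] = {}
    for k, est in enumerate(ESTIMATORS):
        try:
            thresholds[est] = _gt.calibrate_sibship_thresholds(
                freqs, est, cfg.sibship_n_sim, _stage_seed(cfg.seed, 1, k)
            )
        except (CalibrationError, ArgumentError) as exc:
            thresholds[est] = None
            report.setdefault("warnings", []).append(
                f"sibship calibration failed for {est}: {exc}"
            )

    report["groups"] = {}
    for gi, group in enumerate(sorted(groups, key=lambda g: g.group_id)):
        members = [by_id[m] for m in group.member_ids if m in by_id]
        entry: Dict = {
            "group_type": group.group_type,
            "size_observed": group.size_observed,
            "n_members_listed": len(group.member_ids),
            "n_members_genotyped": len(members),
        }
        report["groups"][group.group_id] = entry

        # mtDNA lineage tallies
        haps = [m.mtdna for m in members if m.mtdna]
        if haps:
            counts = {h: haps.count(h) for h in sorted(set(haps))}
            entry["lineages"] = {
                "counts": counts,
                "proportions": {h: c / len(haps) for h, c in counts.items()},
                "n_lineages": len(counts),
            }

        # relationship-category proportions over classified pairs
        ids = [m.id for m in members]
        pair_calls = [
            call_by_pair[frozenset((a, b))]
            for i, a in enumerate(ids)
            for b in ids[i + 1:]
            if frozenset((a, b)) in call_by_pair
        ]
        if pair_calls:
            cat_counts = {c: 0 for c in _classify.CATEGORIES}
            for c in pair_calls:
                cat_counts[c.best] += 1
            entry["relationships"] = {
                "counts": cat_counts,
                "proportions": {
                    k: v / len(pair_calls) for k, v in cat_counts.items()
                },
                "n_pairs": len(pair_calls),
            }

        # relatedness summaries
        entry["relatedness"] = {}
        for est in ESTIMATORS:
            try:
                entry["relatedness"][est] = _jsonable(
                    _gt.group_mean_r_summary(matrices[est], ids)
                )
            except InsufficientDataError as exc:
                entry["relatedness"][est] = {"unavailable": str(exc)}

        # matriline contrast (r_QG, as a moment estimator of r)
        try:
            entry["matriline_contrast"] = _jsonable(
                _gt.matriline_contrast_test(
                    matrices["r_QG"], members, cfg.n_permutations,
                    _stage_seed(cfg.seed, 2, gi),
                )
            )
        except (UntestableError, InsufficientDataError) as exc:
            entry["matriline_contrast"] = {"untestable": str(exc)}

        # sibship frequency test on larger groups, after PO exclusion
        if len(members) >= cfg.sibship_min_group:
            kept = _classify.exclude_po_pairs(
                members, freqs, cfg.po_exclusion_error_rate, cfg.min_shared_loci
            )
            entry["sibship_po_excluded"] = len(members) - len(kept)
            entry["sibship_test"] = {}
            for k, est in enumerate(ESTIMATORS):
                if thresholds[est] is None:
                    entry["sibship_test"][est] = {"unavailable": "calibration failed"}
                    continue
                try:
                    entry["sibship_test"][est] = _jsonable(
                        _gt.sibship_frequency_test(
                            kept, freqs, est, thresholds[est],
                            cfg.sibship_n_randomizations,
                            _stage_seed(cfg.seed, 3, gi * 2 + k),
                            cfg.min_shared_loci,
                        )
                    )
                except (InsufficientDataError, ArgumentError) as exc:
                    entry["sibship_test"][est] = {"unavailable": str(exc)}
        else:
            entry["sibship_test"] = {
                "skipped": f"group has {len(members)} genotyped members; "
                f"test requires more than {cfg.sibship_min_group - 1}"
            }

    # networks on the >= 7-loci subset
    passing7 = filter_min_loci(records, cfg.network_min_loci)
    by_id7 = {r.id: r for r in passing7}
    report["network"] = {"min_loci": cfg.network_min_loci,
                         "n_individuals": len(passing7), "groups": {}}
    net_matrix = None
    if len(passing7) >= 2:
        net_matrix = _rel.relatedness_matrix(
            passing7, "r_QG", freqs, cfg.network_min_loci
        )
    for group in sorted(groups, key=lambda g: g.group_id):
        ids7 = [m for m in group.member_ids if m in by_id7]
        if net_matrix is None or len(ids7) < 3:
            report["network"]["groups"][group.group_id] = {
                "unavailable": f"{len(ids7)} members typed at "
                f">= {cfg.network_min_loci} loci"
            }
            continue
        sub = _rel.relatedness_matrix(
            [by_id7[x] for x in ids7], "r_QG", freqs, cfg.network_min_loci
        )
        try:
            net = _net.build_kin_network(
                sub,
                calls=[c for c in calls
                       if c.id1 in set(ids7) and c.id2 in set(ids7)],
                mode=cfg.network_mode,
                manual_threshold=cfg.manual_threshold,
                node_attributes=[by_id7[x] for x in ids7],
                require_min_loci=cfg.network_min_loci,
            )
            metrics = _net.node_metrics(net)
        except (ArgumentError, KinpodsError) as exc:
            report["network"]["groups"][group.group_id] = {"unavailable": str(exc)}
            continue
        node_table = {
            x: {
                "k": metrics.degree[x],
                "bc": metrics.betweenness[x],
                "C": metrics.clustering[x],
                "C_defined": metrics.clustering_defined[x],
            }
            for x in sorted(net.graph.nodes)
        }
        attr_tests = {}
        for attr in ("mtdna", "sex", "age_class"):
            try:
                attr_tests[attr] = _jsonable(
                    _net.compare_node_attributes(net, metrics, attr)
                )
            except UntestableError as exc:
                attr_tests[attr] = {"untestable": str(exc)}
        report["network"]["groups"][group.group_id] = {
            "mode": net.mode,
            "threshold": net.threshold,
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
            "mean_k": float(np.mean(list(metrics.degree.values()))),
            "mean_bc": float(np.mean(list(metrics.betweenness.values()))),
            "mean_C": float(np.mean(list(metrics.clustering.values()))),
            "nodes": node_table,
            "attribute_tests": attr_tests,
        }

    # behavioural diversity
    report["behaviour"] = {}
    for group in sorted(groups, key=lambda g: g.group_id):
        tally = group.behaviour
        if tally is None or tally.n < 2:
            report["behaviour"][group.group_id] = {"unavailable": "no tally (n < 2)"}
            continue
        try:
            report["behaviour"][group.group_id] = {
                "counts": dict(zip(tally.CATEGORIES, tally.counts)),
                "n": tally.n,
                "D": _behaviour.behaviour_diversity_D(tally, cfg.behaviour_mode),
                "mode": cfg.behaviour_mode,
            }
        except UndefinedEstimateError as exc:
            report["behaviour"][group.group_id] = {"unavailable": str(exc)}

    return _jsonable(report)


def report_to_json(report: dict) -> str:
    """Canonical serialisation: sorted keys, fixed indentation, no
    timestamps — repeated runs with the same seed are byte-identical."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=False) + "\n"


def write_report(report: dict, out_dir) -> Path:
    """Write report.json plus flat CSV side tables (sibship results and
    behaviour D values)."""
    import csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(report_to_json(report), encoding="utf-8")

    with open(out / "sibship.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["group", "n", "estimator", "observed_sib_proportion",
                    "expected_sib_proportion", "chi2", "p"])
        for gid in sorted(report.get("groups", {})):
            tests = report["groups"][gid].get("sibship_test", {})
            for est in sorted(tests):
                t = tests[est]
                if not isinstance(t, dict) or "p" not in t:
                    continue
                w.writerow([gid, t["n_individuals"], est,
                            t["observed_sib_proportion"],
                            t["expected_sib_proportion"], t["chi2"], t["p"]])

    with open(out / "behaviour.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["group", "n", "travel", "mill", "social", "other", "D"])
        for gid in sorted(report.get("behaviour", {})):
            b = report["behaviour"][gid]
            if "D" not in b:
                continue
            c = b["counts"]
            w.writerow([gid, b["n"], c["travel"], c["mill"], c["social"],
                        c["other"], b["D"]])
    return path
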