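"""End-to-end orchestration: simulate -> networks -> key-scores -> function links.

``run_all`` reproduces the full analysis shape on synthetic or user data:
per-generation signed networks (GraphML + edge list + association
report), key-score tables, taxon-function association tables for
TPH/saturates/aromatics, alpha/beta diversity, core/shared/unique taxon
counts, a run manifest with config snapshot and output checksums, and —
when simulating — a ground-truth recovery report.

One global seed fans out deterministically to per-stage child seeds
through ``numpy.random.SeedSequence``, so any stage can be re-run in
isolation and a rerun with the same config yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    AbundanceTable,
    ConsortiumNetwork,
    DegradationRecord,
    PipelineConfig,
    write_abundance_table,
    write_degradation_records,
    write_network,
)
from .ensemble import AssociationResult, infer_network
from .function_link import (
    FunctionAssociation,
    community_metrics,
    core_and_unique,
    taxon_function_scores,
)
from .keystone import KeyScoreTable, keystone_table, rank_keystones
from .synthetic import simulate_study, study_spec

__all__ = ["run_all", "recovery_report"]

REPORTED_FRACTIONS = ("TPH", "saturates", "aromatics")


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def _association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"taxonA": r.taxon_a, "taxonB": r.taxon_b}
        for m, v in r.scores.items():
            row[f"score_{m}"] = v
            row[f"p_{m}"] = r.pvalues.get(m, math.nan)
        row.update(merged_p=r.merged_p, q=r.qvalue, sign=r.sign, weight=r.weight)
        rows.append(row)
    return pd.DataFrame(rows)


def _function_frame(assocs: list[FunctionAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon": [a.taxon for a in assocs],
            "fraction": [a.fraction for a in assocs],
            **{
                f"z_{m}": [a.measure_z.get(m, math.nan) for a in assocs]
                for m in ("bray_curtis", "pearson", "spearman", "mi", "gblm")
            },
            "combined": [a.combined for a in assocs],
            "p": [a.pvalue for a in assocs],
            "q": [a.qvalue for a in assocs],
            "direction": [a.direction for a in assocs],
        }
    )


def run_all(
    config: PipelineConfig,
    out_dir: str | Path,
    table: AbundanceTable | None = None,
    responses: list[DegradationRecord] | None = None,
    simulate: bool = False,
    truth: dict | None = None,
) -> Path:
    """Run every stage and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    seeds = _child_seeds(config.seed, 8)

    if simulate:
        spec = study_spec(seed=seeds[0])
        table, responses, truth = simulate_study(spec)
        write_abundance_table(table, out / "abundance.tsv")
        write_degradation_records(responses, out / "degradation.csv")
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    if table is None:
        raise ValueError("no input table: pass `table` or set simulate=True")

    rel = table.to_relative() if table.mode != "relative" else table
    generations = rel.generation_labels()

    networks: dict[str, ConsortiumNetwork] = {}
    keyscores: dict[str, KeyScoreTable] = {}
    for gi, gen in enumerate(generations):
        gen_config = dataclasses.replace(config, seed=_child_seeds(seeds[1], len(generations))[gi])
        net, results = infer_network(rel, gen_config, generation=gen)
        networks[gen] = net
        write_network(net, out / f"network_{gen}.graphml", fmt="graphml")
        write_network(net, out / f"network_{gen}.edgelist.tsv", fmt="edgelist")
        _write_tsv(_association_frame(results), out / f"associations_{gen}.tsv",
                   chash, index=False)
        ks = keystone_table(net)
        keyscores[gen] = ks
        frame = ks.frame.copy()
        frame["rank"] = [rank_keystones(ks).index(t) + 1 for t in frame.index]
        _write_tsv(frame, out / f"keyscores_{gen}.tsv", chash)

    assocs: dict[str, list[FunctionAssociation]] = {}
    if responses is not None:
        for fi, fraction in enumerate(REPORTED_FRACTIONS):
            fr = taxon_function_scores(
                rel, responses, fraction,
                permutations=max(config.permutations, 200),
                seed=_child_seeds(seeds[2], len(REPORTED_FRACTIONS))[fi],
                gblm_shrinkage=config.gblm_shrinkage,
                gblm_iterations=config.gblm_iterations,
            )
            assocs[fraction] = fr
            _write_tsv(_function_frame(fr), out / f"function_{fraction}.tsv",
                       chash, index=False)

    alpha, beta = community_metrics(rel)
    _write_tsv(alpha, out / "alpha_diversity.tsv", chash)
    _write_tsv(beta, out / "beta_diversity.tsv", chash)

    per_gen = [rel.select_generation(g) for g in generations]
    venn = core_and_unique(per_gen)
    (out / "core_unique.json").write_text(json.dumps(
        {
            "core": sorted(venn["core"]),
            "shared": sorted(venn["shared"]),
            "unique": {g: sorted(u) for g, u in venn["unique"].items()},
            "counts": venn["counts"],
        },
        indent=1,
    ))

    if truth is not None:
        report = {}
        for gen in generations:
            report[gen] = recovery_report(
                truth, networks[gen], keyscores=keyscores[gen],
                assocs=[a for fr in assocs.values() for a in fr] or None,
            )
        (out / "recovery.json").write_text(json.dumps(report, indent=1))

    manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "version": __version__,
        "stages": {
            "networks": list(networks),
            "function_link": list(assocs),
        },
        "checksums": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def recovery_report(
    truth: dict,
    network: ConsortiumNetwork,
    keyscores: KeyScoreTable | None = None,
    assocs: list[FunctionAssociation] | None = None,
    top_k: int = 5,
) -> dict:
    """Score an inferred network (and optional rankings) against planted truth.

    Edge precision/recall and sign accuracy against ``planted_edges``;
    keystone hit rate = fraction of planted keystone taxa in the top-k of
    the key-score ranking; function-link top-1 hit rate = fraction of
    fractions whose strongest planted driver attains the extreme combined
    coefficient of matching sign.  Undefined ratios are reported as None
    (JSON ``null``).
    """
    truth_edges = {
        frozenset((a, b)): ("+" if rho >= 0 else "-")
        for a, b, rho in truth.get("planted_edges", [])
    }
    truth_taxa = {t for e in truth_edges for t in e}
    missing = truth_taxa - set(network.graph.nodes)
    if missing:
        raise ValueError(f"truth taxa absent from network node set: {sorted(missing)}")

    found = {
        frozenset((a, b)): sign for a, b, sign, _, _ in network.edge_records()
    }
    tp = [e for e in found if e in truth_edges]
    precision = len(tp) / len(found) if found else None
    recall = len(tp) / len(truth_edges) if truth_edges else None
    sign_acc = (
        sum(found[e] == truth_edges[e] for e in tp) / len(tp) if tp else None
    )
    report: dict = {
        "edge_precision": precision,
        "edge_recall": recall,
        "sign_accuracy": sign_acc,
        "n_edges": len(found),
        "n_true_edges": len(truth_edges),
    }

    if keyscores is not None and len(keyscores):
        planted_keystones = {t for t, _, _ in truth.get("keystone_effects", [])}
        if planted_keystones:
            top = set(rank_keystones(keyscores)[:top_k])
            report["keystone_topk_hit_rate"] = (
                len(planted_keystones & top) / len(planted_keystones)
            )

    if assocs:
        by_fraction: dict[str, list[FunctionAssociation]] = {}
        for a in assocs:
            by_fraction.setdefault(a.fraction, []).append(a)
        hits = []
        for fraction, items in by_fraction.items():
            drivers = [
                (t, beta) for t, f, beta in truth.get("keystone_effects", [])
                if f == fraction
            ]
            if not drivers:
                continue
            top_taxon, beta = max(drivers, key=lambda d: abs(d[1]))
            if beta >= 0:
                best = max(items, key=lambda a: a.combined)
            else:
                best = min(items, key=lambda a: a.combined)
            hits.append(best.taxon == top_taxon)
        if hits:
            report["function_top1_hit_rate"] = sum(hits) / len(hits)
    return report
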