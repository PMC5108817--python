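"""End-to-end condition analysis and two-condition comparison.

``run_condition`` executes the fixed stage order — ingest the three edge
lists with the significance skim, build the multilayer network, attach
the omic tracks, tabulate centralities, correlate layers, classify and
summarize mutations, test gene-set enrichment — and returns a
machine-readable report (JSON-serializable dict).  Every number in the
report is recomputable from the inputs, whose SHA-256 digests the report
carries.  ``compare_conditions`` diffs two reports on the gene union and
flags the qualitative two-condition signatures (more genes, a denser
conformation neighborhood around the seed gene, more driver mutations
after the stimulus).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag
from .core import MultilayerNetwork, aggregate_layer, build_multilayer
from .ingest import attach_track, load_edge_list, load_track
from .mutations import (
    classify,
    hypergeometric_enrichment,
    load_gene_set,
    load_mutation_scores,
    mutation_summary_table,
    pathway_flag,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    """Read a pipeline config (YAML or JSON, same schema).

    Relative file paths inside the config are resolved against the
    config file's own directory, so a study directory is relocatable.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError(f"{path}: config must be a mapping")
    for key in ("layers", "mutations"):
        if key not in cfg:
            raise PipelineError(f"{path}: missing config key {key!r}")
    if not cfg["layers"]:
        raise PipelineError(f"{path}: config key 'layers' is empty")

    base = os.path.dirname(os.path.abspath(path))

    def resolve(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    cfg["layers"] = {k: resolve(v) for k, v in cfg["layers"].items()}
    for spec in cfg.get("tracks", {}).values():
        spec["path"] = resolve(spec["path"])
    cfg["mutations"] = resolve(cfg["mutations"])
    cfg["gene_sets"] = {
        k: resolve(v) for k, v in cfg.get("gene_sets", {}).items()
    }
    if "universe" in cfg:
        cfg["universe"] = resolve(cfg["universe"])
    return cfg


def _jsonify(obj):
    """Make a report JSON-serializable: numpy scalars out, NaN -> None."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return None if math.isnan(v) else v
    return obj


def _stage(stage_name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(f"stage {stage_name!r} failed: {exc}") from exc


def build_from_config(config: dict) -> MultilayerNetwork:
    """Ingest the configured edge lists and assemble the multilayer."""
    p_threshold = float(config.get("p_threshold", 0.05))
    layers = []
    for lname in sorted(config["layers"]):
        path = config["layers"][lname]
        layers.append(
            _stage(f"ingest:{lname}", load_edge_list, path,
                   name=lname, p_threshold=p_threshold)
        )
    M = _stage("build", build_multilayer, layers,
               coupling_weight=float(config.get("coupling_weight", 1.0)))
    for tname in sorted(config.get("tracks", {})):
        spec = config["tracks"][tname]
        track = _stage(f"track:{tname}", load_track,
                       spec["path"], tname, spec["layer"])
        _stage(f"attach:{tname}", attach_track, M, track)
    return M


def run_condition(config_path) -> dict:
    """Run the full analysis for one condition; return the report dict."""
    config = load_config(config_path)
    condition = config.get("condition", "condition")
    M = build_from_config(config)

    table = _stage("diagnose", diag.diagnostics_table, M)
    scopes = M.layer_names + [diag.AGGREGATE_SCOPE, diag.MULTILAYER_SCOPE]
    top = {
        scope: {
            metric: diag.top_k(table, metric, scope, k=20)
            for metric in ("degree", "strength")
        }
        for scope in scopes
    }
    assort = {
        metric: {
            method: _stage(
                "correlate", diag.interlayer_assortativity,
                M, metric=metric, method=method,
            ).to_dict()
            for method in ("pearson", "spearman")
        }
        for metric in ("degree", "strength")
    }

    threshold = float(config.get("driver_threshold", 0.7))
    triples = _stage("mutstats:load", load_mutation_scores,
                     config["mutations"])
    mutations = _stage("mutstats:classify", classify, triples,
                       threshold=threshold)
    gene_sets = config.get("gene_sets", {})
    if "metabolic" in gene_sets:
        metabolic = load_gene_set(gene_sets["metabolic"])
        mutations = pathway_flag(mutations, metabolic)
    summary = mutation_summary_table(mutations, condition)

    enrichment = None
    if "disease" in gene_sets and "universe" in config:
        disease = load_gene_set(gene_sets["disease"])
        universe = load_gene_set(config["universe"])
        sample = set(M.gene_universe)
        enrichment = _stage(
            "enrich", hypergeometric_enrichment, sample, disease, universe
        ).to_dict()

    ml = table[table["scope"] == diag.MULTILAYER_SCOPE]
    inputs = {}
    for lname, path in config["layers"].items():
        inputs[f"layer:{lname}"] = _digest(path)
    for tname, spec in config.get("tracks", {}).items():
        inputs[f"track:{tname}"] = _digest(spec["path"])
    inputs["mutations"] = _digest(config["mutations"])

    report = {
        "schema_version": SCHEMA_VERSION,
        "condition": condition,
        "inputs": inputs,
        "parameters": {
            "p_threshold": float(config.get("p_threshold", 0.05)),
            "driver_threshold": threshold,
            "coupling_weight": float(config.get("coupling_weight", 1.0)),
        },
        "gene_count": len(M.gene_universe),
        "seed_gene": config.get("seed_gene"),
        "layers": {
            ly.name: {
                "n_genes": ly.n_nodes,
                "n_edges": ly.n_edges,
                "genes": sorted(ly.nodes),
                "seed_degree": (
                    int(ly.graph.degree(config["seed_gene"]))
                    if config.get("seed_gene") in ly.nodes else 0
                ),
            }
            for ly in M.layers
        },
        "multilayer": {
            "degree": dict(zip(ml["gene"], (int(v) for v in ml["degree"]))),
            "strength": dict(zip(ml["gene"], (float(v) for v in ml["strength"]))),
        },
        "top_k": top,
        "assortativity": assort,
        "mutations": {
            "threshold": threshold,
            "counts": mutations.counts(),
            "summary": summary.to_dict(orient="records"),
        },
        "enrichment": enrichment,
    }
    return _jsonify(report)


def write_report(report: dict, path) -> None:
    """Serialize a report deterministically (sorted keys, fixed floats)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")


def compare_conditions(pre: dict, post: dict) -> dict:
    """Diff two condition reports on their gene union.

    Per-gene multilayer degree/strength deltas (post minus pre), gained
    and lost genes per layer, assortativity and mutation-summary deltas,
    and the qualitative signature flags of a stimulus response.
    """
    if pre.get("schema_version") != post.get("schema_version"):
        raise PipelineError("schema-version mismatch between reports")

    def delta_map(key, cast):
        genes = sorted(
            set(pre["multilayer"][key]) | set(post["multilayer"][key])
        )
        return {
            g: cast(post["multilayer"][key].get(g, 0))
            - cast(pre["multilayer"][key].get(g, 0))
            for g in genes
        }

    gained_lost = {}
    for lname in sorted(set(pre["layers"]) | set(post["layers"])):
        g_pre = set(pre["layers"].get(lname, {}).get("genes", []))
        g_post = set(post["layers"].get(lname, {}).get("genes", []))
        gained_lost[lname] = {
            "gained": sorted(g_post - g_pre),
            "lost": sorted(g_pre - g_post),
        }

    assort_delta = {}
    for metric in pre["assortativity"]:
        assort_delta[metric] = {}
        for method in pre["assortativity"][metric]:
            a = pre["assortativity"][metric][method]
            b = post["assortativity"][metric][method]
            vals = [
                [
                    None if (x is None or y is None) else y - x
                    for x, y in zip(ra, rb)
                ]
                for ra, rb in zip(a["values"], b["values"])
            ]
            assort_delta[metric][method] = {
                "layers": a["layers"], "values": vals,
            }

    counts_delta = {
        k: post["mutations"]["counts"].get(k, 0)
        - pre["mutations"]["counts"].get(k, 0)
        for k in set(pre["mutations"]["counts"])
        | set(post["mutations"]["counts"])
    }

    flags = {
        "post_more_genes": post["gene_count"] > pre["gene_count"],
        "post_more_drivers": (
            post["mutations"]["counts"].get("driver", 0)
            > pre["mutations"]["counts"].get("driver", 0)
        ),
    }
    conf = "conformation"
    if conf in pre["layers"] and conf in post["layers"]:
        flags["post_denser_conformation"] = (
            post["layers"][conf]["n_edges"] > pre["layers"][conf]["n_edges"]
        )
        flags["post_seed_conformation_degree_higher"] = (
            post["layers"][conf].get("seed_degree", 0)
            > pre["layers"][conf].get("seed_degree", 0)
        )

    return _jsonify({
        "schema_version": SCHEMA_VERSION,
        "pre": pre["condition"],
        "post": post["condition"],
        "delta_degree": delta_map("degree", int),
        "delta_strength": delta_map("strength", float),
        "gained_lost": gained_lost,
        "delta_assortativity": assort_delta,
        "delta_mutation_counts": counts_delta,
        "delta_gene_count": post["gene_count"] - pre["gene_count"],
        "signature_flags": flags,
    })


def export_layout(M: MultilayerNetwork, seed: int = 0) -> pd.DataFrame:
    """2-D gene positions shared across every layer.

    Computed on the aggregate layer with the two-stage scheme: a
    Fruchterman-Reingold embedding seeds a Kamada-Kawai refinement.
    Connected components are laid out separately and packed side by side
    so their bounding boxes never overlap; coordinates are centered, so a
    single gene sits at the origin.  Deterministic given ``seed``.
    """
    agg = aggregate_layer(M)
    g = agg.graph
    placed = {}
    x_offset = 0.0
    gap = 1.0
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            pos = {next(iter(comp)): np.zeros(2)}
        else:
            fr = nx.spring_layout(sub, seed=seed)
            pos = nx.kamada_kawai_layout(sub, pos=fr)
        xs = np.array([p[0] for p in pos.values()])
        ys = np.array([p[1] for p in pos.values()])
        shift_x = x_offset - xs.min()
        for node, (x, y) in pos.items():
            placed[node] = (x + shift_x, y - ys.min())
        x_offset += (xs.max() - xs.min()) + gap
    if placed:
        cx = np.mean([p[0] for p in placed.values()])
        cy = np.mean([p[1] for p in placed.values()])
        placed = {n: (x - cx, y - cy) for n, (x, y) in placed.items()}
    rows = [
        {"gene": gname, "x": float(x), "y": float(y)}
        for gname, (x, y) in sorted(placed.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "x", "y"])
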