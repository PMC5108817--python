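"""Synthetic multi-omic study generator.

Emulates the statistical structure of a seed-gene-centric two-condition
experiment so the whole pipeline runs without downloads:

* a chromatin-conformation layer grown around a seed gene by preferential
  attachment, which densifies around the seed after the stimulus (the
  post condition adds genes and extra seed-attached edges; the pre graph
  stays a subgraph of the post graph);
* functional-similarity and protein-interaction layers drawn from
  per-gene latent propensities that mix a shared factor with
  layer-private factors — the mixing fraction is the planted truth behind
  the measurable inter-layer degree assortativity;
* anti-correlated methylation and expression tracks (Gaussian copula on
  log-normal margins; the configured correlation is a rank-correlation
  target);
* a bimodal pathogenicity-score table: each SNP is a driver with a
  configured probability, scores drawn from a driver or passenger Beta
  law (defaults Beta(48, 2) / Beta(2, 8), means 0.96 / 0.20, matching the
  magnitudes a cancer-weighted pathogenicity scorer reports for driver
  and passenger mutations).

Defaults emulate an ESR1-centric estrogen-stimulation experiment in a
breast cancer cell line: 114 genes pre-stimulus growing to 353
post-stimulus, 15,611 / 63,689 candidate SNPs with a ~0.70 driver
fraction, and a 20,000-gene background universe standing in for all
human genes in enrichment tests.

Every draw derives from ``rng_seed`` through named child streams, so a
config generates byte-identical output on every run.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Layer
from .ingest import AttributeTrack
from .mutations import MutationTable, classify, pathway_flag

LAYER_SIMILARITY = "similarity"
LAYER_CONFORMATION = "conformation"
LAYER_INTERACTION = "interaction"
LAYERS = (LAYER_SIMILARITY, LAYER_CONFORMATION, LAYER_INTERACTION)

# track name -> layer carrying it
TRACK_LAYERS = {
    "methylation": LAYER_CONFORMATION,
    "expression": LAYER_INTERACTION,
    "mutation_samples": LAYER_SIMILARITY,
}


@dataclass
class SimConfig:
    """Study-level parameters of the synthetic generator.

    ``interlayer_mixing`` in [0, 1] is the fraction of a gene's edge
    propensity shared between the similarity and interaction layers (1 =
    identical propensities, 0 = independent);
    ``methylation_expression_corr`` is the target rank (Spearman)
    correlation between the two tracks.  Score shapes are (a, b) of Beta
    laws on [0, 1].
    """

    seed_gene: str = "ESR1"
    n_genes_pre: int = 114
    n_genes_post: int = 353
    edge_density_pre: float = 0.05
    edge_density_post: float = 0.08
    interlayer_mixing: float = 0.5
    methylation_expression_corr: float = -0.5
    n_snps_pre: int = 15611
    n_snps_post: int = 63689
    driver_fraction: float = 0.70
    passenger_score_shape: tuple = (2.0, 8.0)
    driver_score_shape: tuple = (48.0, 2.0)
    metabolic_fraction: float = 0.10
    disease_fraction_graph: float = 0.30
    disease_fraction_background: float = 0.05
    universe_size: int = 20000
    track_coverage: float = 0.9
    decoy_edge_fraction: float = 0.10
    seed_attach_prob: float = 0.6
    driver_threshold: float = 0.7
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_genes_pre < 5:
            raise ValueError("n_genes_pre must be >= 5")
        if self.n_genes_post < self.n_genes_pre:
            raise ValueError("n_genes_post must be >= n_genes_pre")
        for d in (self.edge_density_pre, self.edge_density_post):
            if not (0 < d <= 1):
                raise ValueError("edge densities must be in (0, 1]")
            # preferential attachment (early nodes can attach only to the
            # few genes already present) and probability-capped propensity
            # sampling both fall short of dense targets; reject upfront
            if d > 0.5:
                raise ValueError(
                    f"edge density {d} infeasible for the seed-centric "
                    "growth and propensity models (max 0.5)"
                )
        if not (0 <= self.interlayer_mixing <= 1):
            raise ValueError("interlayer_mixing must be in [0, 1]")
        if not (-1 <= self.methylation_expression_corr <= 1):
            raise ValueError("methylation_expression_corr must be in [-1, 1]")
        if not (0 <= self.driver_fraction <= 1):
            raise ValueError("driver_fraction must be in [0, 1]")
        for shape in (self.passenger_score_shape, self.driver_score_shape):
            if shape[0] <= 0 or shape[1] <= 0:
                raise ValueError("Beta shapes must be positive")
        if self.universe_size < self.n_genes_post:
            raise ValueError("universe_size must cover all graph genes")


@dataclass
class SyntheticCondition:
    name: str
    layers: dict          # layer name -> Layer
    tracks: dict          # track name -> AttributeTrack
    mutations: MutationTable
    edge_tables: dict     # layer name -> DataFrame(gene_a, gene_b, p_value)
    planted_driver: list = field(default_factory=list)  # truth per SNP


@dataclass
class SyntheticStudy:
    config: SimConfig
    pre: SyntheticCondition
    post: SyntheticCondition
    universe: list
    metabolic_genes: set
    disease_genes: set
    truth: dict


def _edges_per_node(density: float, n: int) -> int:
    """Edges each new node brings so the grown graph hits ``density``."""
    return max(1, round(density * (n - 1) / 2))


def _streams(rng_seed: int) -> dict:
    """Named, order-independent child RNG streams from one seed."""
    names = [
        "conformation_pre", "conformation_post",
        "propensity", "propensity_edges_pre", "propensity_edges_post",
        "tracks_pre", "tracks_post",
        "mutations_pre", "mutations_post",
        "gene_sets", "pvalues", "decoys",
    ]
    children = np.random.SeedSequence(rng_seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _gene_names(cfg: SimConfig) -> list:
    names = [cfg.seed_gene]
    names += [f"G{i:04d}" for i in range(1, cfg.n_genes_post)]
    return names


def _grow_preferential(rng, genes, m, graph_edges, degrees, seed_gene,
                       seed_attach_prob, start):
    """Grow a seed-centric graph by preferential attachment.

    Extends ``graph_edges``/``degrees`` in place, adding ``genes[start:]``
    one at a time with ``m`` attachments each, target probability
    proportional to degree + 1.  Each new node additionally attaches to
    the seed gene with probability ``seed_attach_prob``.
    """
    for i in range(start, len(genes)):
        g = genes[i]
        present = genes[:i]
        w = np.array([degrees[t] + 1.0 for t in present])
        k = min(m, len(present))
        targets = set(
            rng.choice(present, size=k, replace=False, p=w / w.sum())
        )
        if g != seed_gene and rng.random() < seed_attach_prob:
            targets.add(seed_gene)
        for t in targets:
            graph_edges.add((min(g, t), max(g, t)))
            degrees[g] = degrees.get(g, 0) + 1
            degrees[t] = degrees.get(t, 0) + 1


def _conformation_edges(cfg: SimConfig, streams) -> tuple:
    """Pre and post conformation edge sets (pre a subset of post)."""
    genes = _gene_names(cfg)
    edges: set = set()
    degrees: dict = {genes[0]: 0, genes[1]: 0}
    first = (min(genes[0], genes[1]), max(genes[0], genes[1]))
    edges.add(first)
    degrees[genes[0]] = degrees[genes[1]] = 1

    m_pre = _edges_per_node(cfg.edge_density_pre, cfg.n_genes_pre)
    _grow_preferential(
        streams["conformation_pre"], genes[: cfg.n_genes_pre], m_pre,
        edges, degrees, cfg.seed_gene, cfg.seed_attach_prob, start=2,
    )
    pre_edges = set(edges)

    m_post = _edges_per_node(cfg.edge_density_post, cfg.n_genes_post)
    rng_post = streams["conformation_post"]
    _grow_preferential(
        rng_post, genes, m_post,
        edges, degrees, cfg.seed_gene, cfg.seed_attach_prob,
        start=cfg.n_genes_pre,
    )
    # densification around the seed: guarantee the seed gains edges
    new_genes = genes[cfg.n_genes_pre:]
    seed_new = [
        g for g in new_genes
        if (min(g, cfg.seed_gene), max(g, cfg.seed_gene)) in edges
    ]
    if new_genes and not seed_new:
        g = new_genes[int(rng_post.integers(len(new_genes)))]
        edges.add((min(g, cfg.seed_gene), max(g, cfg.seed_gene)))
    return pre_edges, edges


def _propensities(cfg: SimConfig, streams) -> dict:
    """Latent per-gene edge propensities for the two propensity layers.

    u(gene, layer) = mixing * shared + (1 - mixing) * private, with
    shared and private factors log-normal(0, 1).
    """
    rng = streams["propensity"]
    n = cfg.n_genes_post
    shared = rng.lognormal(0.0, 1.0, size=n)
    out = {}
    for layer in (LAYER_SIMILARITY, LAYER_INTERACTION):
        private = rng.lognormal(0.0, 1.0, size=n)
        out[layer] = (
            cfg.interlayer_mixing * shared
            + (1.0 - cfg.interlayer_mixing) * private
        )
    return out


def _propensity_edges(u: np.ndarray, genes: list, density: float, rng,
                      existing: set) -> set:
    """Bernoulli edges with probability ~ u_i * u_j scaled to a density.

    Pairs already in ``existing`` are kept as-is (post conditions extend
    the pre edge set); only the remaining pairs are sampled.
    """
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    raw = np.outer(u, u)[iu, ju]
    # heavy-tailed propensities cap at probability 1, so the naive
    # moment-matched scale undershoots; bisect for the scale whose
    # capped mean hits the target density
    lo, hi = 0.0, density * len(raw) / raw.sum()
    for _ in range(200):
        if np.minimum(1.0, hi * raw).mean() >= density:
            break
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.minimum(1.0, mid * raw).mean() < density:
            lo = mid
        else:
            hi = mid
    p = np.minimum(1.0, hi * raw)
    draws = rng.random(len(p)) < p
    edges = set(existing)
    for a, b, hit in zip(iu, ju, draws):
        if hit:
            ga, gb = genes[a], genes[b]
            edges.add((min(ga, gb), max(ga, gb)))
    return edges


def _edge_table(edges: set, genes: list, cfg: SimConfig, streams) -> pd.DataFrame:
    """Edge TSV rows: significant real edges plus non-significant decoys.

    Real edges draw p ~ U(0, 0.05); decoys (a configurable fraction of
    extra random pairs) draw p ~ U(0.05, 1) and are removed again by the
    ingest skim, exercising the round trip.
    """
    rng_p = streams["pvalues"]
    rng_d = streams["decoys"]
    rows = [
        (a, b, rng_p.uniform(0.0, 0.05)) for a, b in sorted(edges)
    ]
    n_decoys = round(cfg.decoy_edge_fraction * len(edges))
    tried = 0
    while n_decoys > 0 and tried < 50 * n_decoys:
        i, j = rng_d.integers(len(genes), size=2)
        tried += 1
        if i == j:
            continue
        a, b = sorted((genes[i], genes[j]))
        if (a, b) in edges:
            continue
        rows.append((a, b, rng_d.uniform(0.05, 1.0)))
        n_decoys -= 1
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "p_value"])


def _omics_tracks(cfg: SimConfig, genes_by_layer: dict, which: str,
                  streams) -> dict:
    """Methylation/expression (anti-correlated copula) + mutation counts."""
    rng = streams[f"tracks_{which}"]
    # rank-correlation target -> Gaussian copula parameter
    rho = 2.0 * math.sin(math.pi * cfg.methylation_expression_corr / 6.0)
    union = sorted(
        set(genes_by_layer[LAYER_CONFORMATION])
        | set(genes_by_layer[LAYER_INTERACTION])
    )
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=len(union))
    meth = np.exp(0.5 * z[:, 0])
    expr = np.exp(0.5 * z[:, 1])
    meth_map = dict(zip(union, meth))
    expr_map = dict(zip(union, expr))

    sim_genes = sorted(genes_by_layer[LAYER_SIMILARITY])
    mut_counts = rng.negative_binomial(2, 0.1, size=len(sim_genes))
    mut_map = {g: float(c) for g, c in zip(sim_genes, mut_counts)}

    def subsample(values: dict, layer_genes) -> dict:
        keep = sorted(set(values) & set(layer_genes))
        n_keep = round(cfg.track_coverage * len(keep))
        idx = rng.permutation(len(keep))[:n_keep]
        return {keep[i]: values[keep[i]] for i in sorted(idx)}

    return {
        "methylation": AttributeTrack(
            "methylation", LAYER_CONFORMATION,
            subsample(meth_map, genes_by_layer[LAYER_CONFORMATION]),
        ),
        "expression": AttributeTrack(
            "expression", LAYER_INTERACTION,
            subsample(expr_map, genes_by_layer[LAYER_INTERACTION]),
        ),
        "mutation_samples": AttributeTrack(
            "mutation_samples", LAYER_SIMILARITY,
            subsample(mut_map, genes_by_layer[LAYER_SIMILARITY]),
        ),
    }


def _mutations(cfg: SimConfig, graph_genes: list, which: str,
               streams) -> MutationTable:
    rng = streams[f"mutations_{which}"]
    n = cfg.n_snps_pre if which == "pre" else cfg.n_snps_post
    genes = rng.choice(sorted(graph_genes), size=n)
    is_driver = rng.random(n) < cfg.driver_fraction
    pa, pb = cfg.passenger_score_shape
    da, db = cfg.driver_score_shape
    scores = np.where(
        is_driver,
        rng.beta(da, db, size=n),
        rng.beta(pa, pb, size=n),
    )
    triples = [
        (f"{which}_snp{i:06d}", g, float(s))
        for i, (g, s) in enumerate(zip(genes, scores))
    ]
    table = classify(triples, threshold=cfg.driver_threshold)
    return table, [bool(d) for d in is_driver]


def _gene_sets(cfg: SimConfig, graph_genes: list, streams) -> tuple:
    """Universe, metabolic and disease gene sets.

    The disease set is enriched among graph genes relative to the
    background, so the over-representation test has signal to find.
    """
    rng = streams["gene_sets"]
    background = [
        f"BG{i:05d}" for i in range(cfg.universe_size - len(graph_genes))
    ]
    universe = sorted(graph_genes) + background

    graph_sorted = sorted(graph_genes)
    n_met = round(cfg.metabolic_fraction * len(graph_sorted))
    met_idx = rng.permutation(len(graph_sorted))[:n_met]
    metabolic = {graph_sorted[i] for i in met_idx}

    n_dg = round(cfg.disease_fraction_graph * len(graph_sorted))
    dg_idx = rng.permutation(len(graph_sorted))[:n_dg]
    disease = {graph_sorted[i] for i in dg_idx}
    n_db = round(cfg.disease_fraction_background * len(background))
    db_idx = rng.permutation(len(background))[:n_db]
    disease |= {background[i] for i in db_idx}
    return universe, metabolic, disease


def _build_layers(cfg: SimConfig, streams) -> tuple:
    """All six layers (3 per condition); pre layers are subgraphs of post."""
    genes = _gene_names(cfg)
    pre_genes = genes[: cfg.n_genes_pre]

    conf_pre, conf_post = _conformation_edges(cfg, streams)
    u = _propensities(cfg, streams)
    prop_pre, prop_post = {}, {}
    rng_pre = streams["propensity_edges_pre"]
    rng_post = streams["propensity_edges_post"]
    for layer in (LAYER_SIMILARITY, LAYER_INTERACTION):
        pre_e = _propensity_edges(
            u[layer][: cfg.n_genes_pre], pre_genes,
            cfg.edge_density_pre, rng_pre, existing=set(),
        )
        post_e = _propensity_edges(
            u[layer], genes, cfg.edge_density_post, rng_post,
            existing=pre_e,
        )
        prop_pre[layer], prop_post[layer] = pre_e, post_e

    def to_layers(conf, props, node_list):
        out = {}
        for name, edge_set in (
            (LAYER_SIMILARITY, props[LAYER_SIMILARITY]),
            (LAYER_CONFORMATION, conf),
            (LAYER_INTERACTION, props[LAYER_INTERACTION]),
        ):
            layer = Layer(name)
            for g in node_list:
                layer.add_node(g)
            out[name] = (layer, edge_set)
        return out

    return (
        to_layers(conf_pre, prop_pre, pre_genes),
        to_layers(conf_post, prop_post, genes),
    )


def _finalize_condition(name, raw_layers, cfg, streams) -> SyntheticCondition:
    """Attach p-values/weights, build tracks and mutations."""
    layers, edge_tables = {}, {}
    for lname, (layer, edge_set) in raw_layers.items():
        node_list = sorted(layer.nodes)
        table = _edge_table(edge_set, node_list, cfg, streams)
        sig = table[table["p_value"] < 0.05]
        for a, b, p in sig.itertuples(index=False):
            layer.add_edge(a, b, 1.0 - p)
        layers[lname] = layer
        edge_tables[lname] = table
    genes_by_layer = {ln: sorted(ly.nodes) for ln, ly in layers.items()}
    tracks = _omics_tracks(cfg, genes_by_layer, name, streams)
    graph_genes = sorted(
        set().union(*(ly.nodes for ly in layers.values()))
    )
    mutations, planted = _mutations(cfg, graph_genes, name, streams)
    return SyntheticCondition(
        name=name, layers=layers, tracks=tracks,
        mutations=mutations, edge_tables=edge_tables,
        planted_driver=planted,
    )


def generate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate the full pre/post study with its planted truth."""
    cfg.validate()
    streams = _streams(cfg.rng_seed)
    raw_pre, raw_post = _build_layers(cfg, streams)
    pre = _finalize_condition("pre", raw_pre, cfg, streams)
    post = _finalize_condition("post", raw_post, cfg, streams)

    graph_genes = sorted(
        set().union(*(ly.nodes for ly in post.layers.values()))
    )
    universe, metabolic, disease = _gene_sets(cfg, graph_genes, streams)
    pre.mutations = pathway_flag(pre.mutations, metabolic)
    post.mutations = pathway_flag(post.mutations, metabolic)

    truth = {
        "config": dataclasses.asdict(cfg),
        "n_genes_pre": cfg.n_genes_pre,
        "n_genes_post": cfg.n_genes_post,
        "genes_gained": cfg.n_genes_post - cfg.n_genes_pre,
        "interlayer_mixing": cfg.interlayer_mixing,
        "methylation_expression_corr": cfg.methylation_expression_corr,
        "driver_fraction": cfg.driver_fraction,
        "passenger_score_mean": (
            cfg.passenger_score_shape[0]
            / (cfg.passenger_score_shape[0] + cfg.passenger_score_shape[1])
        ),
        "driver_score_mean": (
            cfg.driver_score_shape[0]
            / (cfg.driver_score_shape[0] + cfg.driver_score_shape[1])
        ),
        "seed_gene": cfg.seed_gene,
        "pre_seed_conformation_degree": int(
            pre.layers[LAYER_CONFORMATION].graph.degree(cfg.seed_gene)
        ),
        "post_seed_conformation_degree": int(
            post.layers[LAYER_CONFORMATION].graph.degree(cfg.seed_gene)
        ),
        "pre_driver_count": pre.mutations.counts()["driver"],
        "post_driver_count": post.mutations.counts()["driver"],
        "pre_planted_driver_count": int(sum(pre.planted_driver)),
        "post_planted_driver_count": int(sum(post.planted_driver)),
    }
    return SyntheticStudy(
        config=cfg, pre=pre, post=post, universe=universe,
        metabolic_genes=metabolic, disease_genes=disease, truth=truth,
    )


def generate_condition(cfg: SimConfig, which: str = "pre"):
    """One condition's ``(layers, tracks, mutations)``.

    The post condition is always grown from the pre condition, so the
    same config yields consistent pre/post pairs whichever is requested.
    """
    if which not in ("pre", "post"):
        raise ValueError("which must be 'pre' or 'post'")
    study = generate_study(cfg)
    cond = study.pre if which == "pre" else study.post
    return cond.layers, cond.tracks, cond.mutations


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write a study as the TSV dialects the ingest module reads.

    Produces per condition: three edge lists, three track tables, a
    mutation score table and a ready-to-run pipeline config (JSON); plus
    the shared gene sets, universe and ``truth.json``.  Returns the two
    config paths.
    """
    os.makedirs(outdir, exist_ok=True)
    cfg_paths = {}
    for cond in (study.pre, study.post):
        # config paths are relative to the config file, so a study
        # directory can be moved or committed as a fixture
        paths = {"layers": {}, "tracks": {}}
        for lname, table in sorted(cond.edge_tables.items()):
            fname = f"{cond.name}_{lname}.edges.tsv"
            _write_tsv(table, os.path.join(outdir, fname))
            paths["layers"][lname] = fname
        for tname, track in sorted(cond.tracks.items()):
            fname = f"{cond.name}_{tname}.tsv"
            df = pd.DataFrame(
                sorted(track.values.items()), columns=["gene", "value"]
            )
            _write_tsv(df, os.path.join(outdir, fname))
            paths["tracks"][tname] = {
                "path": fname, "layer": track.layer_name,
            }
        mut_fname = f"{cond.name}_mutations.tsv"
        _write_tsv(
            cond.mutations.to_dataframe()[["snp_id", "gene", "score"]],
            os.path.join(outdir, mut_fname),
        )

        config = {
            "condition": cond.name,
            "seed_gene": study.config.seed_gene,
            "layers": paths["layers"],
            "tracks": paths["tracks"],
            "mutations": mut_fname,
            "gene_sets": {
                "metabolic": "metabolic_genes.txt",
                "disease": "disease_genes.txt",
            },
            "universe": "universe.txt",
            "p_threshold": 0.05,
            "driver_threshold": study.config.driver_threshold,
            "coupling_weight": 1.0,
        }
        cfg_path = os.path.join(outdir, f"{cond.name}_config.json")
        with open(cfg_path, "w") as fh:
            json.dump(config, fh, indent=1, sort_keys=True)
            fh.write("\n")
        cfg_paths[cond.name] = cfg_path

    for fname, genes in (
        ("metabolic_genes.txt", study.metabolic_genes),
        ("disease_genes.txt", study.disease_genes),
    ):
        with open(os.path.join(outdir, fname), "w") as fh:
            for g in sorted(genes):
                fh.write(g + "\n")
    with open(os.path.join(outdir, "universe.txt"), "w") as fh:
        for g in study.universe:
            fh.write(g + "\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(study.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return cfg_paths
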