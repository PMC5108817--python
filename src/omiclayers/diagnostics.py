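"""Centrality descriptors and inter-layer correlation diagnostics.

Per layer: degree (count of incident edges), strength (sum of incident
edge weights) and HITS hub/authority scores.  The same descriptors are
computed on the aggregate layer and for the whole multilayer model, where
degree/strength are the per-layer sums and the hub/authority score of a
gene is the Euclidean norm of its node-layer replica scores in the
supra-structure HITS vector.  Inter-layer assortativity is the Pearson or
Spearman correlation between a descriptor in one layer and the same
genes' descriptor in another, aligned on the gene union with absent genes
scored 0.

On an undirected graph HITS hub and authority coincide and both equal the
principal (Perron) eigenvector of the weighted adjacency; the power
iteration here keeps scores entrywise non-negative and unit Euclidean
norm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Layer, MultilayerNetwork, SupraStructure, aggregate_layer, supra_structure

logger = logging.getLogger(__name__)

AGGREGATE_SCOPE = "aggregate"
MULTILAYER_SCOPE = "multilayer"


def degree(layer: Layer) -> dict:
    """Number of incident edges per gene (isolated genes score 0)."""
    return {g: int(d) for g, d in layer.graph.degree()}


def strength(layer: Layer) -> dict:
    """Sum of incident edge weights per gene."""
    return {g: float(s) for g, s in layer.graph.degree(weight="weight")}


def multilayer_descriptor(
    M: MultilayerNetwork,
    metric: str = "degree",
    include_couplings: bool = False,
) -> dict:
    """Per-gene sum of a descriptor across layers.

    A gene absent from a layer contributes 0 there.  Inter-layer
    couplings are excluded by default; with ``include_couplings`` each
    coupling adds 1 to the degree (or its weight to the strength) of both
    replicas of the gene.
    """
    fn = {"degree": degree, "strength": strength}[metric]
    out = {g: 0.0 for g in M.gene_universe}
    for ly in M.layers:
        for g, v in fn(ly).items():
            out[g] += v
    if include_couplings:
        for (g, _), _, w in M.interlayer_edges:
            out[g] += 2 if metric == "degree" else 2.0 * w
    if metric == "degree":
        return {g: int(v) for g, v in out.items()}
    return out


@dataclass
class HitsResult:
    """HITS scores plus the convergence flag of the power iteration."""

    hub: dict
    authority: dict
    converged: bool
    n_iter: int

    def __iter__(self):
        return iter((self.hub, self.authority))


def _hits_power(A: np.ndarray, tol: float, max_iter: int):
    """Alternating power iteration on a weighted adjacency matrix.

    Returns unit-norm non-negative hub and authority vectors; for
    symmetric A both equal the Perron eigenvector.  The iteration runs
    on A + sigma*I with a positive diagonal shift: the shift leaves the
    eigenvectors untouched but makes the dominant eigenvalue strictly
    largest in magnitude, so bipartite-like structures (where +/-lambda
    tie and the unshifted iteration stalls between the two) still
    converge to the Perron vector.
    """
    n = A.shape[0]
    sigma = float(np.abs(A).sum(axis=1).max())  # >= spectral radius
    A = A + sigma * np.eye(n)
    h = np.full(n, 1.0 / np.sqrt(n))
    a = np.full(n, 1.0 / np.sqrt(n))
    for it in range(1, max_iter + 1):
        a_new = A.T @ h
        na = np.linalg.norm(a_new)
        if na == 0:
            return np.zeros(n), np.zeros(n), True, it
        a_new /= na
        h_new = A @ a_new
        nh = np.linalg.norm(h_new)
        if nh == 0:
            return np.zeros(n), np.zeros(n), True, it
        h_new /= nh
        delta = max(
            np.max(np.abs(h_new - h)), np.max(np.abs(a_new - a))
        )
        h, a = h_new, a_new
        if delta < tol:
            return h, a, True, it
    return h, a, False, max_iter


def hits(structure, tol: float = 1e-9, max_iter: int = 1000) -> HitsResult:
    """HITS hub/authority by power iteration.

    ``structure`` is a :class:`Layer` (keys are genes) or a
    :class:`SupraStructure` (keys are (gene, layer) pairs).  An edgeless
    structure yields all-zero scores with a warning; hitting ``max_iter``
    without meeting ``tol`` returns a result flagged unconverged, with a
    warning.
    """
    if isinstance(structure, SupraStructure):
        keys = list(structure.ordering)
        A = structure.matrix
    else:
        keys = structure.sorted_nodes()
        A = structure.adjacency(keys)
    if not A.any():
        warnings.warn("HITS on an edgeless structure: all-zero scores",
                      stacklevel=2)
        zeros = {k: 0.0 for k in keys}
        return HitsResult(hub=dict(zeros), authority=dict(zeros),
                          converged=True, n_iter=0)
    h, a, converged, n_iter = _hits_power(A, tol, max_iter)
    if not converged:
        warnings.warn(
            f"HITS power iteration did not converge in {max_iter} "
            "iterations", stacklevel=2,
        )
    return HitsResult(
        hub={k: float(v) for k, v in zip(keys, h)},
        authority={k: float(v) for k, v in zip(keys, a)},
        converged=converged,
        n_iter=n_iter,
    )


def multilayer_hits(M: MultilayerNetwork, tol: float = 1e-9,
                    max_iter: int = 1000) -> HitsResult:
    """Whole-multilayer HITS on the supra-structure.

    The per-gene score is the Euclidean norm over that gene's node-layer
    replica scores, so the gene-level vector keeps unit norm.
    """
    res = hits(supra_structure(M), tol=tol, max_iter=max_iter)

    def collapse(scores):
        acc = {g: 0.0 for g in M.gene_universe}
        for (g, _), v in scores.items():
            acc[g] += v * v
        return {g: float(np.sqrt(s)) for g, s in acc.items()}

    return HitsResult(
        hub=collapse(res.hub),
        authority=collapse(res.authority),
        converged=res.converged,
        n_iter=res.n_iter,
    )


@dataclass
class AssortativityMatrix:
    """Symmetric L x L correlation matrix between layer descriptors.

    Undefined entries (a zero-variance descriptor vector in the pair)
    are NaN, never silently 0.
    """

    layer_names: list
    metric: str
    method: str
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.layer_names, columns=self.layer_names
        )

    def to_dict(self) -> dict:
        df = self.to_dataframe()
        return {
            "metric": self.metric,
            "method": self.method,
            "layers": list(self.layer_names),
            "values": [
                [None if np.isnan(v) else float(v) for v in row]
                for row in df.values
            ],
        }


def interlayer_assortativity(
    M: MultilayerNetwork,
    metric: str = "degree",
    method: str = "pearson",
    alignment: str = "union",
) -> AssortativityMatrix:
    """Correlation of a per-gene descriptor between every pair of layers.

    Vectors are aligned on the union of genes with absent genes scored 0
    (``alignment="intersection"`` restricts to shared genes instead).
    Spearman uses mid-ranks for ties.  Diagonal entries are exactly 1;
    a pair where either vector has zero variance is NaN.
    """
    if metric not in ("degree", "strength"):
        raise ValueError(f"unknown metric {metric!r}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if len(M.layers) < 2:
        raise ValueError("need at least two layers")
    if len(M.gene_universe) < 3:
        raise ValueError("need at least three genes in the union")

    fn = {"degree": degree, "strength": strength}[metric]
    per_layer = [fn(ly) for ly in M.layers]
    L = len(M.layers)
    out = np.ones((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            if alignment == "union":
                genes = sorted(M.layers[i].nodes | M.layers[j].nodes)
            else:
                genes = sorted(M.layers[i].nodes & M.layers[j].nodes)
            x = np.array([per_layer[i].get(g, 0.0) for g in genes])
            y = np.array([per_layer[j].get(g, 0.0) for g in genes])
            if len(genes) < 2 or x.std() == 0 or y.std() == 0:
                r = np.nan
            elif method == "pearson":
                r = stats.pearsonr(x, y).statistic
            else:
                r = stats.spearmanr(x, y).statistic
            out[i, j] = out[j, i] = r
    return AssortativityMatrix(
        layer_names=list(M.layer_names),
        metric=metric,
        method=method,
        values=out,
    )


def diagnostics_table(
    M: MultilayerNetwork,
    tol: float = 1e-9,
    max_iter: int = 5000,
    include_couplings: bool = False,
) -> pd.DataFrame:
    """Tabulate degree, strength, hub and authority per (gene, scope).

    Scopes are each layer name, "aggregate" and "multilayer"; every gene
    of the universe appears in every scope, with zeros where absent, so
    stacked per-layer bar tables come out rectangular.  The iteration
    budget is larger than the single-structure default because the
    supra-structure of a near-duplicated layer set has a small spectral
    gap.
    """
    universe = sorted(M.gene_universe)
    rows = []

    def block(scope, deg, stren, hub, auth):
        for g in universe:
            rows.append({
                "gene": g,
                "scope": scope,
                "degree": deg.get(g, 0),
                "strength": stren.get(g, 0.0),
                "hub": hub.get(g, 0.0),
                "authority": auth.get(g, 0.0),
            })

    for ly in M.layers:
        h = hits(ly, tol=tol, max_iter=max_iter) if ly.n_edges else None
        block(
            ly.name, degree(ly), strength(ly),
            h.hub if h else {}, h.authority if h else {},
        )
    agg = aggregate_layer(M)
    hagg = hits(agg, tol=tol, max_iter=max_iter) if agg.n_edges else None
    block(
        AGGREGATE_SCOPE, degree(agg), strength(agg),
        hagg.hub if hagg else {}, hagg.authority if hagg else {},
    )
    hml = multilayer_hits(M, tol=tol, max_iter=max_iter)
    block(
        MULTILAYER_SCOPE,
        multilayer_descriptor(M, "degree", include_couplings),
        multilayer_descriptor(M, "strength", include_couplings),
        hml.hub, hml.authority,
    )
    return pd.DataFrame(rows, columns=[
        "gene", "scope", "degree", "strength", "hub", "authority"
    ])


def top_k(
    table: pd.DataFrame, metric: str, scope: str, k: int = 20
) -> list:
    """Top-k genes by a descriptor within one scope.

    Sorted by the metric descending, ties broken lexicographically by
    gene name; returns min(k, number of genes) names.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if metric not in table.columns:
        raise KeyError(f"no metric column {metric!r}")
    sub = table[table["scope"] == scope]
    if sub.empty:
        raise KeyError(f"no scope {scope!r} in table")
    ranked = sub.sort_values(
        [metric, "gene"], ascending=[False, True], kind="stable"
    )
    return ranked["gene"].head(k).tolist()
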