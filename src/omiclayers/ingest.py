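"""Reading edge lists and omic attribute tables.

Edge lists arrive as TSV with two gene columns and a significance column.
The significance skim keeps only edges with p below a threshold (default
0.05) and stores weight = 1 - p, so that stored weights are the
probability of the relation existing, in [0, 1].  Per-gene scalar tracks
(methylation signal, expression, mutation sample counts) are bound to one
layer each; genes in the layer without a value get 0, and the binding
reports its coverage.

Rendering rules for a bound track: a gene is colored "above" iff its
value is at least the layer mean (zeros included; ties count as above),
and its drawn size grows with log(1 + value / layer max).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Layer, MultilayerNetwork

logger = logging.getLogger(__name__)


class EdgeListError(ValueError):
    """A malformed edge-list or attribute file."""


@dataclass
class AttributeTrack:
    """Per-gene scalar omic values bound to one layer.

    ``values`` maps gene symbol to a non-negative real;
    ``significance_threshold`` records the upstream p-value bound the
    values were filtered at (provenance only, not re-applied here).
    """

    name: str
    layer_name: str
    values: dict
    significance_threshold: float = 0.05

    def __post_init__(self):
        for g, v in self.values.items():
            if v < 0:
                raise ValueError(
                    f"track {self.name!r}: negative value {v} for gene {g!r}"
                )


@dataclass
class RenderSpec:
    """Per-gene rendering rules derived from a bound track."""

    color_class: dict  # gene -> "above" | "below" the layer mean
    size: dict  # gene -> drawn size, >= size_base
    mean: float
    max_value: float


def load_edge_list(
    path,
    name: str = "layer",
    p_column: str = "p_value",
    p_threshold: float = 0.05,
    gene_columns: tuple = ("gene_a", "gene_b"),
) -> Layer:
    """Read a TSV edge list and apply the significance skim.

    Rows with ``p < p_threshold`` are retained with stored weight
    ``1 - p``.  Duplicate unordered pairs are collapsed keeping the
    smallest p (most significant); self-loops are dropped and counted in
    the log.  If every edge is filtered out an empty layer is returned
    with a warning.

    Raises
    ------
    EdgeListError
        On a missing column or a non-numeric significance entry; the
        message carries the offending 1-based data line number.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    df = pd.read_csv(path, sep="\t", dtype=str)
    ga, gb = gene_columns
    for col in (ga, gb, p_column):
        if col not in df.columns:
            raise EdgeListError(f"{path}: missing column {col!r}")
    p = pd.to_numeric(df[p_column], errors="coerce")
    bad = df.index[p.isna() | df[ga].isna() | df[gb].isna()]
    if len(bad):
        # +2: 1-based and one header line
        raise EdgeListError(
            f"{path}: malformed row at line {int(bad[0]) + 2}"
        )
    if ((p < 0) | (p > 1)).any():
        line = int(df.index[(p < 0) | (p > 1)][0]) + 2
        raise EdgeListError(
            f"{path}: significance outside [0, 1] at line {line}"
        )

    n_loops = int((df[ga] == df[gb]).sum())
    if n_loops:
        logger.info("%s: dropped %d self-loop rows", path, n_loops)
    keep = (df[ga] != df[gb]) & (p < p_threshold)
    sub = pd.DataFrame({
        "u": df.loc[keep, ga],
        "v": df.loc[keep, gb],
        "p": p[keep],
    })
    # canonical unordered pair, then keep the most significant duplicate
    swap = sub["u"] > sub["v"]
    sub.loc[swap, ["u", "v"]] = sub.loc[swap, ["v", "u"]].values
    before = len(sub)
    sub = sub.sort_values("p", kind="stable").drop_duplicates(["u", "v"])
    collapsed = before - len(sub)
    if collapsed:
        logger.info("%s: collapsed %d duplicate edges (kept min p)",
                    path, collapsed)

    layer = Layer(name)
    for u, v, pv in sub[["u", "v", "p"]].itertuples(index=False):
        layer.add_edge(u, v, 1.0 - pv)
    if layer.n_edges == 0:
        warnings.warn(
            f"{path}: no edges pass p < {p_threshold}; empty layer",
            stacklevel=2,
        )
    return layer


def extract_gene_universe(layer: Layer) -> list:
    """Sorted unique list of all edge endpoints of a layer."""
    genes = set()
    for u, v in layer.edges:
        genes.add(u)
        genes.add(v)
    return sorted(genes)


def load_track(
    path, name: str, layer_name: str, significance_threshold: float = 0.05
) -> AttributeTrack:
    """Read a two-column ``gene<TAB>value`` attribute TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise EdgeListError(f"{path}: expected columns gene, value")
    gcol, vcol = df.columns[:2]
    values = dict(zip(df[gcol].astype(str), df[vcol].astype(float)))
    return AttributeTrack(
        name=name,
        layer_name=layer_name,
        values=values,
        significance_threshold=significance_threshold,
    )


def attach_track(M: MultilayerNetwork, track: AttributeTrack) -> MultilayerNetwork:
    """Bind a scalar track to its layer's node-layer replicas.

    Genes of the layer absent from the track get value 0; the coverage
    fraction |valued ∩ layer nodes| / |layer nodes| is logged.  Topology
    is never touched.  Returns ``M`` (mutated in place) for chaining.
    """
    layer = M.layer(track.layer_name)  # KeyError on unknown layer
    nodes = layer.nodes
    valued = set(track.values) & nodes
    coverage = len(valued) / len(nodes) if nodes else 0.0
    bound = AttributeTrack(
        name=track.name,
        layer_name=track.layer_name,
        values={g: float(track.values.get(g, 0.0)) for g in sorted(nodes)},
        significance_threshold=track.significance_threshold,
    )
    M.tracks[track.name] = bound
    logger.info(
        "track %r on layer %r: coverage %.3f (%d/%d genes)",
        track.name, track.layer_name, coverage, len(valued), len(nodes),
    )
    return M


def track_coverage(layer: Layer, track: AttributeTrack) -> float:
    """Fraction of the layer's genes carrying a value in the raw track."""
    nodes = layer.nodes
    if not nodes:
        return 0.0
    return len(set(track.values) & nodes) / len(nodes)


def render_spec(
    layer: Layer,
    track: AttributeTrack,
    size_base: float = 1.0,
    size_scale: float = 1.0,
) -> RenderSpec:
    """Mean-threshold coloring and log sizing for a bound track.

    The color threshold is the track mean over *all* genes present in
    the layer, unvalued genes counted as 0; a gene is "above" iff its
    value >= mean.  Size = size_base + size_scale * log(1 + value/max),
    with max taken over the layer (size exactly size_base for value 0,
    and for every gene when the track is all-zero).
    """
    if size_base <= 0 or size_scale <= 0:
        raise ValueError("size_base and size_scale must be positive")
    genes = sorted(layer.nodes)
    vals = np.array([track.values.get(g, 0.0) for g in genes], dtype=float)
    mean = float(vals.mean()) if len(vals) else 0.0
    vmax = float(vals.max()) if len(vals) else 0.0
    color = {
        g: ("above" if v >= mean else "below") for g, v in zip(genes, vals)
    }
    if vmax > 0:
        sizes = size_base + size_scale * np.log1p(vals / vmax)
    else:
        sizes = np.full_like(vals, size_base)
    return RenderSpec(
        color_class=color,
        size={g: float(s) for g, s in zip(genes, sizes)},
        mean=mean,
        max_value=vmax,
    )
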