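import dataclasses

import numpy as np
import pytest

from omiclayers.core import Layer, build_multilayer
from omiclayers.simulate import SimConfig


def random_layer(rng, name, genes, density=0.3):
    """Random undirected weighted layer over the given gene names."""
    layer = Layer(name)
    for g in genes:
        layer.add_node(g)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if rng.random() < density:
                layer.add_edge(genes[i], genes[j], rng.uniform(0.01, 1.0))
    return layer


def random_multilayer(rng, n_layers=3, n_genes=10, density=0.3,
                      presence=1.0, coupling_weight=1.0):
    """Random multilayer; each gene present in a layer w.p. ``presence``."""
    all_genes = [f"G{i:03d}" for i in range(n_genes)]
    layers = []
    for li in range(n_layers):
        genes = [g for g in all_genes if rng.random() < presence]
        if len(genes) < 2:
            genes = all_genes[:2]
        layers.append(random_layer(rng, f"L{li}", genes, density))
    return build_multilayer(layers, coupling_weight=coupling_weight)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_sim_config():
    """Scaled-down study config for fast pipeline tests."""
    return dataclasses.replace(
        SimConfig(),
        n_genes_pre=30,
        n_genes_post=45,
        edge_density_pre=0.10,
        edge_density_post=0.15,
        n_snps_pre=400,
        n_snps_post=900,
        universe_size=300,
        rng_seed=7,
    )
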