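"""Shared fixtures: small populations and reduced lobule geometries.

Everything here is deliberately small so the whole suite stays within a
desk-scale time budget; the acceptance tests build their own full-size
objects where the claim requires them.
"""

import networkx as nx
import numpy as np
import pytest

from apaptox import (
    LobuleGeometryParams, LobuleNetwork, PDParameters, PopulationSpec,
    generate_lobule, sample_population,
)


@pytest.fixture(scope="session")
def params():
    return PDParameters()


@pytest.fixture(scope="session")
def pop80(params):
    """80-cell default population, seed 1 (module-shared, read-only params)."""
    return sample_population(PopulationSpec(n_cells=80, seed=1), params)


@pytest.fixture(scope="session")
def tiny_geometry():
    return LobuleGeometryParams(n_rings=3, n_spokes=12, n_hepatocytes=400,
                                n_layers=2, seed=0)


@pytest.fixture(scope="session")
def tiny_lobule(tiny_geometry):
    return generate_lobule(tiny_geometry)


def make_chain_network(radii, lengths, n_layers=1):
    """Hand-built lobule network: inlet - junctions - outlet in series.

    Node 0 is the central outlet, the last node the portal inlet, with one
    placeholder hepatocyte (tests that need pure advection give it zero
    permeability).
    """
    n_edges = len(radii)
    g = nx.Graph()
    g.add_node(0, kind="central-outlet")
    pos = {0: (0.0, 0.0)}
    x = 0.0
    for i in range(1, n_edges + 1):
        kind = "portal-inlet" if i == n_edges else "junction"
        g.add_node(i, kind=kind)
        x += lengths[i - 1]
        pos[i] = (x, 0.0)
    edges = []
    for i in range(n_edges):
        g.add_edge(i + 1, i, radius=float(radii[i]), length=float(lengths[i]))
        edges.append((i + 1, i))
    geo = LobuleGeometryParams(n_layers=n_layers, n_hepatocytes=1,
                               n_rings=1, n_spokes=1, n_portal_inlets=1)
    return LobuleNetwork(
        graph=g, params=geo, edges=edges, node_pos=pos,
        cell_edge=np.array([0]), cell_arc=np.array([lengths[0] / 2.0]),
        cell_layer=np.array([0]), cell_z=np.array([0.5]))
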