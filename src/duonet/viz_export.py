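"""Sociogram export: MDS layout coordinates and graph-file writers.

Layout uses classical (Torgerson) multidimensional scaling on the geodesic
(shortest-path) distance matrix, so nodes sharing similar connections land
close together.  Geodesic distance is undefined across components; a
finite pseudo-distance of (largest component diameter + 1) is used, and
isolates are placed on a surrounding ring.  Exports carry role class,
provenance (for duocentric networks), coordinates and a fixed role → color
map on every node, and the ordinal weight on every edge.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np

from .duo_merge import DuoNetwork
from .ego_measures import EgoNetwork

__all__ = ["layout_mds", "export_graph", "import_json_graph", "ROLE_COLORS"]

#: Fixed sociogram color map, configurable via export_graph(colors=...).
ROLE_COLORS = {
    "family": "#1b9e77",
    "community": "#7570b3",
    "professional": "#d95f02",
}


def _as_graph(net: Union[EgoNetwork, DuoNetwork, nx.Graph]) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net
    return net.to_networkx()


def _classical_mds(dist: np.ndarray, ndim: int = 2) -> np.ndarray:
    """Torgerson MDS: double-center the squared distances, eigendecompose."""
    n = dist.shape[0]
    d2 = dist.astype(float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:ndim]
    vals = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals)
    if coords.shape[1] < ndim:
        coords = np.pad(coords, ((0, 0), (0, ndim - coords.shape[1])))
    # deterministic sign convention: largest-|x| entry of each axis positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def layout_mds(
    net: Union[EgoNetwork, DuoNetwork, nx.Graph], seed: int = 0
) -> dict[object, tuple[float, float]]:
    """2-D coordinates per node via classical MDS on geodesic distance.

    A single node sits at the origin.  Nodes in non-trivial components are
    laid out jointly with cross-component pseudo-distance diameter+1;
    isolates are arranged on a ring around the layout.  ``seed`` only
    breaks exact coordinate collisions (degenerate eigen-cases).
    """
    g = _as_graph(net)
    nodes = sorted(g.nodes())
    n = len(nodes)
    if n == 0:
        raise ValueError("layout requires at least one node")
    if n == 1:
        return {nodes[0]: (0.0, 0.0)}

    isolates = [v for v in nodes if g.degree(v) == 0]
    core = [v for v in nodes if g.degree(v) > 0]
    pos: dict[object, tuple[float, float]] = {}

    if core:
        idx = {v: i for i, v in enumerate(core)}
        spl = dict(nx.all_pairs_shortest_path_length(g.subgraph(core)))
        finite = [d for lengths in spl.values() for d in lengths.values()]
        pseudo = (max(finite) if finite else 1) + 1
        dist = np.full((len(core), len(core)), float(pseudo))
        np.fill_diagonal(dist, 0.0)
        for u, lengths in spl.items():
            for v, d in lengths.items():
                dist[idx[u], idx[v]] = d
        coords = _classical_mds(dist)
        # jitter exact duplicates deterministically so nodes never coincide
        rng = np.random.default_rng(seed)
        seen: dict[tuple[float, float], int] = {}
        for i in range(len(core)):
            key = (round(coords[i, 0], 9), round(coords[i, 1], 9))
            if key in seen:
                coords[i] += rng.normal(scale=1e-3, size=2)
            else:
                seen[key] = i
        for v in core:
            pos[v] = (float(coords[idx[v], 0]), float(coords[idx[v], 1]))

    if isolates:
        radius = 1.0
        if pos:
            arr = np.array(list(pos.values()))
            radius = 1.2 * max(1.0, float(np.abs(arr).max()))
        for k, v in enumerate(isolates):
            theta = 2 * np.pi * k / len(isolates)
            pos[v] = (
                float(radius * np.cos(theta)),
                float(radius * np.sin(theta)),
            )
    return pos


def _decorate(g: nx.Graph, layout: dict, colors: dict) -> nx.Graph:
    missing = set(g.nodes()) - set(layout)
    if missing:
        raise ValueError(f"layout does not cover nodes {sorted(map(str, missing))}")
    out = g.copy()
    for v, data in out.nodes(data=True):
        x, y = layout[v]
        data["x"], data["y"] = float(x), float(y)
        data["color"] = colors.get(data.get("role_class", ""), "#999999")
        if "supports" in data and not isinstance(data["supports"], str):
            data["supports"] = ",".join(sorted(data["supports"]))
    for _, _, data in out.edges(data=True):
        data.setdefault("weight", 1)
    return out


def export_graph(
    net: Union[EgoNetwork, DuoNetwork, nx.Graph],
    layout: dict,
    path: Union[str, Path],
    fmt: str = "graphml",
    colors: dict = ROLE_COLORS,
) -> Path:
    """Write the network with layout and role attributes to graphml/dot/json."""
    path = Path(path)
    g = _decorate(_as_graph(net), layout, colors)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "json":
        payload = nx.node_link_data(g, edges="edges")
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    elif fmt == "dot":
        path.write_text(_to_dot(g))
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def import_json_graph(path: Union[str, Path]) -> nx.Graph:
    """Read back a JSON export; inverse of export_graph(..., fmt='json')."""
    payload = json.loads(Path(path).read_text())
    return nx.node_link_graph(payload, edges="edges")


def _dot_quote(s: object) -> str:
    return '"' + str(s).replace('"', '\\"') + '"'


def _to_dot(g: nx.Graph) -> str:
    lines = ["graph sociogram {", "  node [style=filled];"]
    for v, data in sorted(g.nodes(data=True), key=lambda t: str(t[0])):
        attrs = {
            "label": data.get("label", v),
            "fillcolor": data.get("color", "#999999"),
            "pos": f"{data.get('x', 0):.4f},{data.get('y', 0):.4f}!",
        }
        if "role_class" in data:
            attrs["role_class"] = data["role_class"]
        if "provenance" in data:
            attrs["provenance"] = data["provenance"]
        attr_s = ", ".join(f"{k}={_dot_quote(val)}" for k, val in attrs.items())
        lines.append(f"  {_dot_quote(v)} [{attr_s}];")
    for u, v, data in sorted(g.edges(data=True), key=lambda t: (str(t[0]), str(t[1]))):
        lines.append(
            f"  {_dot_quote(u)} -- {_dot_quote(v)} "
            f"[weight={data.get('weight', 1)}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
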