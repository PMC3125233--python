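"""Water distribution network representation and file interchange.

A network is a set of nodes (junctions that consume water, and sources —
reservoirs/wells that supply it) joined by pipes.  Pipes carry the geometric
and material attributes that drive contaminant leaching: length, diameter,
and whether the main is asbestos-cement with a sprayed vinyl liner (ACVL),
in which case the liner installation year determines how much solvent
remains to leach in any later calendar year.

Networks are interchanged as a subset of the EPANET INP text format
(``[JUNCTIONS]``, ``[RESERVOIRS]``, ``[PIPES]``, ``[DEMANDS]``,
``[COORDINATES]``) plus a sidecar CSV of per-pipe liner attributes, keeping
the INP file standard.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AttributeTableError, ParseError, StructuralError

logger = logging.getLogger(__name__)

JUNCTION = "junction"
SOURCE = "source"

#: INP sections honored by the reader; anything else is skipped with a warning.
_KNOWN_SECTIONS = {"TITLE", "JUNCTIONS", "RESERVOIRS", "PIPES", "DEMANDS",
                   "COORDINATES", "END"}


@dataclass(frozen=True)
class Node:
    """A point of the network: a consumption junction or a water source.

    ``demand`` is an annual volume in arbitrary but consistent units
    (sources have demand 0; supply is implied by mass balance).
    """

    id: str
    x: float = 0.0
    y: float = 0.0
    kind: str = JUNCTION
    demand: float = 0.0

    def __post_init__(self):
        if self.kind not in (JUNCTION, SOURCE):
            raise StructuralError(f"node {self.id!r}: unknown kind {self.kind!r}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise StructuralError(f"node {self.id!r}: non-finite coordinates")
        if self.demand < 0:
            raise StructuralError(f"node {self.id!r}: negative demand")
        if self.kind == SOURCE and self.demand != 0:
            raise StructuralError(f"source {self.id!r} must have zero demand")


@dataclass(frozen=True)
class Pipe:
    """A pipe segment between two nodes.

    ``roughness`` is the Hazen-Williams coefficient.  ``is_acvl`` marks a
    vinyl-lined asbestos-cement main; ``install_year`` (calendar year the
    liner was applied) is required for ACVL pipes and ignored otherwise.
    """

    id: str
    from_node: str
    to_node: str
    length: float
    diameter: float
    roughness: float = 100.0
    is_acvl: bool = False
    install_year: int | None = None

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise StructuralError(
                f"pipe {self.id!r}: length and diameter must be positive")
        if self.from_node == self.to_node:
            raise StructuralError(f"pipe {self.id!r}: from == to")
        if self.is_acvl and self.install_year is None:
            raise AttributeTableError(
                f"ACVL pipe {self.id!r} missing install_year")

    @property
    def surface_area(self) -> float:
        """Interior surface area pi*d*l (m^2) — the leaching surface."""
        return float(np.pi * self.diameter * self.length)


class Network:
    """An immutable, validated water distribution network."""

    def __init__(self, nodes, pipes):
        node_list = list(nodes)
        pipe_list = list(pipes)
        ids = [n.id for n in node_list]
        if len(set(ids)) != len(ids):
            raise ParseError("duplicate node ids")
        pids = [p.id for p in pipe_list]
        if len(set(pids)) != len(pids):
            raise ParseError("duplicate pipe ids")
        self.nodes: dict[str, Node] = {n.id: n for n in node_list}
        self.pipes: dict[str, Pipe] = {p.id: p for p in pipe_list}
        for p in pipe_list:
            for end in (p.from_node, p.to_node):
                if end not in self.nodes:
                    raise StructuralError(
                        f"pipe {p.id!r} references unknown node {end!r}")
        if not self.sources:
            raise StructuralError("network has no source")
        g = self.graph()
        if len(self.nodes) > 1 and not nx.is_connected(g):
            raise StructuralError("network is not connected")

    @property
    def junctions(self) -> list[Node]:
        return [n for n in self.nodes.values() if n.kind == JUNCTION]

    @property
    def sources(self) -> list[Node]:
        return [n for n in self.nodes.values() if n.kind == SOURCE]

    @property
    def total_demand(self) -> float:
        return float(sum(n.demand for n in self.junctions))

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for p in self.pipes.values():
            g.add_edge(p.from_node, p.to_node, key=p.id)
        return g

    def with_demands(self, demands: dict[str, float]) -> "Network":
        """Return a copy with junction demands replaced."""
        nodes = [replace(n, demand=float(demands.get(n.id, n.demand)))
                 if n.kind == JUNCTION else n for n in self.nodes.values()]
        return Network(nodes, self.pipes.values())

    def __repr__(self):
        return (f"Network({len(self.nodes)} nodes, {len(self.pipes)} pipes, "
                f"{len(self.sources)} sources)")


# ---------------------------------------------------------------------------
# INP + attribute-table interchange


def _tokenize_inp(text: str):
    """Yield (section, tokens) for each data line of an INP file."""
    section = None
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]").upper()
            if section not in _KNOWN_SECTIONS:
                logger.warning("ignoring INP section [%s]", section)
            continue
        if section in _KNOWN_SECTIONS:
            yield section, line.split()


def read_network(inp_text: str, pipe_attrs: pd.DataFrame | None = None) -> Network:
    """Parse a subset INP file plus a pipe-attribute table into a Network.

    ``pipe_attrs`` has columns ``pipe_id, is_acvl, install_year``.  Every
    attribute row must match a pipe; ACVL rows must carry an install year.
    """
    junctions: dict[str, dict] = {}
    reservoirs: dict[str, dict] = {}
    pipe_rows: dict[str, dict] = {}
    coords: dict[str, tuple[float, float]] = {}
    for section, tok in _tokenize_inp(inp_text):
        if section == "JUNCTIONS":
            nid = tok[0]
            if nid in junctions or nid in reservoirs:
                raise ParseError(f"duplicate node id {nid!r}")
            demand = float(tok[2]) if len(tok) > 2 else 0.0
            junctions[nid] = {"demand": demand}
        elif section == "RESERVOIRS":
            nid = tok[0]
            if nid in junctions or nid in reservoirs:
                raise ParseError(f"duplicate node id {nid!r}")
            reservoirs[nid] = {}
        elif section == "PIPES":
            pid = tok[0]
            if pid in pipe_rows:
                raise ParseError(f"duplicate pipe id {pid!r}")
            pipe_rows[pid] = {
                "from_node": tok[1], "to_node": tok[2],
                "length": float(tok[3]), "diameter": float(tok[4]),
                "roughness": float(tok[5]) if len(tok) > 5 else 100.0,
            }
        elif section == "DEMANDS":
            if tok[0] not in junctions:
                raise StructuralError(f"demand for unknown junction {tok[0]!r}")
            junctions[tok[0]]["demand"] = float(tok[1])
        elif section == "COORDINATES":
            coords[tok[0]] = (float(tok[1]), float(tok[2]))

    attrs: dict[str, dict] = {}
    if pipe_attrs is not None:
        for _, row in pipe_attrs.iterrows():
            pid = str(row["pipe_id"])
            if pid not in pipe_rows:
                raise AttributeTableError(
                    f"attribute row for nonexistent pipe id {pid!r}")
            is_acvl = bool(row["is_acvl"])
            iy = row.get("install_year")
            if is_acvl and (iy is None or (isinstance(iy, float) and np.isnan(iy))):
                raise AttributeTableError(
                    f"ACVL pipe {pid!r} missing install_year")
            attrs[pid] = {"is_acvl": is_acvl,
                          "install_year": int(iy) if is_acvl else None}

    nodes = []
    for nid, d in junctions.items():
        x, y = coords.get(nid, (0.0, 0.0))
        nodes.append(Node(nid, x, y, JUNCTION, d["demand"]))
    for nid in reservoirs:
        x, y = coords.get(nid, (0.0, 0.0))
        nodes.append(Node(nid, x, y, SOURCE, 0.0))
    pipes = [Pipe(pid, **row, **attrs.get(pid, {})) for pid, row in pipe_rows.items()]
    return Network(nodes, pipes)


def write_network(network: Network) -> tuple[str, pd.DataFrame]:
    """Serialize to (INP text, pipe-attribute DataFrame); inverse of read."""
    buf = io.StringIO()
    buf.write("[TITLE]\npcenet network\n\n[JUNCTIONS]\n;ID Elev Demand\n")
    for n in sorted(network.junctions, key=lambda n: n.id):
        buf.write(f"{n.id} 0 {n.demand!r}\n")
    buf.write("\n[RESERVOIRS]\n;ID Head\n")
    for n in sorted(network.sources, key=lambda n: n.id):
        buf.write(f"{n.id} 0\n")
    buf.write("\n[PIPES]\n;ID Node1 Node2 Length Diameter Roughness\n")
    for p in sorted(network.pipes.values(), key=lambda p: p.id):
        buf.write(f"{p.id} {p.from_node} {p.to_node} {p.length!r} "
                  f"{p.diameter!r} {p.roughness!r}\n")
    buf.write("\n[COORDINATES]\n;Node X Y\n")
    for n in sorted(network.nodes.values(), key=lambda n: n.id):
        buf.write(f"{n.id} {n.x!r} {n.y!r}\n")
    buf.write("\n[END]\n")
    attrs = pd.DataFrame(
        [{"pipe_id": p.id, "is_acvl": p.is_acvl, "install_year": p.install_year}
         for p in sorted(network.pipes.values(), key=lambda p: p.id)])
    return buf.getvalue(), attrs


def nearest_node_assignment(parcels, network: Network) -> dict[str, str]:
    """Assign each parcel (id, x, y) to its nearest junction.

    Each land parcel stands for a water user served at the closest
    consumption node of the network (never a source).  Ties in Euclidean
    distance break to the lexicographically smaller node id, so the
    assignment is deterministic.
    """
    junctions = sorted(network.junctions, key=lambda n: n.id)
    if not junctions:
        raise StructuralError("network has no junctions")
    if hasattr(parcels, "itertuples"):  # DataFrame with parcel_id,x,y
        parcels = [(r.parcel_id, r.x, r.y) for r in parcels.itertuples()]
    parcels = list(parcels)
    if not parcels:
        return {}
    jx = np.array([n.x for n in junctions])
    jy = np.array([n.y for n in junctions])
    out = {}
    for pid, x, y in parcels:
        d2 = (jx - x) ** 2 + (jy - y) ** 2
        # argmin returns the first minimum; junctions are sorted by id,
        # which implements the lexicographic tie rule.
        out[str(pid)] = junctions[int(np.argmin(d2))].id
    return out
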