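"""PCE leaching from vinyl pipe liners and transport to network nodes.

Leaching model
--------------
The vinyl liner of an ACVL main was applied with PCE as carrier solvent;
the residual solvent diffuses into the water column.  First-order (Fickian)
kinetics give an exponential depletion of the areal load: the fraction of
the initial load still in the liner ``t`` years after installation is
``exp(-t/R)`` with leaching time constant ``R`` (default 2.25 years).  The
mass released by a pipe during the calendar year that begins ``a`` whole
years after installation is therefore

    J_p = S_p * m0 * (exp(-a/R) - exp(-(a+1)/R)),   S_p = pi * d * l,

where ``m0`` is the initial areal load (relative units by default) and
``S_p`` the interior surface area.  Summed over all years the release
telescopes to ``S_p * m0``: every unit of initial load eventually leaches.

Transport model
---------------
Leached mass mixes into the steady flow.  Orienting every pipe by its flow
direction yields a directed acyclic graph; walking it in topological order,
a junction's concentration is the flow-weighted mean of the concentrations
arriving through its inflowing pipes, and a pipe adds ``J_p/|Q_p|`` to the
concentration between its inlet and outlet.  Sources carry clean water.
Pipes whose flow is below a stagnation threshold transport nothing and
their leached mass is dropped from the balance (steady state cannot
represent accumulation in standing water); this is logged.

The annual dose at a node is its concentration times one unit of standard
annual consumption, so in relative units dose and concentration coincide.
Only the ordering of doses across subjects is interpreted — they are
relative delivered doses (RDDs), not absolute intakes — but an absolute
calibration (initial load in ug/m^2 and per-user demand in m^3/year) turns
the relative field into point concentrations in ug/L for comparison with
water samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import MappingError, ParameterError, TransportError
from .flow import FlowSolution
from .network import Network, Pipe

logger = logging.getLogger(__name__)

#: Leaching-rate sensitivity grid (years), from very fast to very slow.
R_SENSITIVITY_GRID = (0.025, 0.75, 2.25, 5.0, 10.0)


@dataclass(frozen=True)
class LeachParams:
    """Leaching time constant R (years) and initial areal load m0."""

    R: float = 2.25
    m0: float = 1.0

    def __post_init__(self):
        if self.R <= 0:
            raise ParameterError("leaching time constant R must be positive")
        if self.m0 <= 0:
            raise ParameterError("initial areal load m0 must be positive")


@dataclass
class ConcentrationField:
    """Per-node relative concentration and annual dose for one calendar year."""

    year: int
    concentration: pd.Series  # node id -> relative mass/volume
    dose: pd.Series           # node id -> relative mass/year at unit consumption
    stagnant_pipes: list[str] = field(default_factory=list)


def annual_leach_mass(pipe: Pipe, year: int, params: LeachParams) -> float:
    """Relative PCE mass leached by ``pipe`` during calendar ``year``.

    Zero for non-ACVL pipes and for years before liner installation.
    """
    if not pipe.is_acvl or pipe.install_year is None:
        return 0.0
    a = year - pipe.install_year
    if a < 0:
        return 0.0
    return (pipe.surface_area * params.m0
            * (math.exp(-a / params.R) - math.exp(-(a + 1) / params.R)))


def steady_concentrations(network: Network, flow: FlowSolution, year: int,
                          params: LeachParams,
                          stagnant_tol: float = 1e-9) -> ConcentrationField:
    """Propagate the year's leached mass through the flow solution.

    ``stagnant_tol`` is relative to total demand; pipes below it are treated
    as stagnant (no transport).
    """
    eps = stagnant_tol * network.total_demand
    dag = nx.MultiDiGraph()
    dag.add_nodes_from(network.nodes)
    stagnant = []
    for p in network.pipes.values():
        q = flow.flows[p.id]
        if abs(q) <= eps:
            stagnant.append(p.id)
            continue
        head, tail = (p.from_node, p.to_node) if q > 0 else (p.to_node, p.from_node)
        dag.add_edge(head, tail, key=p.id, pipe=p, q=abs(q))
    if stagnant:
        logger.warning("%d stagnant pipe(s) dropped from transport: %s",
                       len(stagnant), ", ".join(sorted(stagnant)))
    if not nx.is_directed_acyclic_graph(dag):
        raise TransportError(
            "flow solution contains a directed cycle of nonzero flows; "
            "cannot order transport")

    conc = {nid: 0.0 for nid in network.nodes}
    for nid in nx.topological_sort(dag):
        q_in = 0.0
        mass_in = 0.0
        for up, _, key, data in dag.in_edges(nid, keys=True, data=True):
            pipe, q = data["pipe"], data["q"]
            c_out = conc[up] + annual_leach_mass(pipe, year, params) / q
            q_in += q
            mass_in += q * c_out
        if q_in > 0:
            conc[nid] = mass_in / q_in
    series = pd.Series(conc, dtype=float).sort_index()
    # unit-consumption convention: dose per user-year is numerically C_n
    return ConcentrationField(year=year, concentration=series,
                              dose=series.copy(), stagnant_pipes=stagnant)


def annual_dose(fld: ConcentrationField, node: str) -> float:
    """Relative dose/year delivered at ``node`` under unit consumption."""
    node_id = getattr(node, "id", node)
    if node_id not in fld.dose.index:
        raise MappingError(f"node {node_id!r} not in concentration field")
    return float(fld.dose[node_id])


def point_concentration(fld: ConcentrationField, node: str, m0_abs: float,
                        demand_abs: float) -> float:
    """Absolute concentration (ug/L) at a node.

    ``m0_abs`` is the initial liner load in ug/m^2; ``demand_abs`` the real
    annual water volume (m^3/year) corresponding to one relative demand
    unit.  The relative field must have been computed with m0 = 1.
    """
    if m0_abs <= 0 or demand_abs <= 0:
        raise ParameterError("calibration constants must be positive")
    node_id = getattr(node, "id", node)
    if node_id not in fld.concentration.index:
        raise MappingError(f"node {node_id!r} not in concentration field")
    # ug per m^3, divided by 1000 L/m^3
    return float(fld.concentration[node_id]) * m0_abs / demand_abs / 1000.0


class DoseHistory:
    """Annual relative dose per node across a span of calendar years.

    Wraps a nodes x years matrix with cumulative sums so that windowed
    residence queries are O(1).
    """

    def __init__(self, matrix: pd.DataFrame):
        self.matrix = matrix  # index: node id, columns: int years (sorted)
        self.years = np.asarray(matrix.columns, dtype=int)
        self._cum = matrix.to_numpy().cumsum(axis=1)
        self._row = {nid: i for i, nid in enumerate(matrix.index)}

    @property
    def nodes(self):
        return list(self.matrix.index)

    def dose(self, node: str, year: int) -> float:
        if node not in self._row:
            raise MappingError(f"node {node!r} not in dose history")
        if year < self.years[0] or year > self.years[-1]:
            return 0.0
        return float(self.matrix.iloc[self._row[node], year - self.years[0]])

    def window_sum(self, node: str, y0: int, y1: int) -> float:
        """Sum of annual doses at ``node`` over calendar years [y0, y1]."""
        if node not in self._row:
            raise MappingError(f"node {node!r} not in dose history")
        lo, hi = self.years[0], self.years[-1]
        y0, y1 = max(y0, lo), min(y1, hi)
        if y1 < y0:
            return 0.0
        i = self._row[node]
        s = self._cum[i, y1 - lo]
        if y0 > lo:
            s -= self._cum[i, y0 - 1 - lo]
        return float(s)

    def to_frame(self) -> pd.DataFrame:
        """Long CSV-ready frame: year, node_id, concentration, dose."""
        long = self.matrix.stack()
        long.index.names = ["node_id", "year"]
        out = long.rename("dose").reset_index()
        out["concentration"] = out["dose"]
        return out[["year", "node_id", "concentration", "dose"]]


def compute_dose_history(network: Network, flow: FlowSolution, years,
                         params: LeachParams,
                         stagnant_tol: float = 1e-9) -> DoseHistory:
    """Run the transport model for each calendar year in ``years``."""
    years = sorted(int(y) for y in years)
    cols = {}
    for y in years:
        cols[y] = steady_concentrations(network, flow, y, params,
                                        stagnant_tol).dose
    return DoseHistory(pd.DataFrame(cols))
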