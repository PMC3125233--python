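"""Steady-state demand-driven flow in a water distribution network.

The model is a single time-invariant snapshot: every consumer draws water
simultaneously at their annual demand rate, sources are fixed-head
reservoirs at a common reference head, elevations are flat, and headloss in
each pipe follows the Hazen-Williams law

    h = r * sign(Q) * |Q|**n,   n = 1.852,
    r = 10.67 * L / (C**1.852 * d**4.871),

with L pipe length (m), d diameter (m) and C the roughness coefficient.
Only the relative resistances matter for how flow divides among loops, so
the arbitrary annual volume unit of the demands carries through to the
flows unchanged.

The solver is a damped Newton iteration on junction heads (the nodal or
"global gradient" formulation): at a solution the net pipe inflow at every
junction equals its demand.  On branched (tree) networks mass balance
determines the flows uniquely and Newton converges to them at machine
precision; on looped networks the Hazen-Williams head consistency closes
the system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, SolverError
from .network import Network

HW_EXPONENT = 1.852


def hw_resistance(pipe) -> float:
    """Hazen-Williams resistance coefficient of a pipe (SI-form constant)."""
    return 10.67 * pipe.length / (pipe.roughness ** HW_EXPONENT
                                  * pipe.diameter ** 4.871)


@dataclass
class FlowSolution:
    """Signed steady flow per pipe and head per node.

    ``flows[pipe_id]`` is the volumetric flow in the pipe's from->to
    orientation (negative means physical flow runs to->from), in the same
    annual volume units as the demands.
    """

    flows: dict[str, float]
    heads: dict[str, float]
    iterations: int
    max_residual: float  # worst junction mass-balance defect, demand units


@dataclass
class ConservationReport:
    """Per-junction mass-balance residuals of a flow solution."""

    residuals: dict[str, float]
    max_residual: float
    tol_abs: float
    passed: bool

    def failing_junctions(self) -> list[str]:
        return [j for j, r in self.residuals.items() if abs(r) > self.tol_abs]


def _pipe_flow(dh, r, n, dh_lin):
    """Flow through a pipe for head drop ``dh`` (vectorized).

    Below ``dh_lin`` the law is linearized so the Jacobian stays bounded
    through flow reversals.
    """
    adh = np.abs(dh)
    q = np.sign(dh) * (adh / r) ** (1.0 / n)
    small = adh < dh_lin
    if np.any(small):
        slope = (dh_lin / r[small]) ** (1.0 / n) / dh_lin[small]
        q = np.where(small, slope * dh, q)
    return q


def _pipe_flow_deriv(dh, r, n, dh_lin):
    adh = np.abs(dh)
    with np.errstate(divide="ignore"):
        d = (adh / r) ** (1.0 / n) / (n * np.maximum(adh, 1e-300))
    small = adh < dh_lin
    if np.any(small):
        slope = (dh_lin / r[small]) ** (1.0 / n) / dh_lin[small]
        d = np.where(small, slope, d)
    return d


def solve_steady_flow(network: Network, tol: float = 1e-6,
                      max_iter: int = 200) -> FlowSolution:
    """Solve demand-driven steady flow; ``tol`` is relative to total demand.

    Raises :class:`DegenerateInputError` for zero total demand and
    :class:`SolverError` (with the residual) on non-convergence.
    """
    total_demand = network.total_demand
    if total_demand <= 0:
        raise DegenerateInputError("total demand must be positive")

    junctions = sorted(n.id for n in network.junctions)
    jidx = {nid: i for i, nid in enumerate(junctions)}
    nj = len(junctions)
    pipes = sorted(network.pipes.values(), key=lambda p: p.id)
    r = np.array([hw_resistance(p) for p in pipes])
    n = HW_EXPONENT
    # linearization threshold: headloss at a tiny fraction of total demand
    dh_lin = r * (1e-7 * total_demand) ** n

    # incidence: column index (or -1 for fixed-head source) per pipe end
    ifrom = np.array([jidx.get(p.from_node, -1) for p in pipes])
    ito = np.array([jidx.get(p.to_node, -1) for p in pipes])
    demand = np.array([network.nodes[j].demand for j in junctions])

    def heads_at(h, idx):
        return np.where(idx >= 0, h[np.clip(idx, 0, None)], 0.0)

    def residual(h):
        dh = heads_at(h, ifrom) - heads_at(h, ito)
        q = _pipe_flow(dh, r, n, dh_lin)
        f = -demand.copy()
        np.add.at(f, ifrom[ifrom >= 0], -q[ifrom >= 0])
        np.add.at(f, ito[ito >= 0], q[ito >= 0])
        return f, q

    # initial heads from a linearized (conductance) solve
    g0 = (1.0 / r) ** (1.0 / n) * total_demand ** (1.0 / n - 1.0)
    A = np.zeros((nj, nj))
    b = demand.copy()
    for k in range(len(pipes)):
        i, j, g = ifrom[k], ito[k], g0[k]
        if i >= 0:
            A[i, i] += g
        if j >= 0:
            A[j, j] += g
        if i >= 0 and j >= 0:
            A[i, j] -= g
            A[j, i] -= g
    try:
        h = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError:
        h = np.zeros(nj)

    f, q = residual(h)
    best = np.max(np.abs(f))
    for it in range(1, max_iter + 1):
        if best <= tol * total_demand:
            break
        dh = heads_at(h, ifrom) - heads_at(h, ito)
        dq = _pipe_flow_deriv(dh, r, n, dh_lin)
        J = np.zeros((nj, nj))
        for k in range(len(pipes)):
            i, j, g = ifrom[k], ito[k], dq[k]
            if i >= 0:
                J[i, i] += g
            if j >= 0:
                J[j, j] += g
            if i >= 0 and j >= 0:
                J[i, j] -= g
                J[j, i] -= g
        try:
            step = np.linalg.solve(J, f)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, f, rcond=None)[0]
        # backtracking damping on the residual norm
        alpha = 1.0
        for _ in range(30):
            f_new, q_new = residual(h + alpha * step)
            if np.max(np.abs(f_new)) < best:
                h = h + alpha * step
                f, q = f_new, q_new
                best = np.max(np.abs(f))
                break
            alpha *= 0.5
        else:  # no improving step found
            break
    else:
        it = max_iter

    if best > tol * total_demand:
        raise SolverError(
            f"flow solver did not converge in {max_iter} iterations; "
            f"max junction residual {best:.3e} ({best / total_demand:.3e} "
            "of total demand)", residual=float(best))

    flows = {p.id: float(q[k]) for k, p in enumerate(pipes)}
    heads = {j: float(h[jidx[j]]) for j in junctions}
    heads.update({s.id: 0.0 for s in network.sources})
    return FlowSolution(flows=flows, heads=heads, iterations=it,
                        max_residual=float(best))


def check_conservation(flow: FlowSolution, network: Network,
                       tol: float = 1e-6) -> ConservationReport:
    """Per-junction residual report; pass iff max residual <= tol*demand."""
    residuals = {}
    for node in network.junctions:
        net_in = 0.0
        for p in network.pipes.values():
            if p.to_node == node.id:
                net_in += flow.flows[p.id]
            if p.from_node == node.id:
                net_in -= flow.flows[p.id]
        residuals[node.id] = net_in - node.demand
    tol_abs = tol * max(network.total_demand, 1e-300)
    max_res = max((abs(v) for v in residuals.values()), default=0.0)
    return ConservationReport(residuals=residuals, max_residual=max_res,
                              tol_abs=tol_abs, passed=max_res <= tol_abs)
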