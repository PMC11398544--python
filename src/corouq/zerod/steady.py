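"""Steady nonlinear resistor-network solver.

Quasi-steady reduction of the coronary tree used as the fast inner model for
parameter estimation: segment resistances plus quadratic stenosis losses,
each outlet closed by its total distal resistance to a venous pressure.
Solved by fixed-point iteration on the flow-dependent effective resistances
R_eff = R + S * |Q| around a linear nodal solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import CircuitNetwork


@dataclass
class SteadySolution:
    outlet_ids: list[str]
    outlet_flows: np.ndarray          # cm^3/s, ordered as outlet_ids
    node_pressures: dict[str, float]  # distal-node pressure per segment
    segment_flows: dict[str, float]
    inlet_pressure: float
    venous_pressure: float

    @property
    def inflow(self) -> float:
        return float(self.outlet_flows.sum())


class SteadyTreeModel:
    """Precompiled steady solver for one tree topology.

    ``outlet_resistances`` passed to :meth:`solve` are total distal
    resistances keyed like ``outlet_ids``; segments' R and S come from the
    network anatomy.
    """

    def __init__(self, net: CircuitNetwork, inlet_pressure: float,
                 venous_pressure: float = 0.0):
        self.ids = list(net.segments)
        idx = {sid: k for k, sid in enumerate(self.ids)}
        segs = [net.segments[sid] for sid in self.ids]
        self.parent = np.array([-1 if s.parent is None else idx[s.parent] for s in segs])
        self.R = np.array([s.resistance for s in segs])
        self.S = np.array([s.stenosis_coefficient for s in segs])
        self.outlet_ids = [s.id for s in segs if s.is_outlet]
        self.outlet_rows = np.array([idx[o] for o in self.outlet_ids])
        self.n = len(self.ids)
        self.p_in = inlet_pressure
        self.p_ven = venous_pressure
        # rows of R floored to keep conductances finite (ideal junctions allowed)
        self.R = np.maximum(self.R, 1e-12)

    def solve(self, outlet_resistances: dict[str, float] | np.ndarray,
              tol: float = 1e-12, max_iter: int = 100) -> SteadySolution:
        if isinstance(outlet_resistances, dict):
            r_out = np.array([outlet_resistances[o] for o in self.outlet_ids], float)
        else:
            r_out = np.asarray(outlet_resistances, float)
        if np.any(r_out <= 0):
            raise ValueError("outlet resistances must be > 0")
        q = np.zeros(self.n)
        parent = self.parent
        has_parent = parent >= 0
        g_out = 1.0 / r_out
        p = None
        for _ in range(max_iter):
            g = 1.0 / (self.R + self.S * np.abs(q))
            # nodal system at each segment's distal node
            A = np.zeros((self.n, self.n))
            b = np.zeros(self.n)
            rows = np.arange(self.n)
            A[rows, rows] += g
            # inflow from proximal node (parent distal node or the inlet)
            A[rows[has_parent], parent[has_parent]] -= g[has_parent]
            b[~has_parent] += g[~has_parent] * self.p_in
            # outflow into children
            ch_rows = parent[has_parent]
            np.add.at(A, (ch_rows, ch_rows), g[has_parent])
            np.add.at(A, (ch_rows, rows[has_parent]), -g[has_parent])
            # outlet loads
            A[self.outlet_rows, self.outlet_rows] += g_out
            b[self.outlet_rows] += g_out * self.p_ven
            p = np.linalg.solve(A, b)
            p_prox = np.where(has_parent, p[np.maximum(parent, 0)], self.p_in)
            q_new = (p_prox - p) * g
            if np.max(np.abs(q_new - q)) <= tol * (1.0 + np.max(np.abs(q_new))):
                q = q_new
                break
            q = q_new
        outlet_flows = (p[self.outlet_rows] - self.p_ven) * g_out
        return SteadySolution(
            outlet_ids=list(self.outlet_ids),
            outlet_flows=outlet_flows,
            node_pressures={sid: float(p[k]) for k, sid in enumerate(self.ids)},
            segment_flows={sid: float(q[k]) for k, sid in enumerate(self.ids)},
            inlet_pressure=self.p_in, venous_pressure=self.p_ven)

    def outlet_flow_fn(self, outlet_subset: list[str] | None = None,
                       fixed: dict[str, float] | None = None):
        """Return f(r) mapping a resistance vector for ``outlet_subset`` to
        outlet flows (cm^3/s), holding the remaining outlets at ``fixed``."""
        subset = outlet_subset or self.outlet_ids
        fixed = dict(fixed or {})
        sub_pos = [self.outlet_ids.index(o) for o in subset]
        base = np.empty(len(self.outlet_ids))
        for k, o in enumerate(self.outlet_ids):
            if o not in subset:
                base[k] = fixed[o]

        def f(r: np.ndarray) -> np.ndarray:
            rr = base.copy()
            rr[sub_pos] = r
            sol = self.solve(rr)
            return sol.outlet_flows[sub_pos]

        return f
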