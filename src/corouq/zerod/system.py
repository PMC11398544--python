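"""Generic lumped-parameter circuit assembler and implicit time integrator.

The circuit is described by named nodes and a list of elements.  The state
vector stacks node pressures, branch flows (one per inertial/stenotic
branch) and chamber volumes.  The semi-discrete system has the form

    M dy/dt = g(y, t),

where rows of ``M`` that are identically zero are algebraic constraints
(Kirchhoff balances at compliance-free nodes, prescribed-pressure nodes,
elastance pressure definitions).  Time stepping uses a generalized
trapezoidal rule (theta-method) with Newton iteration on the nonlinear
stenosis and valve terms; algebraic rows are always enforced implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

GROUND = "__ground__"


class SolverError(RuntimeError):
    """Raised when Newton iteration fails or the state becomes non-finite."""


# ---------------------------------------------------------------------------
# Elements


@dataclass
class Element:
    name: str = ""

    def register(self, sys: "CircuitSystem") -> None:  # pragma: no cover
        raise NotImplementedError


@dataclass
class Resistor(Element):
    """Linear resistor stamped directly into the nodal balances (R > 0)."""

    a: str = ""
    b: str = ""
    R: float = 1.0

    def register(self, sys: "CircuitSystem") -> None:
        if self.R <= 0:
            raise ValueError(f"resistor {self.name}: R must be > 0, got {self.R}")
        G = 1.0 / self.R
        ia, ib = sys.node_index(self.a), sys.node_index(self.b)
        # flow a->b = G*(Pa - Pb); inflow at b, outflow at a
        sys.stamp_flow_linear(self.b, {ia: G, ib: -G})
        sys.stamp_flow_linear(self.a, {ia: -G, ib: G})


@dataclass
class Capacitor(Element):
    """Floating capacitor between two nodes (either may be ground/source)."""

    a: str = ""
    b: str = ""
    C: float = 0.0

    def register(self, sys: "CircuitSystem") -> None:
        if self.C < 0:
            raise ValueError(f"capacitor {self.name}: C must be >= 0")
        if self.C == 0:
            return
        ia, ib = sys.node_index(self.a), sys.node_index(self.b)
        # flow a->b through cap: C * d(Pa - Pb)/dt
        sys.stamp_mass(self.a, {ia: self.C, ib: -self.C})
        sys.stamp_mass(self.b, {ia: -self.C, ib: self.C})


@dataclass
class Branch(Element):
    """Series R-L branch with quadratic stenosis loss; carries its own flow
    unknown Q:  L dQ/dt = Pa - Pb - R*Q - S*|Q|*Q."""

    a: str = ""
    b: str = ""
    R: float = 0.0
    L: float = 0.0
    S: float = 0.0

    def register(self, sys: "CircuitSystem") -> None:
        if min(self.R, self.L, self.S) < 0:
            raise ValueError(f"branch {self.name}: R, L, S must be >= 0")
        iq = sys.add_flow_unknown(self.name)
        ia, ib = sys.node_index(self.a), sys.node_index(self.b)
        row = sys.row_of_unknown(iq)
        sys.M[row, iq] += self.L
        if ia >= 0:
            sys.A0[row, ia] += 1.0
        if ib >= 0:
            sys.A0[row, ib] -= 1.0
        sys.A0[row, iq] -= self.R
        if self.S > 0:
            S = self.S

            def _nl(y, out, jrows, jcols, jvals, row=row, iq=iq, S=S):
                q = y[iq]
                out[row] -= S * abs(q) * q
                jrows.append(row)
                jcols.append(iq)
                jvals.append(-2.0 * S * abs(q))

            sys.nonlinear.append(_nl)
        sys.stamp_flow_linear(self.b, {iq: 1.0})
        sys.stamp_flow_linear(self.a, {iq: -1.0})


@dataclass
class Valve(Element):
    """Smoothed diode: conductance blends between open and closed states
    via a sigmoid in the pressure difference."""

    a: str = ""
    b: str = ""
    R_open: float = 5.0
    R_closed: float = 1e7
    steepness: float = 0.05  # 1/(dyn/cm^2)

    def register(self, sys: "CircuitSystem") -> None:
        ia, ib = sys.node_index(self.a), sys.node_index(self.b)
        g_o, g_c, k = 1.0 / self.R_open, 1.0 / self.R_closed, self.steepness
        row_a = sys.flow_row(self.a)
        row_b = sys.flow_row(self.b)

        def _nl(y, out, jrows, jcols, jvals):
            pa = y[ia] if ia >= 0 else 0.0
            pb = y[ib] if ib >= 0 else 0.0
            dp = pa - pb
            x = np.clip(k * dp, -60.0, 60.0)
            sig = 1.0 / (1.0 + np.exp(-x))
            g = g_c + (g_o - g_c) * sig
            q = g * dp  # flow a->b
            dg = (g_o - g_c) * sig * (1.0 - sig) * k
            dq = g + dg * dp  # d q / d dp
            if row_b is not None:
                out[row_b] += q
            if row_a is not None:
                out[row_a] -= q
            for row, sgn in ((row_b, 1.0), (row_a, -1.0)):
                if row is None:
                    continue
                if ia >= 0:
                    jrows.append(row); jcols.append(ia); jvals.append(sgn * dq)
                if ib >= 0:
                    jrows.append(row); jcols.append(ib); jvals.append(-sgn * dq)

        sys.nonlinear.append(_nl)


@dataclass
class FlowSource(Element):
    """Prescribed inflow q(t) injected at a node."""

    node: str = ""
    q: Callable[[float], float] = lambda t: 0.0

    def register(self, sys: "CircuitSystem") -> None:
        qfun = self.q
        row = sys.flow_row(self.node)
        if row is not None:
            sys.forcing.append(lambda t, out, row=row: out.__setitem__(row, out[row] + qfun(t)))


@dataclass
class PressureSource(Element):
    """Node with prescribed pressure p(t); absorbs any net flow."""

    node: str = ""
    p: Callable[[float], float] = lambda t: 0.0

    def register(self, sys: "CircuitSystem") -> None:
        i = sys.node_index(self.node)
        sys.mark_source_node(self.node)
        row = sys.row_of_unknown(i)
        pfun = self.p
        sys.A0[row, i] -= 1.0
        sys.forcing.append(lambda t, out, row=row: out.__setitem__(row, out[row] + pfun(t)))


@dataclass
class LinkedPressureSource(Element):
    """Node whose pressure tracks another node's pressure times a scale
    (used for the intramyocardial pressure applied to coronary beds)."""

    node: str = ""
    ref_node: str = ""
    scale: float = 1.0

    def register(self, sys: "CircuitSystem") -> None:
        i = sys.node_index(self.node)
        j = sys.node_index(self.ref_node)
        sys.mark_source_node(self.node)
        row = sys.row_of_unknown(i)
        sys.A0[row, i] -= 1.0
        sys.A0[row, j] += self.scale


@dataclass
class ElastanceChamber(Element):
    """Time-varying elastance chamber: P = E(t) * (V - V0).

    Owns a volume unknown integrated from the net inflow at its node.
    """

    node: str = ""
    elastance: Callable[[float], float] = lambda t: 1000.0
    V0: float = 0.0
    V_init: float = 50.0

    def register(self, sys: "CircuitSystem") -> None:
        i = sys.node_index(self.node)
        iv = sys.add_volume_unknown(self.name or self.node, self.V_init)
        sys.mark_chamber_node(self.node, iv)
        # pressure definition (algebraic): P - E(t)*(V - V0) = 0
        prow = sys.row_of_unknown(i)
        sys.A0[prow, i] -= 1.0
        efun, V0 = self.elastance, self.V0
        sys.tv_entries.append((prow, iv, efun))
        sys.forcing.append(
            lambda t, out, prow=prow, efun=efun, V0=V0: out.__setitem__(
                prow, out[prow] - efun(t) * V0
            )
        )
        # volume row: dV/dt = net inflow at node  -> handled via flow_row mapping
        vrow = sys.row_of_unknown(iv)
        sys.M[vrow, iv] += 1.0


# ---------------------------------------------------------------------------
# System


class CircuitSystem:
    """Assembles elements into M, A0, forcing and nonlinear callbacks."""

    def __init__(self, node_names: Sequence[str], elements: Sequence[Element]):
        self.node_names = [n for n in node_names if n != GROUND]
        self._node_idx = {n: i for i, n in enumerate(self.node_names)}
        self.n_nodes = len(self.node_names)
        self.flow_names: list[str] = []
        self.volume_names: list[str] = []
        self._volume_init: list[float] = []
        self._chamber_vrow: dict[str, int] = {}
        self._source_nodes: set[str] = set()
        n_q = sum(1 for e in elements if isinstance(e, Branch))
        n_v = sum(1 for e in elements if isinstance(e, ElastanceChamber))
        self.n = self.n_nodes + n_q + n_v
        self.M = np.zeros((self.n, self.n))
        self.A0 = np.zeros((self.n, self.n))
        self.tv_entries: list[tuple[int, int, Callable[[float], float]]] = []
        self.forcing: list[Callable[[float, np.ndarray], None]] = []
        self.nonlinear: list[Callable] = []
        self._next_q = self.n_nodes
        self._next_v = self.n_nodes + n_q
        self.elements = list(elements)
        for e in self.elements:
            e.register(self)

    # -- registration helpers -------------------------------------------------

    def node_index(self, name: str) -> int:
        if name == GROUND:
            return -1
        return self._node_idx[name]

    def row_of_unknown(self, i: int) -> int:
        return i

    def add_flow_unknown(self, name: str) -> int:
        i = self._next_q
        self._next_q += 1
        self.flow_names.append(name or f"q{i}")
        return i

    def add_volume_unknown(self, name: str, v_init: float) -> int:
        i = self._next_v
        self._next_v += 1
        self.volume_names.append(name)
        self._volume_init.append(v_init)
        return i

    def mark_chamber_node(self, node: str, iv: int) -> None:
        self._chamber_vrow[node] = self.row_of_unknown(iv)

    def mark_source_node(self, node: str) -> None:
        self._source_nodes.add(node)

    def flow_row(self, node: str):
        """Row receiving net-inflow contributions for ``node`` (None if the
        node absorbs flow, i.e. ground or a pressure source)."""
        if node == GROUND or node in self._source_nodes:
            return None
        if node in self._chamber_vrow:
            return self._chamber_vrow[node]
        return self.row_of_unknown(self.node_index(node))

    def stamp_flow_linear(self, node: str, coeffs: dict[int, float]) -> None:
        row = self.flow_row(node)
        if row is None:
            return
        for col, val in coeffs.items():
            if col >= 0:
                self.A0[row, col] += val

    def stamp_mass(self, node: str, coeffs: dict[int, float]) -> None:
        row = self.flow_row(node)
        if row is None:
            return
        for col, val in coeffs.items():
            if col >= 0:
                self.M[row, col] += val

    # -- evaluation -----------------------------------------------------------

    def g(self, y: np.ndarray, t: float):
        """Right-hand side g(y, t) and its Jacobian."""
        A = self.A0.copy()
        for row, col, fn in self.tv_entries:
            A[row, col] += fn(t)
        out = A @ y
        for f in self.forcing:
            f(t, out)
        jrows: list[int] = []
        jcols: list[int] = []
        jvals: list[float] = []
        for nl in self.nonlinear:
            nl(y, out, jrows, jcols, jvals)
        if jrows:
            A[jrows, jcols] += np.asarray(jvals)
        return out, A

    def initial_state(self, pressures: dict[str, float] | None = None) -> np.ndarray:
        y = np.zeros(self.n)
        if pressures:
            for name, p in pressures.items():
                y[self.node_index(name)] = p
        for k, v in enumerate(self._volume_init):
            y[self.n_nodes + len(self.flow_names) + k] = v
        return y

    # -- time stepping --------------------------------------------------------

    def step(self, y0: np.ndarray, t0: float, dt: float, theta: float = 0.5,
             atol: float = 1e-8, rtol: float = 1e-6, max_iter: int = 30) -> np.ndarray:
        diff = np.abs(self.M).sum(axis=1) > 0.0
        g0, _ = self.g(y0, t0)
        t1 = t0 + dt
        y = y0.copy()
        scale = atol + rtol * np.maximum(np.abs(y0), 1.0)

        def residual(yc):
            g1, A1 = self.g(yc, t1)
            r = np.where(diff, self.M @ (yc - y0) - dt * (theta * g1 + (1 - theta) * g0), -g1)
            return r, A1

        res, A1 = residual(y)
        rnorm = np.linalg.norm(res)
        for it in range(max_iter):
            J = np.where(diff[:, None], self.M - dt * theta * A1, -A1)
            try:
                dy = np.linalg.solve(J, -res)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise SolverError(f"singular Jacobian at t={t1:.6g}") from exc
            # backtracking on the residual norm (valve sigmoids can overshoot)
            lam = 1.0
            for _ in range(8):
                y_try = y + lam * dy
                res_try, A_try = residual(y_try)
                rn_try = np.linalg.norm(res_try)
                if np.isfinite(rn_try) and (rn_try <= rnorm or lam <= 1.0 / 128):
                    break
                lam *= 0.5
            y, res, A1, rnorm = y_try, res_try, A_try, rn_try
            if not np.all(np.isfinite(y)):
                raise SolverError(f"non-finite state at t={t1:.6g}, iter {it}")
            if np.max(lam * np.abs(dy) / scale) < 1.0:
                return y
        raise SolverError(f"Newton did not converge at t={t1:.6g} after {max_iter} iterations")

    def robust_step(self, y0: np.ndarray, t0: float, dt: float, theta: float = 0.5) -> np.ndarray:
        """Take one step; on Newton failure fall back to backward-Euler
        substeps (valve transitions can defeat the trapezoidal rule)."""
        try:
            return self.step(y0, t0, dt, theta=theta)
        except SolverError:
            pass
        y = y0
        for nsub in (1, 4, 16):
            try:
                h = dt / nsub
                y = y0
                for j in range(nsub):
                    y = self.step(y, t0 + j * h, h, theta=1.0, max_iter=60)
                return y
            except SolverError:
                continue
        raise SolverError(f"step at t={t0:.6g} failed even with 16 backward-Euler substeps")

    def integrate(self, y0: np.ndarray, t_end: float, dt: float, theta: float = 0.5,
                  n_startup_be: int = 5, record: bool = True):
        """Integrate from t=0 to t_end; returns (times, states) arrays."""
        nsteps = int(round(t_end / dt))
        times = np.linspace(0.0, nsteps * dt, nsteps + 1)
        y = y0.copy()
        states = np.empty((nsteps + 1, self.n)) if record else None
        if record:
            states[0] = y
        for k in range(nsteps):
            th = 1.0 if k < n_startup_be else theta
            y = self.robust_step(y, times[k], dt, theta=th)
            if record:
                states[k + 1] = y
        return times, (states if record else y)


@dataclass
class SimulationResult:
    """Waveforms of the retained final cycle plus convergence diagnostics."""

    time: np.ndarray
    pressures: dict[str, np.ndarray]
    flows: dict[str, np.ndarray]
    volumes: dict[str, np.ndarray] = field(default_factory=dict)
    cycle_convergence: float = np.nan

    def mean_pressure(self, node: str) -> float:
        return float(np.mean(self.pressures[node]))

    def mean_flow(self, branch: str) -> float:
        return float(np.mean(self.flows[branch]))

    def to_frame(self):
        """Long-format table (time, node, pressure_mmHg) / (time, branch, flow)."""
        import pandas as pd
        from ..units import DYNCM2_TO_MMHG

        rows = []
        for name, p in self.pressures.items():
            for t, v in zip(self.time, p):
                rows.append(("pressure", name, t, v * DYNCM2_TO_MMHG))
        for name, q in self.flows.items():
            for t, v in zip(self.time, q):
                rows.append(("flow", name, t, v))
        return pd.DataFrame(rows, columns=["kind", "name", "time_s", "value"])


def run_periodic(sys: CircuitSystem, y0: np.ndarray, period: float, n_cycles: int,
                 steps_per_cycle: int, theta: float = 0.5,
                 conv_indices: Sequence[int] | None = None) -> SimulationResult:
    """Integrate n_cycles and retain the final cycle's waveforms.

    The convergence metric is the maximum relative change, between the last
    two cycles, of the cycle-mean of the monitored state components
    (``conv_indices``; all components by default).
    """
    dt = period / steps_per_cycle
    y = y0.copy()
    prev_means = None
    conv = np.nan
    last = None
    mon = np.arange(sys.n) if conv_indices is None else np.asarray(conv_indices)
    for c in range(n_cycles):
        t_off = c * period
        states = np.empty((steps_per_cycle + 1, sys.n))
        states[0] = y
        for k in range(steps_per_cycle):
            th = 1.0 if (c == 0 and k < 5) else theta
            y = sys.robust_step(y, t_off + k * dt, dt, theta=th)
            states[k + 1] = y
        means = states[1:, mon].mean(axis=0)
        if prev_means is not None:
            ref = np.maximum(np.abs(prev_means), 1e-3 * np.max(np.abs(prev_means)) + 1e-30)
            conv = float(np.max(np.abs(means - prev_means) / ref))
        prev_means = means
        last = states
    t = np.arange(steps_per_cycle + 1) * dt
    np_, nq = sys.n_nodes, len(sys.flow_names)
    pressures = {name: last[:, i] for i, name in enumerate(sys.node_names)}
    flows = {name: last[:, np_ + i] for i, name in enumerate(sys.flow_names)}
    volumes = {name: last[:, np_ + nq + i] for i, name in enumerate(sys.volume_names)}
    return SimulationResult(time=t, pressures=pressures, flows=flows,
                            volumes=volumes, cycle_convergence=conv)
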