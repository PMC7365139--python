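"""Composition and simulation of sensor/gate circuits over an AHL wire.

A circuit is a directed acyclic network of typed nodes:

``sensor``
    reads one named inducer from the environment through an activating
    Hill curve (instantaneous: small-molecule sensing equilibrates much
    faster than gate turnover);
``not_gate`` / ``nor_gate``
    CRISPRi repression stages with repressive Hill transfer functions;
``ahl_sender``
    expresses LuxI from its driving promoter; its output (a LuxI proxy in
    MEFL) feeds volumetric AHL production at ``k_prod`` nM/h per OD600 per
    MEFL;
``ahl_receiver``
    the LuxR-activated promoter, an activating Hill curve versus the
    shared AHL concentration in nM;
``reporter``
    a probe of exactly one upstream node (pass-through).

Steady-state prediction is a single topological pass of the fitted Hill
models, mirroring how the composed MUX/DEMUX models are assembled from
individually characterized parts.  Dynamics assume excess dCas9 and
stable, quickly forming dCas9:sgRNA complexes, so each gate output relaxes
toward its steady-state value at the cell growth rate (dilution of stable
repressor by growth is the only decay process):

    dX/dt = lambda * (f(upstream) - X)

AHL is shared and well mixed, produced at ``dA/dt = k_prod * OD * LuxI``
and removed only by media-replacement dilution events, which also scale
each strain's OD by the retained fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import networkx as nx
import pandas as pd
from scipy.integrate import solve_ivp

from .gates import HillParams, not_response, nor_response, sensor_response

__all__ = [
    "AhlParams",
    "CircuitNode",
    "CircuitSpec",
    "Phase",
    "Protocol",
    "Trajectory",
    "steady_state",
    "simulate_dynamics",
    "estimate_ahl_rate",
    "activation_time",
]

AHL_SPECIES = "AHL"

#: AHL production rate of LuxI measured with a receiver-strain biosensor,
#: in nM of AHL per hour per OD600 of sender cells per MEFL of LuxI proxy.
DEFAULT_K_PROD = 0.089


@dataclass(frozen=True)
class AhlParams:
    """AHL wire parameters: production rate plus the receiving promoter."""

    k_prod: float = DEFAULT_K_PROD
    receiver: HillParams | None = None

    def __post_init__(self) -> None:
        if self.k_prod < 0:
            raise ValueError("k_prod must be >= 0")


@dataclass(frozen=True)
class CircuitNode:
    id: str
    role: str  # sensor | not_gate | nor_gate | ahl_sender | ahl_receiver | reporter
    inputs: tuple[str, ...] = ()
    params: object = None  # HillParams or AhlParams depending on role

    _ARITY = {
        "sensor": 1,
        "not_gate": 1,
        "nor_gate": 2,
        "ahl_sender": 1,
        "ahl_receiver": 1,
        "reporter": 1,
    }

    def __post_init__(self) -> None:
        if self.role not in self._ARITY:
            raise ValueError(f"unknown node role {self.role!r}")
        if len(self.inputs) != self._ARITY[self.role]:
            raise ValueError(
                f"{self.role} node {self.id!r} needs exactly "
                f"{self._ARITY[self.role]} input(s)"
            )
        if self.role == "ahl_receiver" and self.inputs != (AHL_SPECIES,):
            raise ValueError("ahl_receiver input must be the shared AHL species")


@dataclass(frozen=True)
class CircuitSpec:
    """Acyclic network of sensors, gates, AHL wire steps, and reporters."""

    nodes: tuple[CircuitNode, ...]
    strain_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        known = set(ids) | {AHL_SPECIES}
        for n in self.nodes:
            if n.role == "sensor":
                continue  # sensor input is an inducer name in the environment
            for src in n.inputs:
                if src not in known:
                    raise ValueError(f"node {n.id!r} reads unknown node {src!r}")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValueError("circuit contains a cycle")

    def node(self, node_id: str) -> CircuitNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_node(AHL_SPECIES)
        for n in self.nodes:
            g.add_node(n.id)
        for n in self.nodes:
            if n.role == "sensor":
                continue
            for src in n.inputs:
                g.add_edge(src, n.id)
            if n.role == "ahl_sender":
                g.add_edge(n.id, AHL_SPECIES)
        return g

    def topological(self) -> list[CircuitNode]:
        order = {nid: i for i, nid in enumerate(nx.topological_sort(self.graph()))}
        return sorted(self.nodes, key=lambda n: order[n.id])

    def strain(self, node_id: str) -> str:
        return dict(self.strain_of).get(node_id, "strain")

    def strains(self) -> list[str]:
        return sorted({self.strain(n.id) for n in self.nodes})


@dataclass(frozen=True)
class Phase:
    """One protocol phase: a constant inducer environment with periodic dilution."""

    duration_h: float
    environment: Mapping[str, float] = field(default_factory=dict)
    dilution_period_h: float | None = None
    retained_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("phase duration must be > 0")
        if not (0 < self.retained_fraction <= 1):
            raise ValueError("retained fraction must be in (0, 1]")
        if self.dilution_period_h is not None and self.dilution_period_h <= 0:
            raise ValueError("dilution period must be > 0")


@dataclass(frozen=True)
class Protocol:
    phases: tuple[Phase, ...]
    initial_od: Mapping[str, float] = field(default_factory=dict)
    growth_rate: Mapping[str, float] = field(default_factory=dict)
    dilute_ahl: bool = True  # fresh medium contains no AHL

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        for od in dict(self.initial_od).values():
            if od <= 0:
                raise ValueError("initial ODs must be > 0")

    def od0(self, strain: str) -> float:
        return dict(self.initial_od).get(strain, 0.05)

    def rate(self, strain: str) -> float:
        return dict(self.growth_rate).get(strain, 0.6)


@dataclass
class Trajectory:
    """Time series of node outputs (MEFL), per-strain OD600, and AHL (nM)."""

    times: np.ndarray
    outputs: dict[str, np.ndarray]
    od: dict[str, np.ndarray]
    ahl: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, variable, value) table."""
        rows = []
        for name, series in self.outputs.items():
            rows.append(pd.DataFrame({"time": self.times, "variable": name, "value": series}))
        for strain, series in self.od.items():
            rows.append(
                pd.DataFrame({"time": self.times, "variable": f"OD:{strain}", "value": series})
            )
        rows.append(pd.DataFrame({"time": self.times, "variable": "AHL", "value": self.ahl}))
        return pd.concat(rows, ignore_index=True)


def _node_output(
    node: CircuitNode,
    upstream: Callable[[str], float],
    env: Mapping[str, float],
    ahl: float,
) -> float:
    if node.role == "sensor":
        inducer = node.inputs[0]
        if inducer not in env:
            raise KeyError(f"environment does not define inducer {inducer!r}")
        return sensor_response(env[inducer], node.params)
    if node.role == "not_gate":
        return not_response(upstream(node.inputs[0]), node.params)
    if node.role == "nor_gate":
        return nor_response(upstream(node.inputs[0]), upstream(node.inputs[1]), node.params)
    if node.role == "ahl_sender":
        return upstream(node.inputs[0])  # LuxI proxy = driving promoter MEFL
    if node.role == "ahl_receiver":
        return sensor_response(ahl, node.params)
    if node.role == "reporter":
        return upstream(node.inputs[0])
    raise AssertionError(node.role)


def steady_state(
    c: CircuitSpec,
    env: Mapping[str, float],
    ahl_window_h: float = 1.0,
    sender_od: float = 0.2,
) -> dict[str, float]:
    """Predict per-node steady-state MEFL with one topological pass.

    If the environment supplies an ``"AHL"`` concentration it drives the
    receiver directly; otherwise, when the circuit contains a sender, a
    quasi-steady AHL level ``k_prod * sender_od * LuxI * ahl_window_h`` is
    used (AHL itself never reaches a true steady state under constant
    production, so the accumulation window is an explicit convention).
    The returned mapping includes the ``"AHL"`` level used.
    """
    values: dict[str, float] = {}
    ahl = float(env.get(AHL_SPECIES, 0.0))
    up = values.__getitem__
    for node in c.topological():
        values[node.id] = _node_output(node, up, env, ahl)
        if node.role == "ahl_sender" and AHL_SPECIES not in env:
            ahl = node.params.k_prod * sender_od * values[node.id] * ahl_window_h
    values[AHL_SPECIES] = ahl
    return values


def simulate_dynamics(
    c: CircuitSpec,
    proto: Protocol,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    record_dt_h: float = 0.05,
) -> Trajectory:
    """Integrate circuit dynamics through a dilution/induction protocol.

    Sensors are algebraic; every gate and receiver output is a first-order
    variable relaxing to its instantaneous Hill target at the strain's
    growth rate; AHL accumulates from all senders.  Dilution events scale
    ODs (and AHL, when ``proto.dilute_ahl``) by the retained fraction;
    intracellular MEFL states are unchanged by culture dilution.
    """
    order = c.topological()
    inducers = {n.inputs[0] for n in order if n.role == "sensor"}

    def phase_env(phase: Phase) -> dict[str, float]:
        # every sensor's inducer defaults to absent; "AHL" names exogenous AHL
        env = {name: 0.0 for name in inducers}
        env.update(phase.environment)
        return env

    dynamic = [n for n in order if n.role in ("not_gate", "nor_gate", "ahl_receiver")]
    dyn_index = {n.id: i for i, n in enumerate(dynamic)}
    strains = c.strains()
    sender_nodes = [n for n in order if n.role == "ahl_sender"]
    n_dyn, n_str = len(dynamic), len(strains)

    def outputs_at(state, env):
        """All node outputs given the dynamic state vector."""
        vals: dict[str, float] = {}
        ahl = max(state[n_dyn + n_str], 0.0) + env.get(AHL_SPECIES, 0.0)

        def up(nid: str) -> float:
            return vals[nid]

        for node in order:
            if node.id in dyn_index:
                vals[node.id] = max(state[dyn_index[node.id]], 0.0)
            else:
                vals[node.id] = _node_output(node, up, env, ahl)
        return vals

    def rhs(t, state, env):
        vals = outputs_at(state, env)
        ahl = max(state[n_dyn + n_str], 0.0) + env.get(AHL_SPECIES, 0.0)
        d = np.zeros_like(state)
        for node in dynamic:
            lam = proto.rate(c.strain(node.id))
            target = _node_output(node, vals.__getitem__, env, ahl)
            d[dyn_index[node.id]] = lam * (target - state[dyn_index[node.id]])
        for j, s in enumerate(strains):
            d[n_dyn + j] = proto.rate(s) * state[n_dyn + j]
        dA = 0.0
        for node in sender_nodes:
            od = state[n_dyn + strains.index(c.strain(node.id))]
            dA += node.params.k_prod * od * vals[node.id]
        d[n_dyn + n_str] = dA
        return d

    # initial condition: gates start at their uninduced steady state
    init = steady_state(c, {**{name: 0.0 for name in inducers}, AHL_SPECIES: 0.0})
    state = np.zeros(n_dyn + n_str + 1)
    for nid, i in dyn_index.items():
        state[i] = init[nid]
    for j, s in enumerate(strains):
        state[n_dyn + j] = proto.od0(s)
    state[n_dyn + n_str] = 0.0

    times: list[float] = []
    records: list[np.ndarray] = []
    out_records: list[dict[str, float]] = []
    t0 = 0.0

    def record(t, state, env):
        vals = outputs_at(state, env)
        times.append(t)
        records.append(state.copy())
        out_records.append(vals)

    record(t0, state, phase_env(proto.phases[0]))
    for phase in proto.phases:
        env = phase_env(phase)
        t_end = t0 + phase.duration_h
        # segment boundaries at dilution events
        bounds = [t0]
        if phase.dilution_period_h is not None:
            t = t0 + phase.dilution_period_h
            while t < t_end - 1e-9:
                bounds.append(t)
                t += phase.dilution_period_h
        bounds.append(t_end)
        for a, b in zip(bounds[:-1], bounds[1:]):
            n_rec = max(2, int(np.ceil((b - a) / record_dt_h)) + 1)
            t_eval = np.linspace(a, b, n_rec)
            sol = solve_ivp(
                rhs, (a, b), state, t_eval=t_eval, args=(env,), rtol=rtol, atol=atol,
                method="LSODA",
            )
            if not sol.success:
                raise RuntimeError(f"integration failed on [{a:.3g}, {b:.3g}]: {sol.message}")
            for ti, yi in zip(sol.t[1:], sol.y.T[1:]):
                record(ti, yi, env)
            state = sol.y[:, -1].copy()
            if b < t_end - 1e-9:  # dilution event at b
                frac = phase.retained_fraction
                state[n_dyn : n_dyn + n_str] *= frac
                if proto.dilute_ahl:
                    state[n_dyn + n_str] *= frac
                record(b + 1e-9, state, env)
        t0 = t_end

    t_arr = np.asarray(times)
    rec_arr = np.asarray(records)
    keep = np.concatenate([[True], np.diff(t_arr) > 0])
    t_arr, rec_arr = t_arr[keep], rec_arr[keep]
    out_records = [o for o, k in zip(out_records, keep) if k]
    outputs = {
        n.id: np.array([o[n.id] for o in out_records]) for n in order
    }
    od = {s: rec_arr[:, n_dyn + j] for j, s in enumerate(strains)}
    return Trajectory(
        times=t_arr, outputs=outputs, od=od, ahl=np.maximum(rec_arr[:, -1], 0.0)
    )


def estimate_ahl_rate(
    times: Sequence[float],
    od: Sequence[float],
    luxi_mefl: Sequence[float],
    receiver_readout: Sequence[float],
    receiver_params: HillParams,
) -> float:
    """Estimate the LuxI AHL production rate from a biosensor time course.

    Supernatant sampled at ``times`` is read out by a receiver strain; the
    receiver's activating Hill curve is inverted to AHL (nM) and regressed
    through the origin against the trapezoidal integral of OD * LuxI, whose
    slope is ``k_prod`` in nM/h/OD600/MEFL.  Readouts outside the strictly
    invertible range (at or beyond the curve's asymptotes) are excluded
    with a warning.
    """
    t = np.asarray(times, dtype=float)
    od_arr = np.asarray(od, dtype=float)
    lux = np.asarray(luxi_mefl, dtype=float)
    y = np.asarray(receiver_readout, dtype=float)
    if receiver_params.mode != "activation":
        raise ValueError("receiver params must be activation mode")
    p = receiver_params
    span = p.y_max - p.y_min
    if span <= 0:
        raise ValueError("receiver curve is flat; not invertible")
    frac = (y - p.y_min) / span
    ok = (frac > 0) & (frac < 1)
    # a readout at exactly y_min inverts to zero AHL; keep it (regression anchor)
    at_floor = np.isclose(y, p.y_min)
    ahl = np.full_like(y, np.nan)
    ahl[ok] = p.K * (frac[ok] / (1 - frac[ok])) ** (1.0 / p.n)
    ahl[at_floor] = 0.0
    usable = ok | at_floor
    if not np.all(usable):
        warnings.warn(
            f"{int((~usable).sum())} receiver readout(s) outside the invertible "
            "range were excluded from the AHL-rate regression"
        )
    exposure = np.concatenate(
        [[0.0], np.cumsum(0.5 * (od_arr[1:] * lux[1:] + od_arr[:-1] * lux[:-1]) * np.diff(t))]
    )
    xx = exposure[usable]
    yy = ahl[usable]
    denom = float(np.sum(xx**2))
    if denom == 0.0:
        return 0.0
    return float(np.sum(xx * yy) / denom)


def activation_time(
    t: Trajectory,
    node_id: str,
    threshold_fraction: float,
    lo: float | None = None,
    hi: float | None = None,
) -> float | None:
    """First time a node's output crosses lo + fraction * (hi - lo).

    By default ``lo``/``hi`` are the node trajectory's own minimum and
    maximum, so a first-order rise from 0 to P/lambda crosses the 0.5
    threshold at ln(2)/lambda.  Linear interpolation between recorded
    steps; returns None if the threshold is never crossed.
    """
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must be in (0, 1)")
    if node_id not in t.outputs:
        raise KeyError(f"trajectory has no node {node_id!r}")
    y = t.outputs[node_id]
    lo = float(np.min(y)) if lo is None else lo
    hi = float(np.max(y)) if hi is None else hi
    thr = lo + threshold_fraction * (hi - lo)
    above = y >= thr
    if above[0]:
        # rising crossings only: skip until the signal is below threshold
        below_idx = np.argmax(~above)
        if above[below_idx]:
            return None  # never below threshold -> no rise to detect
    for i in range(1, len(y)):
        if y[i] >= thr and y[i - 1] < thr:
            t0, t1 = t.times[i - 1], t.times[i]
            y0, y1 = y[i - 1], y[i]
            return float(t0 + (thr - y0) / (y1 - y0) * (t1 - t0))
    return None
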