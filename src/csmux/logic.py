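"""Exhaustive synthesis and analysis of NOT/NOR gate networks.

Transcriptional logic built from CRISPRi repressors offers exactly two
primitives: a NOT gate (one input promoter driving an sgRNA that represses
the output promoter) and a NOR gate (two input promoters driving the same
sgRNA).  Both are functionally complete, so any combinational function --
in particular the 2-input multiplexer (MUX) and the 2-output demultiplexer
(DEMUX) that make up a channel selector -- can be compiled into them.

This module provides:

* :class:`TruthTable`, :class:`GateNetwork`, :class:`NetworkMetrics` --
  the combinational-logic domain types;
* :func:`evaluate_network` -- deterministic Boolean evaluation;
* :func:`synthesize_minimal` -- exhaustive iterative-deepening search for
  a network with the provably minimum number of gates;
* :func:`network_metrics` -- gate counts, layers, fan-in, fan-out;
* :func:`build_cs_network` -- constructive n-channel channel selectors in
  two composition styles, for scaling-law measurements.

Constant signals (tie-to-0/1) are deliberately unavailable: in the
biological setting an absent promoter is simply a low signal, and the only
sources are the declared inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "TruthTable",
    "Gate",
    "GateNetwork",
    "NetworkMetrics",
    "NotSynthesizableError",
    "evaluate_network",
    "synthesize_minimal",
    "network_metrics",
    "build_cs_network",
    "mux_truth_table",
    "demux_truth_table",
]

GateKind = str  # "NOT" | "NOR"


class NotSynthesizableError(ValueError):
    """Raised when no NOT/NOR network within the gate budget matches the table."""


@dataclass(frozen=True)
class TruthTable:
    """A complete truth table over ``n_inputs`` Boolean inputs.

    Row ``r`` assigns input ``i`` the value ``(r >> i) & 1`` (input 0 is the
    least-significant bit), and ``rows[r]`` is the output bit-vector for
    that assignment.
    """

    n_inputs: int
    n_outputs: int
    rows: tuple[tuple[int, ...], ...]
    input_names: tuple[str, ...] = ()
    output_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("need at least one input")
        if len(self.rows) != 2**self.n_inputs:
            raise ValueError(
                f"expected {2 ** self.n_inputs} rows, got {len(self.rows)}"
            )
        for row in self.rows:
            if len(row) != self.n_outputs:
                raise ValueError("output vector length != n_outputs")
            if any(v not in (0, 1) for v in row):
                raise ValueError("truth table entries must be 0/1")
        if not self.input_names:
            object.__setattr__(
                self, "input_names", tuple(f"x{i}" for i in range(self.n_inputs))
            )
        if not self.output_names:
            object.__setattr__(
                self, "output_names", tuple(f"y{i}" for i in range(self.n_outputs))
            )

    @classmethod
    def from_function(
        cls,
        n_inputs: int,
        fn,
        input_names: Sequence[str] = (),
        output_names: Sequence[str] = (),
    ) -> "TruthTable":
        """Tabulate ``fn(bits) -> output bits`` over all assignments."""
        rows = []
        for r in range(2**n_inputs):
            bits = tuple((r >> i) & 1 for i in range(n_inputs))
            out = fn(bits)
            if isinstance(out, int):
                out = (out,)
            rows.append(tuple(int(v) for v in out))
        return cls(
            n_inputs,
            len(rows[0]),
            tuple(rows),
            tuple(input_names),
            tuple(output_names),
        )

    def column(self, j: int) -> int:
        """Output column ``j`` packed as an integer bit-vector over rows."""
        v = 0
        for r, row in enumerate(self.rows):
            v |= row[j] << r
        return v


def mux_truth_table() -> TruthTable:
    """2-input multiplexer: OUT = IN1 if SELECT == 0 else IN2."""
    return TruthTable.from_function(
        3,
        lambda b: b[0] if b[2] == 0 else b[1],
        input_names=("IN1", "IN2", "SELECT"),
        output_names=("OUT_MUX",),
    )


def demux_truth_table() -> TruthTable:
    """2-output demultiplexer: (OUT1, OUT2) = (IN & ~S, IN & S)."""
    return TruthTable.from_function(
        2,
        lambda b: (b[0] & (1 - b[1]), b[0] & b[1]),
        input_names=("IN", "SELECT"),
        output_names=("OUT1", "OUT2"),
    )


@dataclass(frozen=True)
class Gate:
    id: str
    kind: GateKind
    inputs: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind == "NOT":
            if len(self.inputs) != 1:
                raise ValueError(f"NOT gate {self.id} must have exactly 1 input")
        elif self.kind == "NOR":
            if len(self.inputs) < 2:
                raise ValueError(f"NOR gate {self.id} needs >= 2 inputs")
        else:
            raise ValueError(f"unknown gate kind {self.kind!r}")


@dataclass(frozen=True)
class GateNetwork:
    """An acyclic network of NOT/NOR gates over named inputs.

    ``gates`` need not be topologically sorted; validation orders them.
    Every non-input node must be reachable from the inputs (guaranteed by
    acyclicity plus each gate input referring to an existing node).
    """

    inputs: tuple[str, ...]
    gates: tuple[Gate, ...]
    outputs: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = set(self.inputs)
        for g in self.gates:
            if g.id in ids:
                raise ValueError(f"duplicate node id {g.id!r}")
            ids.add(g.id)
        for g in self.gates:
            for src in g.inputs:
                if src not in ids:
                    raise ValueError(f"gate {g.id} reads unknown node {src!r}")
        for out in self.outputs:
            if out not in ids:
                raise ValueError(f"unknown output node {out!r}")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValueError("gate network contains a cycle")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.inputs, kind="INPUT")
        for gate in self.gates:
            g.add_node(gate.id, kind=gate.kind)
            for src in gate.inputs:
                g.add_edge(src, gate.id)
        return g

    def topological_gates(self) -> list[Gate]:
        order = {n: i for i, n in enumerate(nx.topological_sort(self.graph()))}
        return sorted(self.gates, key=lambda g: order[g.id])

    def serialize(self) -> tuple:
        """Canonical netlist tuple used for deterministic tie-breaking."""
        return (
            self.inputs,
            tuple((g.kind, g.id, g.inputs) for g in self.topological_gates()),
            self.outputs,
        )


@dataclass(frozen=True)
class NetworkMetrics:
    n_not: int
    n_nor: int
    depth: int
    max_fan_in: int
    max_fan_out: int

    @property
    def n_gates(self) -> int:
        return self.n_not + self.n_nor


def evaluate_network(
    network: GateNetwork, assignment: Sequence[int]
) -> tuple[int, ...]:
    """Evaluate the network on one input bit-vector.

    ``assignment`` is ordered like ``network.inputs``.  NOT(x) = ~x,
    NOR(a, b, ...) = ~(a | b | ...).
    """
    if len(assignment) != len(network.inputs):
        raise ValueError(
            f"assignment length {len(assignment)} != {len(network.inputs)} inputs"
        )
    values: dict[str, int] = {
        name: int(bool(v)) for name, v in zip(network.inputs, assignment)
    }
    for gate in network.topological_gates():
        ins = [values[s] for s in gate.inputs]
        values[gate.id] = int(not any(ins))  # NOT is 1-ary NOR
    return tuple(values[o] for o in network.outputs)


def network_metrics(network: GateNetwork) -> NetworkMetrics:
    """Gate counts, depth in gate layers, and fan statistics.

    Depth is the longest input-to-output path counted in gate nodes; a
    single gate has depth 1.  Fan-out counts consumers of a node's signal,
    including input nodes.
    """
    n_not = sum(1 for g in network.gates if g.kind == "NOT")
    n_nor = sum(1 for g in network.gates if g.kind == "NOR")
    layer: dict[str, int] = {name: 0 for name in network.inputs}
    fan_out: dict[str, int] = {name: 0 for name in network.inputs}
    max_fan_in = 0
    for gate in network.topological_gates():
        layer[gate.id] = 1 + max(layer[s] for s in gate.inputs)
        max_fan_in = max(max_fan_in, len(gate.inputs))
        fan_out.setdefault(gate.id, 0)
        for s in gate.inputs:
            fan_out[s] += 1
    depth = max((layer[o] for o in network.outputs), default=0)
    return NetworkMetrics(
        n_not=n_not,
        n_nor=n_nor,
        depth=depth,
        max_fan_in=max_fan_in,
        max_fan_out=max(fan_out.values(), default=0),
    )


# ---------------------------------------------------------------------------
# Minimal synthesis
# ---------------------------------------------------------------------------


def _fanin_closure(gate_inputs: list[tuple[int, ...]], n_in: int, start: int) -> set:
    """Indices of gates in the transitive fan-in of signal ``start``."""
    seen: set[int] = set()
    stack = [start]
    while stack:
        s = stack.pop()
        if s < n_in or s in seen:
            continue
        seen.add(s)
        stack.extend(gate_inputs[s - n_in])
    return seen


def synthesize_minimal(
    tt: TruthTable, gate_budget: int = 6, terminal_outputs: bool = True
) -> GateNetwork:
    """Find a NOT/NOR network matching ``tt`` with provably minimum gate count.

    Iterative deepening over the total gate count guarantees that the first
    size at which a match exists is the minimum; the search at each size is
    exhaustive over fan-in-2 NOR and fan-in-1 NOT gates reading any earlier
    signal.  Networks in which a gate duplicates an already-available
    Boolean function are pruned (any matching network containing such a
    gate can be rewired to a strictly smaller one, so no minimum is lost).

    With ``terminal_outputs`` (the default) output nodes may not feed other
    gates: in the transcriptional realization every output promoter drives
    its payload gene, not further logic.  For multi-output tables this can
    raise the minimum relative to unconstrained electronic synthesis
    (``terminal_outputs=False``); single-output tables are unaffected.

    Among all minimum-size solutions the result is the best under the key
    (fewer layers, fewer NOR gates, lexicographically smallest canonical
    netlist), making the output deterministic.

    Raises :class:`NotSynthesizableError` if no network with at most
    ``gate_budget`` gates matches.
    """
    if gate_budget < 0:
        raise ValueError("gate_budget must be >= 0")
    n = tt.n_inputs
    n_rows = 2**n
    mask = (1 << n_rows) - 1
    input_vecs = []
    for i in range(n):
        v = 0
        for r in range(n_rows):
            v |= ((r >> i) & 1) << r
        input_vecs.append(v)
    targets = [tt.column(j) for j in range(tt.n_outputs)]

    def emit(signals: list[int], gates: list[tuple[str, tuple[int, ...]]]):
        """Yield complete networks matching all outputs, all gates used."""
        k = len(gates)
        candidates = []
        for t in targets:
            cand = [i for i, s in enumerate(signals) if s == t]
            if not cand:
                return
            candidates.append(cand)
        gate_inputs = [g[1] for g in gates]
        all_gates = set(range(n, n + k))
        consumed = {s for _, ins in gates for s in ins}
        for choice in itertools.product(*candidates):
            # inputs may fan out freely; only gate outputs are terminal
            if terminal_outputs and any(c >= n and c in consumed for c in choice):
                continue
            used: set[int] = set()
            for c in choice:
                used |= _fanin_closure(gate_inputs, n, c)
            if used != all_gates:
                continue
            names = list(tt.input_names) + [f"g{i + 1}" for i in range(k)]
            net = GateNetwork(
                inputs=tt.input_names,
                gates=tuple(
                    Gate(names[n + i], kind, tuple(names[j] for j in ins))
                    for i, (kind, ins) in enumerate(gates)
                ),
                outputs=tuple(names[c] for c in choice),
            )
            yield net

    for k in range(gate_budget + 1):
        best: tuple | None = None
        best_net: GateNetwork | None = None

        def rec(signals: list[int], gates: list):
            nonlocal best, best_net
            if len(gates) == k:
                for net in emit(signals, gates):
                    m = network_metrics(net)
                    key = (m.depth, m.n_nor, net.serialize())
                    if best is None or key < best:
                        best, best_net = key, net
                return
            seen = set(signals)
            m_sig = len(signals)
            for a in range(m_sig):
                f = ~signals[a] & mask
                if f not in seen:
                    rec(signals + [f], gates + [("NOT", (a,))])
            for a in range(m_sig):
                for b in range(a + 1, m_sig):
                    f = ~(signals[a] | signals[b]) & mask
                    if f not in seen:
                        rec(signals + [f], gates + [("NOR", (a, b))])

        rec(list(input_vecs), [])
        if best_net is not None:
            return best_net
    raise NotSynthesizableError(
        f"no NOT/NOR network with <= {gate_budget} gates matches the truth table"
    )


# ---------------------------------------------------------------------------
# Constructive channel selectors
# ---------------------------------------------------------------------------


class _Builder:
    """Incremental netlist builder with fresh gate names."""

    def __init__(self, inputs: Sequence[str]):
        self.inputs = tuple(inputs)
        self.gates: list[Gate] = []
        self._n = 0
        self._not_cache: dict[str, str] = {}

    def fresh(self, prefix: str) -> str:
        self._n += 1
        return f"{prefix}{self._n}"

    def NOT(self, a: str, shared: bool = False) -> str:
        # shared=True memoizes the inverter so each signal is inverted once
        if shared and a in self._not_cache:
            return self._not_cache[a]
        gid = self.fresh("not")
        self.gates.append(Gate(gid, "NOT", (a,)))
        if shared:
            self._not_cache[a] = gid
        return gid

    def NOR(self, *srcs: str) -> str:
        gid = self.fresh("nor")
        self.gates.append(Gate(gid, "NOR", tuple(srcs)))
        return gid


def _mux2(b: _Builder, in1: str, in2: str, sel: str) -> str:
    """Minimal 2-input MUX: OUT = NOR(NOR(IN1, S), NOR(IN2, NOT S))."""
    nsel = b.NOT(sel)
    t1 = b.NOR(in1, sel)
    t2 = b.NOR(in2, nsel)
    return b.NOR(t1, t2)


def _demux2(b: _Builder, inp: str, sel: str) -> tuple[str, str]:
    """Minimal 2-output DEMUX: OUT1 = NOR(NOT IN, S), OUT2 = NOR(NOT IN, NOT S)."""
    ninp = b.NOT(inp)
    nsel = b.NOT(sel)
    return b.NOR(ninp, sel), b.NOR(ninp, nsel)


def _mux_two_layer(b: _Builder, ins: Sequence[str], sels: Sequence[str]) -> str:
    """Flat NOR-NOR (product-of-sums) MUX with wide gates.

    OUT = AND_i (IN_i or ~minterm_i(S)) = NOR_i( NOR(IN_i, literals) ) where
    the level-1 literals are the complements of minterm i's select literals.
    """
    k = len(sels)
    terms = []
    for i in range(len(ins)):
        lits = []
        for j in range(k):
            want = (i >> j) & 1  # minterm literal: S_j if bit set else ~S_j
            # complement of the minterm literal:
            lits.append(b.NOT(sels[j], shared=True) if want else sels[j])
        terms.append(b.NOR(ins[i], *lits))
    if len(terms) == 1:
        return b.NOT(terms[0])
    return b.NOR(*terms)


def _demux_two_layer(
    b: _Builder, inp: str, sels: Sequence[str]
) -> list[str]:
    """Flat DEMUX: OUT_i = NOR(~IN, complements of minterm_i literals)."""
    ninp = b.NOT(inp)
    k = len(sels)
    outs = []
    for i in range(2**k):
        lits = []
        for j in range(k):
            want = (i >> j) & 1
            lits.append(b.NOT(sels[j], shared=True) if want else sels[j])
        outs.append(b.NOR(ninp, *lits))
    return outs


def _mux_recursive(b: _Builder, ins: Sequence[str], sels: Sequence[str]) -> str:
    if len(ins) == 2:
        return _mux2(b, ins[0], ins[1], sels[0])
    half = len(ins) // 2
    lo = _mux_recursive(b, ins[:half], sels[:-1])
    hi = _mux_recursive(b, ins[half:], sels[:-1])
    return _mux2(b, lo, hi, sels[-1])


def _demux_recursive(b: _Builder, inp: str, sels: Sequence[str]) -> list[str]:
    if len(sels) == 1:
        return list(_demux2(b, inp, sels[0]))
    lo, hi = _demux2(b, inp, sels[-1])
    return _demux_recursive(b, lo, sels[:-1]) + _demux_recursive(b, hi, sels[:-1])


def build_cs_network(
    n_channels: int, style: str = "two_layer"
) -> tuple[GateNetwork, NetworkMetrics]:
    """Construct an n-channel channel selector (MUX wired into DEMUX).

    ``style`` selects the composition approach: ``"two_layer"`` builds each
    side as flat two-level NOR logic (wide gates, shallow), ``"recursive"``
    composes trees of the minimal 2-channel blocks (fan-in-2 gates, deep).
    For ``n_channels == 2`` both styles reduce to the same 8-gate design
    (3 NOT + 5 NOR).  ``n_channels == 1`` is a gateless pass-through.

    Returns the network together with its :class:`NetworkMetrics`, from
    which scaling laws (gates, layers, fan-in, fan-out versus channel
    count) can be read off constructively.
    """
    if n_channels < 1 or n_channels & (n_channels - 1):
        raise ValueError("n_channels must be a power of two")
    if style not in ("two_layer", "recursive"):
        raise ValueError(f"unknown style {style!r}")
    if n_channels == 1:
        net = GateNetwork(inputs=("IN1",), gates=(), outputs=("IN1",))
        return net, network_metrics(net)
    k = n_channels.bit_length() - 1
    ins = [f"IN{i + 1}" for i in range(n_channels)]
    sels = [f"SEL{j + 1}" for j in range(k)]
    b = _Builder(ins + sels)
    if style == "two_layer":
        wire = _mux_two_layer(b, ins, sels)
        b._not_cache.clear()  # DEMUX strain re-inverts its own select lines
        outs = _demux_two_layer(b, wire, sels)
    else:
        wire = _mux_recursive(b, ins, sels)
        outs = _demux_recursive(b, wire, sels)
    net = GateNetwork(inputs=b.inputs, gates=tuple(b.gates), outputs=tuple(outs))
    return net, network_metrics(net)
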