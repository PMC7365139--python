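"""Reference channel-selector circuit topologies and parameter sets.

The canonical 2-channel biological channel selector couples two strains:

* the sender strain carries the sensor-fronted MUX: an aTc sensor routed
  through NOT1 gives IN1, an IPTG sensor through an inverter gives IN2, a
  DAPG sensor through NOT4 gives SELECT; the MUX itself is NOR5/NOT2/
  NOR6*/NOR3, and OUT_MUX drives LuxI (the AHL sender);
* the receiver strain carries the AHL-fronted DEMUX: the LuxR-activated
  promoter (AHL receiver) feeds NOT8, a second DAPG sensor through NOT3
  gives the DEMUX SELECT, and NOR7/NOT9/NOR2 complete the routing to OUT1
  and OUT2.

The longest computation path runs DAPG sensor -> NOT4 -> NOT2 -> NOR6* ->
NOR3 -> AHL wire -> NOT8 -> NOR7: eight sequential layers, with the
sender/receiver pair of the AHL wire counting as a single layer.

The Hill parameter sets bundled here are synthetic, representative values
chosen to give digital behavior at the experimental inducer doses; the
published per-gate fit tables are not redistributed with this package, so
any quantitative prediction made with these defaults characterizes the
model structure, not the measured strains.
"""

from __future__ import annotations

from .circuit import AHL_SPECIES, AhlParams, CircuitNode, CircuitSpec, DEFAULT_K_PROD
from .gates import HillParams

__all__ = [
    "default_gate_params",
    "default_sensor_params",
    "default_receiver_params",
    "build_mux_circuit",
    "build_demux_circuit",
    "build_channel_selector",
    "signal_path_layers",
]

#: Saturating inducer doses used in the binary characterization assays.
INDUCER_HIGH = {"aTc": 20.0, "IPTG": 0.3, "DAPG": 100.0}  # ng/ml, mM, uM


def default_gate_params() -> HillParams:
    """Representative CRISPRi gate transfer function (synthetic stand-in)."""
    return HillParams(y_min=100.0, y_max=20000.0, K=2000.0, n=2.0, mode="repression")


def default_sensor_params(inducer: str) -> HillParams:
    """Representative sensor curves with K near mid-dose (synthetic stand-ins)."""
    table = {
        "aTc": HillParams(50.0, 15000.0, K=2.0, n=2.0, mode="activation"),
        "IPTG": HillParams(50.0, 15000.0, K=0.05, n=1.5, mode="activation"),
        "DAPG": HillParams(50.0, 15000.0, K=20.0, n=2.0, mode="activation"),
    }
    return table[inducer]


def default_receiver_params() -> HillParams:
    """Weakened LuxR-activated promoter (P_lux*-like, synthetic stand-in)."""
    return HillParams(y_min=80.0, y_max=9000.0, K=3.0, n=1.5, mode="activation")


def _gate(gid: str, kind: str, inputs: tuple[str, ...], p: HillParams) -> CircuitNode:
    return CircuitNode(gid, kind, inputs, p)


def build_mux_circuit(
    gate_params: HillParams | None = None,
    with_sensors: bool = True,
    with_ahl: bool = True,
    k_prod: float = DEFAULT_K_PROD,
) -> CircuitSpec:
    """Sensor-fronted MUX (the sender strain), optionally with the AHL sender.

    Without sensors, IN1/IN2/SELECT are direct sensor-like inputs named
    ``IN1``, ``IN2``, ``SELECT`` reading inducers of the same names (used
    for bare-MUX test circuits).
    """
    gp = gate_params or default_gate_params()
    nodes: list[CircuitNode] = []
    if with_sensors:
        nodes += [
            CircuitNode("aTc_sensor", "sensor", ("aTc",), default_sensor_params("aTc")),
            CircuitNode("IPTG_sensor", "sensor", ("IPTG",), default_sensor_params("IPTG")),
            CircuitNode("DAPG_sensor", "sensor", ("DAPG",), default_sensor_params("DAPG")),
            _gate("NOT1", "not_gate", ("aTc_sensor",), gp),      # IN1 = NOT(aTc)
            _gate("NOT5s", "not_gate", ("IPTG_sensor",), gp),    # IN2 = NOT(IPTG)
            _gate("NOT4", "not_gate", ("DAPG_sensor",), gp),     # SELECT = NOT(DAPG)
        ]
        in1, in2, sel = "NOT1", "NOT5s", "NOT4"
    else:
        nodes += [
            CircuitNode("IN1", "sensor", ("IN1",), default_sensor_params("aTc")),
            CircuitNode("IN2", "sensor", ("IN2",), default_sensor_params("aTc")),
            CircuitNode("SELECT", "sensor", ("SELECT",), default_sensor_params("aTc")),
        ]
        in1, in2, sel = "IN1", "IN2", "SELECT"
    nodes += [
        _gate("NOR5", "nor_gate", (in1, sel), gp),
        _gate("NOT2", "not_gate", (sel,), gp),
        _gate("NOR6", "nor_gate", (in2, "NOT2"), gp),
        _gate("NOR3", "nor_gate", ("NOR5", "NOR6"), gp),  # OUT_MUX
    ]
    if with_ahl:
        nodes.append(
            CircuitNode("LuxI", "ahl_sender", ("NOR3",), AhlParams(k_prod=k_prod))
        )
    strain = {n.id: "sender" for n in nodes}
    return CircuitSpec(tuple(nodes), strain)


def build_demux_circuit(
    gate_params: HillParams | None = None,
    with_sensors: bool = True,
) -> CircuitSpec:
    """AHL-fronted DEMUX (the receiver strain).

    With sensors, IN_DEMUX comes from the AHL receiver and SELECT from a
    DAPG sensor routed through NOT3; without, ``IN`` and ``SELECT`` are
    direct inputs (bare-DEMUX test circuits).
    """
    gp = gate_params or default_gate_params()
    nodes: list[CircuitNode] = []
    if with_sensors:
        nodes += [
            CircuitNode("AHL_receiver", "ahl_receiver", (AHL_SPECIES,), default_receiver_params()),
            CircuitNode("DAPG_sensor2", "sensor", ("DAPG",), default_sensor_params("DAPG")),
            _gate("NOT3", "not_gate", ("DAPG_sensor2",), gp),  # DEMUX SELECT
        ]
        ind, sel = "AHL_receiver", "NOT3"
    else:
        nodes += [
            CircuitNode("IN", "sensor", ("IN",), default_sensor_params("aTc")),
            CircuitNode("SELECT", "sensor", ("SELECT",), default_sensor_params("aTc")),
        ]
        ind, sel = "IN", "SELECT"
    nodes += [
        _gate("NOT8", "not_gate", (ind,), gp),
        _gate("NOR7", "nor_gate", ("NOT8", sel), gp),   # OUT1 (high when SELECT low)
        _gate("NOT9", "not_gate", (sel,), gp),
        _gate("NOR2", "nor_gate", ("NOT8", "NOT9"), gp),  # OUT2 (high when SELECT high)
    ]
    strain = {n.id: "receiver" for n in nodes}
    return CircuitSpec(tuple(nodes), strain)


def build_channel_selector(
    gate_params: HillParams | None = None,
    k_prod: float = DEFAULT_K_PROD,
) -> CircuitSpec:
    """Full two-strain channel selector: sensor-MUX-AHL + AHL-DEMUX co-culture."""
    mux = build_mux_circuit(gate_params, with_sensors=True, with_ahl=True, k_prod=k_prod)
    demux = build_demux_circuit(gate_params, with_sensors=True)
    strain = {**dict(mux.strain_of), **dict(demux.strain_of)}
    return CircuitSpec(mux.nodes + demux.nodes, strain)


def signal_path_layers(c: CircuitSpec) -> int:
    """Longest computation path through the circuit, in sequential layers.

    Sensors, gates, and the AHL communication step each count as one
    layer; the sender/receiver pair of the AHL wire is a single layer
    (one communication event), and reporters are transparent.
    """
    import networkx as nx

    g = c.graph()
    # fuse the sender -> AHL -> receiver chain into one layer: sender and
    # AHL species are zero-weight, the receiver carries the single count.
    weight = {}
    for n in c.nodes:
        if n.role in ("reporter", "ahl_sender"):
            weight[n.id] = 0
        else:
            weight[n.id] = 1
    weight[AHL_SPECIES] = 0
    best: dict[str, int] = {}
    for nid in nx.topological_sort(g):
        preds = list(g.predecessors(nid))
        base = max((best[p] for p in preds), default=0)
        best[nid] = base + weight.get(nid, 0)
    return max(best.values(), default=0)
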