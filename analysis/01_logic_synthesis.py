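"""Synthesize the minimal MUX/DEMUX gate networks and tabulate CS scaling.

Exhaustive iterative-deepening search over NOT/NOR networks confirms the
minimal designs (MUX: 1 NOT + 3 NOR in 3 layers; DEMUX: 2 NOT + 2 NOR in
2 layers under the terminal-output convention), then builds n-channel
channel selectors in both composition styles and records their
constructive scaling metrics.

Writes results/logic_minimal.json and results/cs_scaling.csv.
"""

import json
from pathlib import Path

import pandas as pd

from csmux.io import network_to_json
from csmux.logic import (
    build_cs_network,
    demux_truth_table,
    mux_truth_table,
    network_metrics,
    synthesize_minimal,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    report = {}
    for name, tt in [("mux", mux_truth_table()), ("demux", demux_truth_table())]:
        net = synthesize_minimal(tt, gate_budget=5)
        m = network_metrics(net)
        report[name] = {
            "n_not": m.n_not,
            "n_nor": m.n_nor,
            "layers": m.depth,
            "network": json.loads(network_to_json(net)),
        }
        print(f"{name.upper()}: minimal = {m.n_not} NOT + {m.n_nor} NOR in {m.depth} layers")
    (OUT / "logic_minimal.json").write_text(json.dumps(report, indent=2))

    rows = []
    for style in ("two_layer", "recursive"):
        for n in (1, 2, 4, 8):
            _, m = build_cs_network(n, style)
            rows.append(
                {
                    "style": style,
                    "channels": n,
                    "gates": m.n_gates,
                    "n_not": m.n_not,
                    "n_nor": m.n_nor,
                    "layers": m.depth,
                    "max_fan_in": m.max_fan_in,
                    "max_fan_out": m.max_fan_out,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "cs_scaling.csv", index=False)
    print("\nChannel-selector scaling (constructive counts):")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
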