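"""Serialization: CSV tables, JSON reports, FASTA/BED/GFF genome inputs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .gates import FitResult, HillParams, TransferDataset
from .guides import GenomeTarget
from .logic import Gate, GateNetwork, TruthTable

__all__ = [
    "read_transfer_csv",
    "write_transfer_csv",
    "fit_result_to_json",
    "read_genome_target",
    "truth_table_from_json",
    "network_to_json",
]


def read_transfer_csv(path) -> TransferDataset:
    """Columns: input, input_units, mean_output_mefl, optional sem."""
    df = pd.read_csv(path)
    units = str(df["input_units"].iloc[0]) if "input_units" in df else "MEFL"
    sem = tuple(df["sem"]) if "sem" in df and df["sem"].notna().all() else None
    return TransferDataset(
        x=tuple(df["input"]), y=tuple(df["mean_output_mefl"]), sem=sem, input_units=units
    )


def write_transfer_csv(d: TransferDataset, path) -> None:
    df = pd.DataFrame(
        {
            "input": d.x,
            "input_units": d.input_units,
            "mean_output_mefl": d.y,
            "sem": d.sem if d.sem is not None else float("nan"),
        }
    )
    df.to_csv(path, index=False)


def fit_result_to_json(fr: FitResult) -> str:
    payload = {
        "params": dataclasses.asdict(fr.params),
        "rmse_decades": fr.rmse_decades,
        "constrained": fr.constrained,
        "unidentifiable": fr.unidentifiable,
        "aic": fr.aic,
    }
    return json.dumps(payload, indent=2)


def _read_bed(path) -> list[tuple[int, int, str]]:
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) > 5 else "."
            feats.append((int(parts[1]), int(parts[2]), strand))
    return feats


def _read_gff3(path) -> list[tuple[int, int, str]]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                continue
            # GFF is 1-based inclusive -> 0-based half-open
            feats.append((int(parts[3]) - 1, int(parts[4]), parts[6]))
    return feats


def read_genome_target(fasta_path, features_path=None) -> GenomeTarget:
    """Load a genome FASTA (first record) and essential features (BED or GFF3)."""
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    feats: list[tuple[int, int, str]] = []
    if features_path is not None:
        suffix = Path(features_path).suffix.lower()
        feats = _read_gff3(features_path) if suffix in (".gff", ".gff3") else _read_bed(
            features_path
        )
    return GenomeTarget(genome=str(record.seq).upper(), essential_features=tuple(feats))


def truth_table_from_json(path) -> TruthTable:
    """JSON schema: {n_inputs, n_outputs, rows: [[...], ...], input_names?, output_names?}."""
    with open(path) as fh:
        obj = json.load(fh)
    return TruthTable(
        n_inputs=obj["n_inputs"],
        n_outputs=obj["n_outputs"],
        rows=tuple(tuple(r) for r in obj["rows"]),
        input_names=tuple(obj.get("input_names", ())),
        output_names=tuple(obj.get("output_names", ())),
    )


def network_to_json(net: GateNetwork) -> str:
    return json.dumps(
        {
            "inputs": list(net.inputs),
            "gates": [
                {"id": g.id, "kind": g.kind, "inputs": list(g.inputs)}
                for g in net.topological_gates()
            ],
            "outputs": list(net.outputs),
        },
        indent=2,
    )
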