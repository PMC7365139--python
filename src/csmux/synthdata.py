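"""Synthetic flow-cytometry and transfer-function data generators.

Single-cell fluorescence of a clonal bacterial population in calibrated
MEFL units is modeled as an additive autofluorescence background plus a
log-normal signal component, matching the decade-spanning, roughly
log-symmetric distributions seen in calibrated cytometry.  Two-strain
co-cultures are separable on the FL3 (red, MECY) channel, and FSC/SSC are
correlated log-normal nuisance channels that exist solely to exercise
density gating -- there is no optics model.

These generators close the loop with the estimators: a transfer dataset
generated from known Hill parameters should be recovered by
:func:`csmux.gates.fit_transfer_function`, a synthetic sender/receiver
series by :func:`csmux.circuit.estimate_ahl_rate`, and a synthetic
co-culture by FL3 classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gates import HillParams, TransferDataset, not_response, sensor_response

__all__ = [
    "PopulationSpec",
    "CytometrySample",
    "sample_population",
    "generate_transfer_dataset",
    "generate_coculture_sample",
    "generate_orthogonality_panel",
    "ATC_GRID_NG_ML",
]

#: aTc dose grid used for NOT-gate transfer functions (ng/ml).
ATC_GRID_NG_ML = (0.0, 1.0, 1.5, 2.0, 3.0, 4.0, 20.0)

#: Sensor dose grids (10 points each) used for sensor transfer functions.
SENSOR_GRIDS = {
    "aTc": (0.0, 0.5, 0.793, 1.26, 1.99, 3.16, 5.01, 7.95, 12.6, 20.0),
    "IPTG": (0.0, 0.0090, 0.0216, 0.0520, 0.125, 0.3, 0.721, 1.73, 4.16, 10.0),
    "DAPG": (0.0, 2.33, 4.36, 8.16, 15.3, 28.6, 53.5, 100.0, 187.0, 350.0),
    "AHL": (0.0, 0.1, 0.237, 0.562, 1.33, 3.16, 7.50, 17.8, 42.2, 100.0),
}


@dataclass(frozen=True)
class PopulationSpec:
    """One log-normal fluorescent population.

    ``log10_mean`` of None means no expressed signal (autofluorescence
    only).  Defaults: 0.2-decade spread, 20,000 events, autofluorescence
    around 100 MEFL -- fixture choices representative of calibrated
    E. coli cytometry, not published population statistics.
    """

    log10_mean: float | None
    log10_sd: float = 0.2
    autofluorescence_mean: float = 100.0
    fl3_log10_mean: float = 1.0
    n_events: int = 20000

    def __post_init__(self) -> None:
        if self.log10_sd <= 0:
            raise ValueError("log10_sd must be > 0")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


@dataclass
class CytometrySample:
    """Event-level fluorescence table with optional true strain labels."""

    events: pd.DataFrame  # columns FL1, FL3, FSC, SSC
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        required = {"FL1", "FL3", "FSC", "SSC"}
        if not required <= set(self.events.columns):
            raise ValueError(f"events table needs columns {sorted(required)}")
        if (self.events[sorted(required)] <= 0).any().any():
            raise ValueError("all channels must be positive")
        if self.labels is not None and len(self.labels) != len(self.events):
            raise ValueError("labels length must equal event count")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_population(spec: PopulationSpec, seed: int | np.random.Generator = 0) -> CytometrySample:
    """Draw one population: FL1 = autofluorescence + log-normal signal."""
    rng = _rng(seed)
    n = spec.n_events
    auto = 10 ** rng.normal(np.log10(spec.autofluorescence_mean), 0.1, size=n)
    if spec.log10_mean is not None:
        signal = 10 ** rng.normal(spec.log10_mean, spec.log10_sd, size=n)
    else:
        signal = 0.0
    fl1 = auto + signal
    fl3 = 10 ** rng.normal(spec.fl3_log10_mean, spec.log10_sd, size=n)
    # correlated scatter channels (shared size factor)
    size = rng.normal(0.0, 0.1, size=n)
    fsc = 10 ** (2.0 + size + rng.normal(0.0, 0.08, size=n))
    ssc = 10 ** (2.0 + 0.8 * size + rng.normal(0.0, 0.08, size=n))
    return CytometrySample(
        events=pd.DataFrame({"FL1": fl1, "FL3": fl3, "FSC": fsc, "SSC": ssc})
    )


def generate_transfer_dataset(
    true_params: HillParams,
    input_grid: Sequence[float] = ATC_GRID_NG_ML,
    noise_sd_decades: float = 0.05,
    replicates: int = 3,
    seed: int | np.random.Generator = 0,
) -> TransferDataset:
    """Simulate a replicate-averaged transfer-function measurement.

    Each replicate perturbs the true Hill response with multiplicative
    log-normal noise of the given decade-scale sd; replicates are averaged
    in linear MEFL, mirroring replicate-averaged mean fluorescence.
    """
    rng = _rng(seed)
    x = np.asarray(input_grid, dtype=float)
    model = (
        sensor_response(x, true_params)
        if true_params.mode == "activation"
        else not_response(x, true_params)
    )
    if noise_sd_decades == 0:
        y = np.asarray(model, dtype=float)
        sem = np.zeros_like(y)
    else:
        reps = model * 10 ** rng.normal(0.0, noise_sd_decades, size=(replicates, len(x)))
        y = reps.mean(axis=0)
        sem = reps.std(axis=0, ddof=1) / np.sqrt(replicates)
    return TransferDataset(
        x=tuple(x), y=tuple(y), sem=tuple(sem), input_units="MEFL"
    )


def generate_coculture_sample(
    spec_a: PopulationSpec,
    spec_b: PopulationSpec,
    ratio: float = 10.0,
    n_events: int = 22000,
    seed: int | np.random.Generator = 0,
) -> CytometrySample:
    """Mix two strains at an expected a:b event ratio, keeping true labels.

    The default 10:1 ratio matches the sender-heavy co-culture inoculation;
    strain identity is a per-event Bernoulli draw, so realized counts vary
    binomially.  FL3 separation comes from the two specs' fl3 means.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    rng = _rng(seed)
    p_a = 1.0 if np.isinf(ratio) else ratio / (ratio + 1.0)
    is_a = rng.random(n_events) < p_a
    n_a = int(is_a.sum())
    sa = sample_population(
        PopulationSpec(
            spec_a.log10_mean, spec_a.log10_sd, spec_a.autofluorescence_mean,
            spec_a.fl3_log10_mean, max(n_a, 1),
        ),
        rng,
    )
    sb = sample_population(
        PopulationSpec(
            spec_b.log10_mean, spec_b.log10_sd, spec_b.autofluorescence_mean,
            spec_b.fl3_log10_mean, max(n_events - n_a, 1),
        ),
        rng,
    )
    frames, labels = [], []
    if n_a > 0:
        frames.append(sa.events.iloc[:n_a])
        labels += ["a"] * n_a
    if n_events - n_a > 0:
        frames.append(sb.events.iloc[: n_events - n_a])
        labels += ["b"] * (n_events - n_a)
    events = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(events))
    events = events.iloc[order].reset_index(drop=True)
    lab = pd.Series(np.asarray(labels)[order], name="strain")
    return CytometrySample(events=events, labels=lab)


def generate_orthogonality_panel(
    n_pairs: int = 9,
    on_target_fold: float = 100.0,
    off_target_fold: float = 1.0,
    noise_sd_decades: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """All-by-all sgRNA x promoter repression-fold table (one strain per cell).

    Diagonal (cognate) entries scatter around ``on_target_fold``,
    off-diagonal entries around ``off_target_fold`` (~1, no cross-talk),
    with multiplicative log-normal noise.
    """
    if on_target_fold <= 0 or off_target_fold <= 0:
        raise ValueError("fold changes must be > 0")
    rng = _rng(seed)
    base = np.full((n_pairs, n_pairs), off_target_fold, dtype=float)
    np.fill_diagonal(base, on_target_fold)
    noisy = base * 10 ** rng.normal(0.0, noise_sd_decades, size=base.shape) \
        if noise_sd_decades > 0 else base
    idx = [f"S{i + 1}" for i in range(n_pairs)]
    cols = [f"P{i + 1}" for i in range(n_pairs)]
    return pd.DataFrame(noisy, index=idx, columns=cols)
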