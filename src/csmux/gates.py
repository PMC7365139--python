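"""Hill transfer-function models for CRISPRi gates and small-molecule sensors.

Every signal in the circuit is expressed in reporter-equivalent MEFL
(molecules of equivalent fluorescein), the bead-calibrated unit in which
each promoter's activity is probed.  A NOT gate maps the MEFL of its input
promoter to the MEFL of its output promoter through a repressive Hill
curve; a NOR gate sums the transcriptional flux of its two input promoters
before the same nonlinearity (both promoters transcribe the same sgRNA
species, driving a single repressor pool); a chemical sensor maps inducer
concentration to output MEFL through an activating Hill curve.

Fitting is performed on log10 fluorescence, since measured outputs span
several decades, with multi-start initialization of the half-maximal
constant K and box bounds on all parameters.  The fit error is reported as
an RMSE in MEFL decades, the same metric used to score circuit-level
predictions (see :mod:`csmux.evaluate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HillParams",
    "TransferDataset",
    "FitResult",
    "not_response",
    "nor_response",
    "sensor_response",
    "fit_transfer_function",
    "compare_fits",
]


@dataclass(frozen=True)
class HillParams:
    """Parameters of one repressive or activating Hill transfer function.

    y_min, y_max : MEFL
        Floor (fully repressed / uninduced) and ceiling (fully active)
        output.  y_min includes cellular autofluorescence, so it is
        strictly positive for any measured promoter.
    K : MEFL (repression) or inducer units (activation)
        Input at which the output sits halfway between y_min and y_max.
    n : dimensionless
        Hill coefficient (cooperativity / apparent ultrasensitivity).
    """

    y_min: float
    y_max: float
    K: float
    n: float
    mode: str = "repression"  # "repression" | "activation"

    def __post_init__(self) -> None:
        if not (0 <= self.y_min <= self.y_max):
            raise ValueError("require 0 <= y_min <= y_max")
        if self.y_min == self.y_max:
            # degenerate (unidentifiable) params are allowed as fit output
            pass
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if self.n <= 0:
            raise ValueError("Hill coefficient n must be > 0")
        if self.mode not in ("repression", "activation"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class TransferDataset:
    """Measured (or simulated) transfer-function data.

    ``x`` is input MEFL for gates or inducer concentration for sensors
    (units recorded in ``input_units``); ``y`` is mean output MEFL.
    """

    x: tuple[float, ...]
    y: tuple[float, ...]
    sem: tuple[float, ...] | None = None
    input_units: str = "MEFL"

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if self.sem is not None and len(self.sem) != len(self.y):
            raise ValueError("sem length mismatch")
        if any(v < 0 for v in self.x):
            raise ValueError("inputs must be non-negative")
        if any(v <= 0 for v in self.y):
            raise ValueError("outputs must be positive (autofluorescence floor)")


@dataclass(frozen=True)
class FitResult:
    params: HillParams
    rmse_decades: float
    constrained: bool
    unidentifiable: bool = False
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.rmse_decades < 0:
            raise ValueError("rmse_decades must be >= 0")

    @property
    def aic(self) -> float:
        """Akaike information criterion on the log10-space Gaussian residuals."""
        n = self.n_points
        k = 3 if self.constrained else 4
        rss = self.rmse_decades**2 * n
        if n == 0:
            return math.nan
        return n * math.log(max(rss / n, 1e-300)) + 2 * k


def _hill_fraction(x, K: float, n: float):
    """(x/K)^n / (1 + (x/K)^n), numerically safe for x = 0 and large x."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        t = (x / K) ** n
        return np.where(np.isinf(t), 1.0, t / (1.0 + t))


def not_response(x, p: HillParams):
    """Repressive Hill curve: y_min + (y_max - y_min) / (1 + (x/K)^n).

    Monotone non-increasing in x; equals y_max at x = 0 and approaches
    y_min as x grows.
    """
    if p.mode != "repression":
        raise ValueError("not_response requires repression-mode params")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("input MEFL must be non-negative")
    y = p.y_min + (p.y_max - p.y_min) * (1.0 - _hill_fraction(x_arr, p.K, p.n))
    return float(y) if np.isscalar(x) else y


def nor_response(x1, x2, p: HillParams):
    """Two-input NOR: the repressive Hill curve of the summed input flux.

    Both input promoters transcribe the same sgRNA, so their fluxes add
    before repression; the response is symmetric and reduces to
    :func:`not_response` when one input is silent.
    """
    x1_arr = np.asarray(x1, dtype=float)
    x2_arr = np.asarray(x2, dtype=float)
    if np.any(x1_arr < 0) or np.any(x2_arr < 0):
        raise ValueError("input MEFL must be non-negative")
    total = x1_arr + x2_arr
    y = not_response(total, p)
    return float(y) if (np.isscalar(x1) and np.isscalar(x2)) else y


def sensor_response(c, p: HillParams):
    """Activating Hill curve: y_min + (y_max - y_min) * (c/K)^n / (1 + (c/K)^n)."""
    if p.mode != "activation":
        raise ValueError("sensor_response requires activation-mode params")
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("inducer concentration must be non-negative")
    y = p.y_min + (p.y_max - p.y_min) * _hill_fraction(c_arr, p.K, p.n)
    return float(y) if np.isscalar(c) else y


def _model(x, p: HillParams):
    return sensor_response(x, p) if p.mode == "activation" else not_response(x, p)


def _rmse_decades(y_pred, y_obs) -> float:
    r = np.log10(y_pred) - np.log10(y_obs)
    return float(np.sqrt(np.mean(r**2)))


def fit_transfer_function(
    d: TransferDataset,
    constrain_n: bool = False,
    mode: str = "repression",
    autofluorescence_floor: float = 1.0,
    x0: HillParams | None = None,
) -> FitResult:
    """Least-squares Hill fit of log10(model) to log10(y).

    Parameters are bounded: y_min in [autofluorescence floor, min(y)],
    y_max in [max(y), 10 max(y)], n in [0.5, 4]; K is multi-started at the
    quantiles of the positive inputs to avoid local minima.  With
    ``constrain_n`` the Hill coefficient is pinned at 1 (the constrained
    model of the CRISPRi literature); ``x0`` optionally seeds one extra
    start, which lets a nested unconstrained fit start from the
    constrained optimum and guarantees it never scores worse.

    Degenerate data (all outputs equal) yield a flat fit with K and n
    flagged unidentifiable.
    """
    x = np.asarray(d.x, dtype=float)
    y = np.asarray(d.y, dtype=float)
    n_pts = len(x)
    if n_pts < 2:
        raise ValueError("need at least two data points")
    if float(np.ptp(np.log10(y))) < 1e-12:
        flat = float(y[0])
        return FitResult(
            params=HillParams(flat, flat, 1.0, 1.0, mode=mode),
            rmse_decades=0.0,
            constrained=constrain_n,
            unidentifiable=True,
            n_points=n_pts,
        )
    lo_ymin = min(autofluorescence_floor, float(y.min()))
    bounds_lo = [math.log10(lo_ymin), math.log10(y.max())]
    bounds_hi = [math.log10(y.min()) + 1e-9, math.log10(10 * y.max())]
    xpos = x[x > 0]
    k_starts = np.quantile(xpos, [0.1, 0.25, 0.5, 0.75, 0.9]) if len(xpos) else [1.0]
    logy = np.log10(y)

    def residuals(theta):
        ly_min, ly_max, lK = theta[0], theta[1], theta[2]
        nn = 1.0 if constrain_n else theta[3]
        p = HillParams(10**ly_min, 10**ly_max, 10**lK, nn, mode=mode)
        return np.log10(_model(x, p)) - logy

    lo = bounds_lo + [math.log10(max(xpos.min(), 1e-12)) - 2 if len(xpos) else -6]
    hi = bounds_hi + [math.log10(xpos.max()) + 2 if len(xpos) else 6]
    if not constrain_n:
        lo.append(0.5)
        hi.append(4.0)

    starts = []
    for K0 in np.atleast_1d(k_starts):
        s = [math.log10(y.min()), math.log10(y.max()), math.log10(max(K0, 1e-12))]
        if not constrain_n:
            s.append(1.0)
        starts.append(s)
    if x0 is not None:
        s = [
            math.log10(max(x0.y_min, lo_ymin)),
            math.log10(max(x0.y_max, y.max())),
            math.log10(x0.K),
        ]
        if not constrain_n:
            s.append(min(max(x0.n, 0.5), 4.0))
        starts.append(s)

    best = None
    for s in starts:
        s = [min(max(v, l), h) for v, l, h in zip(s, lo, hi)]
        sol = least_squares(residuals, s, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    theta = best.x
    nn = 1.0 if constrain_n else float(theta[3])
    p = HillParams(10 ** theta[0], 10 ** theta[1], 10 ** theta[2], nn, mode=mode)
    return FitResult(
        params=p,
        rmse_decades=_rmse_decades(_model(x, p), y),
        constrained=constrain_n,
        n_points=n_pts,
    )


def compare_fits(
    d: TransferDataset, mode: str = "repression", autofluorescence_floor: float = 1.0
) -> dict[str, FitResult]:
    """Fit both the constrained (n = 1) and unconstrained Hill models.

    The unconstrained fit is additionally seeded from the constrained
    optimum, so its RMSE is never larger (model nesting).  Both results
    are returned with their AICs available, leaving the preference rule
    to the caller.
    """
    constrained = fit_transfer_function(
        d, constrain_n=True, mode=mode, autofluorescence_floor=autofluorescence_floor
    )
    unconstrained = fit_transfer_function(
        d,
        constrain_n=False,
        mode=mode,
        autofluorescence_floor=autofluorescence_floor,
        x0=constrained.params,
    )
    return {"constrained": constrained, "unconstrained": unconstrained}
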