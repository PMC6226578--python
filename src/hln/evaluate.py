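"""Model assessment and membrane-potential summary statistics.

Model accuracy is the cross-validated fraction of variance explained,

    VE = 1 - MSE(v, vhat) / Var(v),

computed per held-out segment.  The module also provides the three summary
statistics used to calibrate synthetic inputs against dendritic recordings:
plateau probability (fraction of time above a voltage threshold),
autocorrelation decay timescale, and the membrane-potential histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "EvalReport",
    "variance_explained",
    "plateau_probability",
    "normalized_autocorrelation",
    "autocorrelation_timescale",
    "vm_histogram",
    "evaluate",
]

PLATEAU_THRESHOLD_MV = -35.0


def variance_explained(v: np.ndarray, vhat: np.ndarray) -> float:
    """Fraction of variance of ``v`` explained by the prediction ``vhat``.

    Equals 1 for a perfect prediction, 0 for predicting the mean, and is
    negative for predictions worse than the mean.
    """
    v = np.asarray(v, dtype=float)
    vhat = np.asarray(vhat, dtype=float)
    if v.shape != vhat.shape:
        raise ValueError("traces must share one grid")
    var = float(np.var(v))
    if var == 0:
        raise ValueError("target trace has zero variance")
    return 1.0 - float(np.mean((v - vhat) ** 2)) / var


def plateau_probability(vm: np.ndarray, threshold_mv: float = PLATEAU_THRESHOLD_MV) -> float:
    """Fraction of time bins with membrane potential strictly above the
    plateau threshold (default -35 mV)."""
    vm = np.asarray(vm, dtype=float)
    return float(np.mean(vm > threshold_mv))


def normalized_autocorrelation(vm: np.ndarray, max_lag_bins: int) -> np.ndarray:
    """Autocorrelation of the mean-subtracted trace for lags 0..max_lag,
    normalized to 1 at lag zero."""
    vm = np.asarray(vm, dtype=float)
    x = vm - vm.mean()
    n = x.shape[0]
    if max_lag_bins >= n:
        raise ValueError("max_lag must be shorter than the trace")
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("trace has zero variance")
    ac = np.array([np.dot(x[: n - k], x[k:]) for k in range(max_lag_bins + 1)])
    return ac / denom


def autocorrelation_timescale(
    vm: np.ndarray,
    dt: float = 1.0,
    max_lag_ms: float = 500.0,
    n_segments: int = 1,
) -> float:
    """Exponential decay constant (ms) of the voltage autocorrelation.

    The normalized autocorrelation is computed per segment and averaged,
    then a single exponential ``exp(-lag/tau)`` is fitted by least squares
    over lags 0..max_lag.
    """
    vm = np.asarray(vm, dtype=float)
    max_lag_bins = int(round(max_lag_ms / dt))
    seg_len = vm.shape[0] // n_segments
    if seg_len <= 2 * max_lag_bins:
        raise ValueError("trace too short for the requested max_lag")
    acs = [
        normalized_autocorrelation(vm[i * seg_len : (i + 1) * seg_len], max_lag_bins)
        for i in range(n_segments)
    ]
    ac = np.mean(acs, axis=0)
    lags = np.arange(max_lag_bins + 1) * dt
    (tau,), _ = curve_fit(
        lambda t, tau: np.exp(-t / tau), lags, ac, p0=[max_lag_ms / 5.0],
        bounds=(dt * 1e-3, max_lag_ms * 100),
    )
    return float(tau)


def vm_histogram(
    vm: np.ndarray, bin_width_mv: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized density histogram of the membrane potential.

    Returns (bin edges, densities); densities integrate to 1.
    """
    if bin_width_mv <= 0:
        raise ValueError("bin width must be positive")
    vm = np.asarray(vm, dtype=float)
    lo = np.floor(vm.min() / bin_width_mv) * bin_width_mv
    hi = np.ceil(vm.max() / bin_width_mv) * bin_width_mv
    if hi <= lo:
        hi = lo + bin_width_mv
    edges = np.arange(lo, hi + bin_width_mv / 2, bin_width_mv)
    dens, edges = np.histogram(vm, bins=edges, density=True)
    return edges, dens


@dataclass
class EvalReport:
    """Per-segment accuracy plus membrane-potential summary statistics."""

    variance_explained: list[float]
    plateau_probability: float
    autocorrelation_timescale_ms: float | None
    vm_hist_edges: np.ndarray = field(repr=False)
    vm_hist_density: np.ndarray = field(repr=False)

    @property
    def median_ve(self) -> float:
        return float(np.median(self.variance_explained))

    @property
    def ve_quartiles(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.variance_explained, [25, 75])
        return float(q1), float(q3)

    def to_dict(self) -> dict:
        return {
            "variance_explained": [float(x) for x in self.variance_explained],
            "median_ve": self.median_ve,
            "ve_quartiles": list(self.ve_quartiles),
            "plateau_probability": self.plateau_probability,
            "autocorrelation_timescale_ms": self.autocorrelation_timescale_ms,
            "vm_hist_edges": self.vm_hist_edges.tolist(),
            "vm_hist_density": self.vm_hist_density.tolist(),
        }


def evaluate(
    predictions: list[np.ndarray],
    targets: list[np.ndarray],
    dt: float = 1.0,
    plateau_threshold_mv: float = PLATEAU_THRESHOLD_MV,
    ac_max_lag_ms: float = 500.0,
    hist_bin_width_mv: float = 1.0,
) -> EvalReport:
    """Evaluate model predictions on held-out segments.

    ``predictions`` and ``targets`` are parallel lists of per-segment
    traces (the segments must be disjoint held-out data).  Variance
    explained is computed per segment; the summary statistics are computed
    on the concatenated target trace.
    """
    if len(predictions) != len(targets) or not targets:
        raise ValueError("need equally many prediction and target segments")
    ves = [variance_explained(t, p) for p, t in zip(predictions, targets)]
    vm = np.concatenate(targets)
    try:
        tau = autocorrelation_timescale(vm, dt=dt, max_lag_ms=ac_max_lag_ms)
    except (ValueError, RuntimeError):
        tau = None
    edges, dens = vm_histogram(vm, hist_bin_width_mv)
    return EvalReport(
        variance_explained=ves,
        plateau_probability=plateau_probability(vm, plateau_threshold_mv),
        autocorrelation_timescale_ms=tau,
        vm_hist_edges=edges,
        vm_hist_density=dens,
    )
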