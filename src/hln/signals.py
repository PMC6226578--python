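"""Time discretization, spike trains, synaptic kernels, and spike-to-signal convolution.

The hLN model is evaluated in discrete time on a uniform grid (default
``dt = 1`` ms).  Presynaptic spike trains are binned to the grid and
convolved with alpha-function synaptic kernels; all downstream model
evaluation works on the resulting per-group filtered signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "TimeGrid",
    "SpikeTrain",
    "SpikeTrainSet",
    "KernelParams",
    "TAU_SLOW_OFFSET",
    "TAU_SLOW_SLOPE",
    "coupled_tau_slow",
    "alpha_kernel",
    "alpha_kernel_dtau",
    "build_kernel",
    "bin_spikes",
    "convolve_spikes",
    "convolve_counts",
]

# Empirical linear coupling between the slow and fast kernel time constants,
# tau_slow = 10.4 + 2.8 * tau_fast (ms).
TAU_SLOW_OFFSET = 10.4
TAU_SLOW_SLOPE = 2.8

#: Kernel support is truncated at this multiple of the largest time constant;
#: the discarded alpha-function tail then holds < 1e-3 of the kernel mass.
DEFAULT_SUPPORT_FACTOR = 10.0


def coupled_tau_slow(tau_fast: float) -> float:
    """Slow time constant implied by the fast one in coupled-kernel mode (ms)."""
    return TAU_SLOW_OFFSET + TAU_SLOW_SLOPE * tau_fast


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid; bin ``k`` spans ``[t0 + k*dt, t0 + (k+1)*dt)``.

    Parameters
    ----------
    dt : float
        Bin width in ms (> 0).
    n_bins : int
        Number of bins (>= 1).
    t0 : float
        Start time in ms.
    """

    dt: float = 1.0
    n_bins: int = 1
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")

    @property
    def duration(self) -> float:
        """Total span in ms."""
        return self.n_bins * self.dt

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        """Bin-center times (ms)."""
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.dt

    def edges(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_bins + 1) * self.dt

    @classmethod
    def from_duration(cls, duration_ms: float, dt: float = 1.0, t0: float = 0.0) -> "TimeGrid":
        n = int(round(duration_ms / dt))
        return cls(dt=dt, n_bins=max(n, 1), t0=t0)


@dataclass
class SpikeTrain:
    """Event times of one presynaptic input.

    times are in ms and kept sorted; ``label`` is ``"excitatory"`` or
    ``"inhibitory"``; ``ensemble_id`` tags which input ensemble (shared rate
    process) the synapse belongs to.
    """

    times: np.ndarray
    label: str = "excitatory"
    ensemble_id: int = 0

    VALID_LABELS = ("excitatory", "inhibitory")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.label not in self.VALID_LABELS:
            raise ValueError(f"label must be one of {self.VALID_LABELS}, got {self.label!r}")
        if self.times.size and np.any(np.diff(self.times) < 0):
            self.times = np.sort(self.times)

    def __len__(self) -> int:
        return self.times.size

    @property
    def is_excitatory(self) -> bool:
        return self.label == "excitatory"


@dataclass
class SpikeTrainSet:
    """Collection of per-synapse spike trains keyed by integer synapse id."""

    trains: dict[int, SpikeTrain] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trains)

    def __getitem__(self, synapse_id: int) -> SpikeTrain:
        return self.trains[synapse_id]

    def __iter__(self):
        return iter(sorted(self.trains))

    def items(self):
        return ((sid, self.trains[sid]) for sid in sorted(self.trains))

    def add(self, synapse_id: int, train: SpikeTrain) -> None:
        self.trains[synapse_id] = train

    def synapse_ids(self) -> list[int]:
        return sorted(self.trains)

    def excitatory_ids(self) -> list[int]:
        return [sid for sid, tr in self.items() if tr.is_excitatory]

    def inhibitory_ids(self) -> list[int]:
        return [sid for sid, tr in self.items() if not tr.is_excitatory]

    def n_spikes(self) -> int:
        return sum(len(tr) for tr in self.trains.values())


@dataclass
class KernelParams:
    """Parameters of one synaptic kernel (a single alpha function or a
    fast+slow mixture of two).

    w_fast, w_slow : amplitudes (mV per spike; negative for inhibition)
    tau_fast, tau_slow : time constants (ms); when ``tau_slow`` is None and
        ``w_slow`` is set, the slow time constant is coupled to the fast one
        via ``tau_slow = 10.4 + 2.8 * tau_fast``.
    delay : axonal/synaptic propagation delay (ms, >= 0), rounded to the
        nearest grid bin when sampled.
    """

    w_fast: float
    tau_fast: float
    delay: float = 0.0
    w_slow: float | None = None
    tau_slow: float | None = None

    def __post_init__(self) -> None:
        if self.tau_fast <= 0:
            raise ValueError(f"tau_fast must be positive, got {self.tau_fast}")
        if self.tau_slow is not None and self.tau_slow <= 0:
            raise ValueError(f"tau_slow must be positive, got {self.tau_slow}")
        if self.delay < 0:
            raise ValueError(f"delay must be >= 0, got {self.delay}")

    @property
    def has_slow(self) -> bool:
        return self.w_slow is not None

    @property
    def coupled(self) -> bool:
        """True when the slow time constant is tied to the fast one."""
        return self.has_slow and self.tau_slow is None

    def effective_tau_slow(self) -> float | None:
        if not self.has_slow:
            return None
        return self.tau_slow if self.tau_slow is not None else coupled_tau_slow(self.tau_fast)

    def max_tau(self) -> float:
        ts = self.effective_tau_slow()
        return max(self.tau_fast, ts) if ts is not None else self.tau_fast

    def copy(self, **changes) -> "KernelParams":
        return replace(self, **changes)


def alpha_kernel(t, tau: float):
    """Alpha-function synaptic kernel ``H(t) * (t/tau) * exp(-t/tau)``.

    Unit-normalized to peak value 1/e at ``t = tau``; zero for ``t < 0``.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / tau
    out[pos] = x * np.exp(-x)
    if out.ndim == 0:
        return float(out)
    return out


def alpha_kernel_dtau(t, tau: float):
    """Partial derivative of :func:`alpha_kernel` with respect to ``tau``.

    d/dtau [ (t/tau) e^{-t/tau} ] = (t / tau^2) e^{-t/tau} (t/tau - 1).
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / tau
    out[pos] = (x / tau) * np.exp(-x) * (x - 1.0)
    return out


def _kernel_lags(params: KernelParams, grid: TimeGrid, support_factor: float) -> np.ndarray:
    horizon = params.delay + support_factor * params.max_tau()
    if horizon < params.delay:
        raise ValueError("truncation horizon shorter than the propagation delay")
    # tolerance keeps the lag count stable under float jitter in tau
    n_lags = int(np.ceil(horizon / grid.dt - 1e-9)) + 1
    # lag of bin center relative to the spike bin
    return np.arange(n_lags) * grid.dt


def build_kernel(
    params: KernelParams,
    grid: TimeGrid,
    support_factor: float = DEFAULT_SUPPORT_FACTOR,
) -> np.ndarray:
    """Sample the (possibly two-component) synaptic kernel on grid lags.

    The kernel is evaluated at lags ``k*dt`` for ``k = 0..ceil(horizon/dt)``
    with the delay rounded to the nearest bin, and truncated at
    ``delay + support_factor * max(tau)``.
    """
    lags = _kernel_lags(params, grid, support_factor)
    delay = round(params.delay / grid.dt) * grid.dt
    t = lags - delay
    ker = params.w_fast * alpha_kernel(t, params.tau_fast)
    if params.has_slow:
        ker = ker + params.w_slow * alpha_kernel(t, params.effective_tau_slow())
    return ker


def build_kernel_dlogtau(
    params: KernelParams,
    grid: TimeGrid,
    support_factor: float = DEFAULT_SUPPORT_FACTOR,
    which: str = "fast",
) -> np.ndarray:
    """Derivative of the sampled kernel with respect to log(tau_fast) or
    log(tau_slow), including the coupled-slow chain-rule term."""
    lags = _kernel_lags(params, grid, support_factor)
    delay = round(params.delay / grid.dt) * grid.dt
    t = lags - delay
    if which == "fast":
        d = params.w_fast * alpha_kernel_dtau(t, params.tau_fast) * params.tau_fast
        if params.coupled:
            # tau_slow = 10.4 + 2.8 tau_fast; d tau_slow/d log tau_fast = 2.8 tau_fast
            d = d + (
                params.w_slow
                * alpha_kernel_dtau(t, params.effective_tau_slow())
                * TAU_SLOW_SLOPE
                * params.tau_fast
            )
        return d
    if which == "slow":
        if not params.has_slow or params.coupled:
            raise ValueError("no independent slow time constant in this kernel")
        return params.w_slow * alpha_kernel_dtau(t, params.tau_slow) * params.tau_slow
    raise ValueError(f"which must be 'fast' or 'slow', got {which!r}")


def kernel_truncation_error(params: KernelParams, support_factor: float = DEFAULT_SUPPORT_FACTOR) -> float:
    """Fraction of total (absolute) kernel mass discarded by truncation.

    The alpha function integrates to tau * e over [0, inf); the tail beyond
    ``T`` is ``(1 + T/tau) exp(-T/tau) * tau``... computed in closed form.
    """
    T = support_factor * params.max_tau()

    def tail_fraction(tau: float) -> float:
        x = T / tau
        return (1.0 + x) * np.exp(-x)

    total = abs(params.w_fast) * params.tau_fast
    tail = abs(params.w_fast) * params.tau_fast * tail_fraction(params.tau_fast)
    if params.has_slow:
        ts = params.effective_tau_slow()
        total += abs(params.w_slow) * ts
        tail += abs(params.w_slow) * ts * tail_fraction(ts)
    if total == 0:
        return 0.0
    return tail / total


def bin_spikes(times: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """Spike counts per grid bin. Spikes outside the grid span raise."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.zeros(grid.n_bins)
    if times.min() < grid.t0 or times.max() >= grid.t_end:
        raise ValueError(
            f"spike times outside grid span [{grid.t0}, {grid.t_end}): "
            f"range [{times.min()}, {times.max()}]"
        )
    idx = np.floor((times - grid.t0) / grid.dt).astype(int)
    return np.bincount(idx, minlength=grid.n_bins).astype(float)


def convolve_counts(counts: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal discrete convolution of binned counts with a sampled kernel,
    truncated to the grid length."""
    n = counts.shape[0]
    if kernel.shape[0] <= 64:
        out = np.convolve(counts, kernel)
    else:
        out = fftconvolve(counts, kernel)
    return out[:n]


def convolve_spikes(
    train: SpikeTrain,
    params: KernelParams,
    grid: TimeGrid,
    support_factor: float = DEFAULT_SUPPORT_FACTOR,
) -> np.ndarray:
    """Per-synapse filtered signal: the spike train convolved with its kernel.

    Spikes are binned to the grid first; the response to an empty train is
    identically zero. Linear in the spike train.
    """
    counts = bin_spikes(train.times, grid)
    if not counts.any():
        return np.zeros(grid.n_bins)
    kernel = build_kernel(params, grid, support_factor)
    return convolve_counts(counts, kernel)
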