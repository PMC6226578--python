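"""Spiking extension of the hLN model (hierarchical GLM).

The subthreshold response drives an inhomogeneous Poisson process through
an exponential link, ``lambda(t) = lambda0 * exp(beta * v(t))``, and each
output spike feeds back an additive adaptation current built from
raised-cosine basis functions:

    psi_i(tau) = 1/2 [cos(a log(tau + c) - phi_i) + 1]
                 for a log(tau + c) in [phi_i - pi, phi_i + pi], else 0

with the centers phi_i uniformly spaced.  Time lags tau are in ms (with
the default constants a = 3.75, c = 0.01 and phi in [3, 22] the basis
supports span roughly one millisecond to one second, the range of spike-
frequency adaptation).  Spikes are drawn by thinning on the discrete grid
with at most one spike per bin; absolute refractoriness is not modeled —
suppression after a spike comes only from negative adaptation weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import HLNArchitecture, evaluate
from .signals import (
    DEFAULT_SUPPORT_FACTOR,
    SpikeTrain,
    SpikeTrainSet,
    TimeGrid,
    bin_spikes,
    convolve_counts,
)

__all__ = [
    "AdaptationBasis",
    "SpikingParams",
    "raised_cosine_basis",
    "adaptation_signal",
    "subthreshold_with_adaptation",
    "firing_rate",
    "sample_spikes",
    "fit_spiking",
    "fit_adaptation_weights",
    "poisson_log_likelihood",
]

LAMBDA0_FLOOR = 1e-4  # Hz


@dataclass
class AdaptationBasis:
    """Raised-cosine post-spike basis sampled on grid lags.

    ``functions`` has shape (n_basis, n_lags); row i is psi_i evaluated at
    lags ``k * dt`` ms.
    """

    n_basis: int
    a: float
    c: float
    phi: np.ndarray
    dt: float
    functions: np.ndarray = field(repr=False)

    def support(self, i: int) -> tuple[float, float]:
        """Lag interval (ms) outside which psi_i vanishes."""
        lo = float(np.exp((self.phi[i] - np.pi) / self.a) - self.c)
        hi = float(np.exp((self.phi[i] + np.pi) / self.a) - self.c)
        return max(lo, 0.0), hi


@dataclass
class SpikingParams:
    """Exponential-link parameters of the Poisson spiking mechanism."""

    lambda0: float  # baseline rate, Hz
    beta: float  # sharpness, 1/mV
    gamma: np.ndarray | None = None  # adaptation weights, mV per basis unit

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ValueError(f"lambda0 must be positive, got {self.lambda0}")


def raised_cosine_basis(
    grid: TimeGrid,
    n_basis: int = 10,
    a: float = 3.75,
    c: float = 0.01,
    phi_range: tuple[float, float] = (3.0, 22.0),
) -> AdaptationBasis:
    """Raised-cosine "bump" basis for post-spike adaptation kernels.

    Centers are uniform on ``phi_range`` in the warped coordinate
    ``a * log(tau + c)``; each bump is nonzero only where the warped lag is
    within pi of its center.
    """
    if n_basis < 1:
        raise ValueError("n_basis must be >= 1")
    lo, hi = phi_range
    if hi < lo:
        raise ValueError(f"invalid phi_range {phi_range}")
    phi = np.linspace(lo, hi, n_basis) if n_basis > 1 else np.array([(lo + hi) / 2.0])
    tau_max = np.exp((phi[-1] + np.pi) / a) - c
    n_lags = int(np.ceil(tau_max / grid.dt)) + 1
    tau = np.arange(n_lags) * grid.dt
    warped = a * np.log(tau + c)
    funcs = np.zeros((n_basis, n_lags))
    for i, p in enumerate(phi):
        m = np.abs(warped - p) <= np.pi
        funcs[i, m] = 0.5 * (np.cos(warped[m] - p) + 1.0)
    return AdaptationBasis(n_basis=n_basis, a=a, c=c, phi=phi, dt=grid.dt, functions=funcs)


def adaptation_signal(
    out_spikes: np.ndarray | SpikeTrain,
    basis: AdaptationBasis,
    gamma: np.ndarray,
    grid: TimeGrid,
) -> np.ndarray:
    """Summed post-spike adaptation term sum_j gamma_j psi_j(t)."""
    if abs(basis.dt - grid.dt) > 1e-12:
        raise ValueError("basis was sampled at a different dt than the grid")
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape[0] != basis.n_basis:
        raise ValueError("gamma length does not match the basis")
    times = out_spikes.times if isinstance(out_spikes, SpikeTrain) else out_spikes
    counts = bin_spikes(np.asarray(times, dtype=float), grid)
    out = np.zeros(grid.n_bins)
    for j in range(basis.n_basis):
        if gamma[j] != 0.0:
            out += gamma[j] * convolve_counts(counts, basis.functions[j])
    return out


def basis_convolutions(
    out_spikes: np.ndarray | SpikeTrain, basis: AdaptationBasis, grid: TimeGrid
) -> np.ndarray:
    """Each basis function convolved with the output spike train;
    shape (n_basis, n_bins)."""
    times = out_spikes.times if isinstance(out_spikes, SpikeTrain) else out_spikes
    counts = bin_spikes(np.asarray(times, dtype=float), grid)
    return np.stack([convolve_counts(counts, f) for f in basis.functions])


def subthreshold_with_adaptation(
    arch: HLNArchitecture,
    spikes_in: SpikeTrainSet,
    out_spikes: np.ndarray | SpikeTrain,
    basis: AdaptationBasis,
    gamma: np.ndarray,
    grid: TimeGrid,
    support_factor: float = DEFAULT_SUPPORT_FACTOR,
) -> np.ndarray:
    """Model voltage with the adaptation term added to the root subunit's
    input (zero gamma reduces exactly to the ordinary forward pass)."""
    extra = adaptation_signal(out_spikes, basis, gamma, grid)
    state = evaluate(arch, spikes_in, grid, support_factor, extra_root_input=extra)
    return state.v


def firing_rate(vtilde: np.ndarray, params: SpikingParams) -> np.ndarray:
    """Instantaneous Poisson rate lambda(t) = lambda0 * exp(beta * v) (Hz)."""
    return params.lambda0 * np.exp(params.beta * np.asarray(vtilde, dtype=float))


def sample_spikes(
    rate_hz: np.ndarray, grid: TimeGrid, rng: np.random.Generator
) -> np.ndarray:
    """Draw output spike times by per-bin thinning (at most one per bin).

    The bin spiking probability is ``1 - exp(-lambda * dt)``; spikes are
    placed at bin centers.
    """
    rate_hz = np.asarray(rate_hz, dtype=float)
    if rate_hz.shape[0] != grid.n_bins:
        raise ValueError("rate trace length does not match the grid")
    p = 1.0 - np.exp(-np.clip(rate_hz, 0.0, None) * grid.dt / 1000.0)
    hits = rng.random(grid.n_bins) < p
    return grid.times()[hits]


def poisson_log_likelihood(
    spike_times: np.ndarray, vtilde: np.ndarray, params: SpikingParams, grid: TimeGrid
) -> float:
    """Discrete-time inhomogeneous-Poisson log likelihood
    ``sum_spikes log(lambda dt) - sum_bins lambda dt``."""
    lam = firing_rate(vtilde, params)
    dt_s = grid.dt / 1000.0
    counts = bin_spikes(np.asarray(spike_times, dtype=float), grid)
    with np.errstate(divide="ignore"):
        ll = float(np.dot(counts, np.log(lam * dt_s))) - float(np.sum(lam * dt_s))
    return ll


def fit_spiking(
    vtilde: np.ndarray,
    observed_spikes: np.ndarray | SpikeTrain,
    grid: TimeGrid,
) -> SpikingParams:
    """Maximum-likelihood (lambda0, beta) given the subthreshold response.

    The log likelihood is concave in (log lambda0, beta); a quasi-Newton
    descent on its negative converges to the global optimum.  With no
    observed spikes lambda0 is returned at a small floor value with a
    warning.
    """
    vtilde = np.asarray(vtilde, dtype=float)
    if vtilde.shape[0] != grid.n_bins:
        raise ValueError("vtilde length does not match the grid")
    times = observed_spikes.times if isinstance(observed_spikes, SpikeTrain) else observed_spikes
    counts = bin_spikes(np.asarray(times, dtype=float), grid)
    n_spikes = counts.sum()
    dt_s = grid.dt / 1000.0
    if n_spikes == 0:
        warnings.warn("no observed spikes: lambda0 returned at its floor", stacklevel=2)
        return SpikingParams(lambda0=LAMBDA0_FLOOR, beta=0.0)

    # center v for conditioning; fold the shift back into lambda0 afterwards
    v_mean = float(np.mean(vtilde))
    vc = vtilde - v_mean

    def nll(x):
        eta, beta = x
        log_lam_dt = eta + beta * vc + np.log(dt_s)
        lam_dt = np.exp(log_lam_dt)
        f = -(np.dot(counts, log_lam_dt) - lam_dt.sum())
        g_eta = -(n_spikes - lam_dt.sum())
        g_beta = -(np.dot(counts, vc) - np.dot(lam_dt, vc))
        return f, np.array([g_eta, g_beta])

    x0 = np.array([np.log(n_spikes / (grid.n_bins * dt_s)), 0.0])
    res = minimize(nll, x0, jac=True, method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
    eta, beta = res.x
    lambda0 = float(np.exp(eta - beta * v_mean))
    return SpikingParams(lambda0=max(lambda0, LAMBDA0_FLOOR), beta=float(beta))


def fit_adaptation_weights(
    arch: HLNArchitecture,
    spikes_in: SpikeTrainSet,
    out_spikes: np.ndarray | SpikeTrain,
    basis: AdaptationBasis,
    target: np.ndarray,
    grid: TimeGrid,
    gamma0: np.ndarray | None = None,
    support_factor: float = DEFAULT_SUPPORT_FACTOR,
) -> np.ndarray:
    """Least-squares adaptation weights gamma given fixed hLN parameters.

    Minimizes the mean squared error of the adapted subthreshold response;
    the gradient uses the chain rule through the root subunit (for a linear
    root this is an ordinary linear least-squares problem and the optimum is
    reached in a few quasi-Newton steps).
    """
    target = np.asarray(target, dtype=float)
    psi = basis_convolutions(out_spikes, basis, grid)
    root = arch.root
    if gamma0 is None:
        gamma0 = np.zeros(basis.n_basis)

    if len(root.channels) == 1 and not root.channels[0].has_nonlinearity:
        # linear root: v is affine in gamma, solve exactly
        base = evaluate(arch, spikes_in, grid, support_factor).v
        A = (root.coupling * psi).T
        sol, *_ = np.linalg.lstsq(A, target - base, rcond=None)
        return sol

    def obj(gamma):
        extra = psi.T @ gamma
        state = evaluate(arch, spikes_in, grid, support_factor, extra_root_input=extra)
        resid = state.v - target
        f = float(np.mean(resid**2))
        g_root = root.coupling * state.slope[(root.id, 0)]
        back = (2.0 / grid.n_bins) * resid * g_root
        return f, psi @ back

    res = minimize(obj, gamma0, jac=True, method="L-BFGS-B", options={"maxiter": 300})
    return res.x
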