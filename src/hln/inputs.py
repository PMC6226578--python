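"""In-vivo-like presynaptic input generator.

Emulates the synaptic input statistics of a visual-cortex L2/3 pyramidal
neuron during drifting-grating stimulation:

* excitatory synapses are divided into orientation-tuned *ensembles*;
  inputs within an ensemble switch synchronously between a background
  (5 Hz) and an elevated (20 Hz) firing rate, with the switch-on rate an
  orientation-tuned sine between 0.5 and 14 Hz, a constant switch-off rate
  of 20 Hz, and active states capped at 150 ms;
* on top of the two-state equilibrium, each ensemble's rate follows a
  shared Ornstein-Uhlenbeck fluctuation (tau = 500 ms; SD 2.5 Hz in the
  background and 10 Hz in the elevated state), clipped at zero;
* spikes are drawn from an inhomogeneous Poisson process;
* a single inhibitory population tracks the instantaneous mean excitatory
  rate affinely, from 20 Hz (all ensembles background) to 30 Hz (all
  elevated).

A session consists of 3 s blocks of each of the 16 grating orientations
(48 s total); ensemble preferred orientations are drawn from
Normal(0, 33 deg) and rounded to the 22.5 deg stimulus wheel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import SpikeTrain, SpikeTrainSet, TimeGrid

__all__ = [
    "EnsembleConfig",
    "OUParams",
    "InhibitionRule",
    "GeneratorConfig",
    "GeneratedDataset",
    "orientation_on_rate",
    "sample_active_durations",
    "sample_state_sequence",
    "sample_state_sequence_scheduled",
    "sample_ou_rates",
    "inhibitory_rate",
    "sample_poisson_spikes",
    "generate_dataset",
]

ORIENTATION_STEP = 22.5  # deg; 16 stimulus orientations on the wheel


@dataclass
class EnsembleConfig:
    """Two-state switching statistics of the excitatory ensembles."""

    n_ensembles: int = 13
    synapses_per_ensemble: int = 48
    background_rate: float = 5.0  # Hz
    elevated_rate: float = 20.0  # Hz
    omega_on_range: tuple[float, float] = (0.5, 14.0)  # Hz
    omega_off: float = 20.0  # Hz
    max_active_duration: float = 150.0  # ms
    orientation_pref_sd: float = 33.0  # deg, mean 0

    def __post_init__(self) -> None:
        if self.background_rate <= 0 or self.elevated_rate <= 0:
            raise ValueError("state rates must be positive")
        if self.omega_on_range[0] > self.omega_on_range[1]:
            raise ValueError("omega_on_range must be ordered")

    @property
    def omega_on_default(self) -> float:
        """Scalar switch-on rate used outside an orientation context
        (midpoint of the tuning range)."""
        return 0.5 * (self.omega_on_range[0] + self.omega_on_range[1])


@dataclass
class OUParams:
    """Ornstein-Uhlenbeck firing-rate fluctuation parameters."""

    tau: float = 500.0  # ms
    sd_background: float = 2.5  # Hz
    sd_elevated: float = 10.0  # Hz

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sd_background < 0 or self.sd_elevated < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class InhibitionRule:
    """Affine tracking of the mean excitatory rate by inhibition."""

    rate_at_all_background: float = 20.0  # Hz
    rate_at_all_elevated: float = 30.0  # Hz


@dataclass
class GeneratorConfig:
    """Full configuration of a synthetic input session."""

    ensembles: EnsembleConfig = field(default_factory=EnsembleConfig)
    ou: OUParams = field(default_factory=OUParams)
    inhibition: InhibitionRule = field(default_factory=InhibitionRule)
    n_inh_synapses: int = 540  # 120 dendritic + 420 perisomatic in the reference cell
    dt: float = 1.0  # ms
    block_duration: float = 3000.0  # ms per orientation
    ou_enabled: bool = True

    def to_dict(self) -> dict:
        return {
            "ensembles": vars(self.ensembles).copy(),
            "ou": vars(self.ou).copy(),
            "inhibition": vars(self.inhibition).copy(),
            "n_inh_synapses": self.n_inh_synapses,
            "dt": self.dt,
            "block_duration": self.block_duration,
            "ou_enabled": self.ou_enabled,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        ens = d.get("ensembles", {})
        if "omega_on_range" in ens:
            ens = dict(ens)
            ens["omega_on_range"] = tuple(ens["omega_on_range"])
        return cls(
            ensembles=EnsembleConfig(**ens),
            ou=OUParams(**d.get("ou", {})),
            inhibition=InhibitionRule(**d.get("inhibition", {})),
            n_inh_synapses=int(d.get("n_inh_synapses", 540)),
            dt=float(d.get("dt", 1.0)),
            block_duration=float(d.get("block_duration", 3000.0)),
            ou_enabled=bool(d.get("ou_enabled", True)),
        )


def orientation_on_rate(
    preferred: float, stimulus: float, config: EnsembleConfig | None = None
) -> float:
    """Orientation-tuned switch-on rate (Hz).

    Sinusoidal tuning on the orientation circle,
    ``omega_on = mid + half_range * cos(2 * (stimulus - preferred))``,
    peaking at the preferred orientation and bottoming out at the
    orthogonal one (anchors 14 Hz and 0.5 Hz by default).
    """
    config = config or EnsembleConfig()
    lo, hi = config.omega_on_range
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    d = np.deg2rad(stimulus - preferred)
    return float(mid + half * np.cos(2.0 * d))


def sample_active_durations(
    omega_off: float,
    max_duration_ms: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Active-state durations (ms): exponential with rate omega_off (Hz),
    capped at the maximum duration."""
    dur = rng.exponential(1000.0 / omega_off, size=n)
    return np.minimum(dur, max_duration_ms)


def sample_state_sequence(
    omega_on: float,
    omega_off: float,
    max_duration_ms: float,
    duration_ms: float,
    dt: float,
    rng: np.random.Generator,
    return_periods: bool = False,
):
    """Binary background(0)/active(1) state trace.

    Background durations are exponential with rate ``omega_on`` (Hz);
    active durations exponential with rate ``omega_off``, truncated by
    capping at ``max_duration_ms``.  Simulated event-driven in continuous
    time, then binned (a bin is active if its center falls in an active
    period).  ``omega_on = 0`` yields an all-background trace.  With
    ``return_periods`` the (onset, offset) times (ms) of the sampled active
    periods are returned alongside the trace.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    n_bins = int(round(duration_ms / dt))
    states = np.zeros(n_bins, dtype=bool)
    periods: list[tuple[float, float]] = []
    if omega_on <= 0:
        return (states, periods) if return_periods else states
    t = 0.0
    centers = (np.arange(n_bins) + 0.5) * dt
    while t < duration_ms:
        t += rng.exponential(1000.0 / omega_on)  # background period
        if t >= duration_ms:
            break
        dur = min(rng.exponential(1000.0 / omega_off), max_duration_ms)
        states[(centers >= t) & (centers < t + dur)] = True
        periods.append((t, t + dur))
        t += dur
    return (states, periods) if return_periods else states


def sample_state_sequence_scheduled(
    omega_on_per_bin: np.ndarray,
    omega_off: float,
    max_duration_ms: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """State trace under a piecewise-constant switch-on rate schedule.

    Per-bin Markov chain (switch probabilities ``1 - exp(-omega * dt)``)
    with the active-duration cap enforced across schedule boundaries; for
    ``dt`` much smaller than the mean state durations the sampled durations
    are indistinguishable from (truncated) exponentials.
    """
    omega_on_per_bin = np.asarray(omega_on_per_bin, dtype=float)
    n_bins = omega_on_per_bin.shape[0]
    p_on = 1.0 - np.exp(-np.clip(omega_on_per_bin, 0.0, None) * dt / 1000.0)
    p_off = 1.0 - np.exp(-omega_off * dt / 1000.0)
    u = rng.random(n_bins)
    states = np.zeros(n_bins, dtype=bool)
    active = False
    elapsed = 0.0
    for k in range(n_bins):
        if active:
            elapsed += dt
            if elapsed >= max_duration_ms or u[k] < p_off:
                active = False
        else:
            if u[k] < p_on[k]:
                active = True
                elapsed = 0.0
        states[k] = active
    return states


def sample_ou_rates(
    states: np.ndarray,
    background_rate: float,
    elevated_rate: float,
    ou: OUParams,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Firing-rate trace (Hz): OU fluctuations around the state-dependent
    equilibrium, clipped at zero.

    Uses the exact OU discretization
    ``r[k+1] = eq + (r[k] - eq) * exp(-dt/tau) + sd * sqrt(1 - exp(-2 dt/tau)) * xi``
    with the equilibrium and the stationary SD switching with the state.
    Zero SDs reproduce the equilibrium rates exactly.
    """
    states = np.asarray(states, dtype=bool)
    n = states.shape[0]
    eq = np.where(states, elevated_rate, background_rate)
    sd = np.where(states, ou.sd_elevated, ou.sd_background)
    if ou.sd_background == 0 and ou.sd_elevated == 0:
        return eq.astype(float)
    a = np.exp(-dt / ou.tau)
    b = np.sqrt(1.0 - a * a)
    xi = rng.standard_normal(n)
    # simulate the zero-mean fluctuation, then add the state-dependent mean
    dev = np.empty(n)
    dev[0] = sd[0] * xi[0]
    for k in range(1, n):
        dev[k] = a * dev[k - 1] + b * sd[k] * xi[k]
    return np.clip(eq + dev, 0.0, None)


def inhibitory_rate(
    mean_exc_rate: np.ndarray,
    rule: InhibitionRule,
    exc_background: float = 5.0,
    exc_elevated: float = 20.0,
) -> np.ndarray:
    """Inhibitory population rate tracking the mean excitatory rate.

    Affine map anchored at the all-background mean excitatory rate
    (-> ``rate_at_all_background``) and the all-elevated one
    (-> ``rate_at_all_elevated``); clipped at zero.
    """
    mean_exc_rate = np.asarray(mean_exc_rate, dtype=float)
    span = exc_elevated - exc_background
    frac = (mean_exc_rate - exc_background) / span
    out = rule.rate_at_all_background + frac * (
        rule.rate_at_all_elevated - rule.rate_at_all_background
    )
    return np.clip(out, 0.0, None)


def sample_poisson_spikes(
    rate_hz: np.ndarray, grid: TimeGrid, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times (ms) from a per-bin rate trace.

    Per-bin Poisson counts with mean ``rate * dt`` (spikes placed at bin
    centers), so the expected total count equals the integrated rate.
    """
    rate_hz = np.asarray(rate_hz, dtype=float)
    if rate_hz.shape[0] != grid.n_bins:
        raise ValueError("rate trace length does not match the grid")
    if np.any(rate_hz < 0):
        raise ValueError("rates must be >= 0")
    counts = rng.poisson(rate_hz * grid.dt / 1000.0)
    return np.repeat(grid.times(), counts)


@dataclass
class GeneratedDataset:
    """One synthetic input session with all latent traces."""

    spikes: SpikeTrainSet
    grid: TimeGrid
    states: np.ndarray  # (n_ensembles, n_bins) bool
    exc_rates: np.ndarray  # (n_ensembles, n_bins) Hz
    inh_rate: np.ndarray  # (n_bins,) Hz
    orientation: np.ndarray  # (n_bins,) deg
    preferred_orientations: np.ndarray  # (n_ensembles,) deg
    config: GeneratorConfig
    seed: int


def _preferred_orientations(cfg: EnsembleConfig, rng: np.random.Generator) -> np.ndarray:
    raw = rng.normal(0.0, cfg.orientation_pref_sd, size=cfg.n_ensembles)
    return np.round(raw / ORIENTATION_STEP) * ORIENTATION_STEP


def generate_dataset(
    config: GeneratorConfig | None = None,
    duration_ms: float | None = None,
    orientations: np.ndarray | None = None,
    seed: int = 0,
) -> GeneratedDataset:
    """Generate a full synthetic session.

    By default the stimulus schedule is one ``block_duration`` block of each
    of the 16 orientations (48 s at the defaults).  ``orientations``
    overrides the schedule (one block per entry); ``duration_ms`` instead
    repeats/truncates the default schedule to the requested length.
    Deterministic given the seed.
    """
    config = config or GeneratorConfig()
    cfg = config.ensembles
    rng = np.random.default_rng(seed)

    if orientations is None:
        orientations = np.arange(16) * ORIENTATION_STEP
    orientations = np.asarray(orientations, dtype=float)
    bins_per_block = int(round(config.block_duration / config.dt))
    n_bins = bins_per_block * orientations.size
    if duration_ms is not None:
        n_total = int(round(duration_ms / config.dt))
        reps = int(np.ceil(n_total / n_bins))
        orientations = np.tile(orientations, reps)
        n_bins = n_total
    grid = TimeGrid(dt=config.dt, n_bins=n_bins, t0=0.0)
    orient_per_bin = np.repeat(orientations, bins_per_block)[:n_bins]

    prefs = _preferred_orientations(cfg, rng)

    states = np.zeros((cfg.n_ensembles, n_bins), dtype=bool)
    exc_rates = np.zeros((cfg.n_ensembles, n_bins))
    for e in range(cfg.n_ensembles):
        omega_on = np.array(
            [orientation_on_rate(prefs[e], o, cfg) for o in orient_per_bin]
        )
        states[e] = sample_state_sequence_scheduled(
            omega_on, cfg.omega_off, cfg.max_active_duration, config.dt, rng
        )
        if config.ou_enabled:
            exc_rates[e] = sample_ou_rates(
                states[e], cfg.background_rate, cfg.elevated_rate, config.ou, config.dt, rng
            )
        else:
            exc_rates[e] = np.where(states[e], cfg.elevated_rate, cfg.background_rate)

    inh = inhibitory_rate(
        exc_rates.mean(axis=0), config.inhibition, cfg.background_rate, cfg.elevated_rate
    )

    spikes = SpikeTrainSet()
    sid = 0
    for e in range(cfg.n_ensembles):
        for _ in range(cfg.synapses_per_ensemble):
            times = sample_poisson_spikes(exc_rates[e], grid, rng)
            spikes.add(sid, SpikeTrain(times, "excitatory", ensemble_id=e))
            sid += 1
    for _ in range(config.n_inh_synapses):
        times = sample_poisson_spikes(inh, grid, rng)
        spikes.add(sid, SpikeTrain(times, "inhibitory", ensemble_id=-1))
        sid += 1

    return GeneratedDataset(
        spikes=spikes,
        grid=grid,
        states=states,
        exc_rates=exc_rates,
        inh_rate=inh,
        orientation=orient_per_bin,
        preferred_orientations=prefs,
        config=config,
        seed=seed,
    )
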