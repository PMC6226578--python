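"""Staged maximum-likelihood fitting of hLN model parameters.

The training objective is the mean squared deviation between the recorded
subthreshold somatic voltage and the model response (optionally plus a
log-normal penalty on kernel amplitudes and time constants).  The error
surface is non-convex, so fitting proceeds in stages:

1. *Coupled stage* — a single-subunit linear model in which all excitatory
   synapses share one kernel and all inhibitory synapses another.
2. *Pre-tuning* — the target (hierarchical, nonlinear) architecture is
   initialized from the coupled fit by rescaling each subunit's inputs so
   the total-input distribution sits on the central, approximately linear
   part of its sigmoid (mean at the threshold, SD = 1/rho), while leaving
   every synapse's somatic response amplitude unchanged.  The scale factor
   rho is scanned over a grid and the best post-optimization training error
   wins (ties go to smaller rho, i.e. the more linear initialization).
3. *Decoupled stage* — kernel parameters are untied down to synapse groups
   (proximal/middle/distal) and re-optimized under the log-normal prior
   whenever there are more groups than subunits.

Gradients are computed analytically by a reverse sweep through the subunit
tree; time constants and couplings are optimized in log space to keep them
positive.  Synaptic delays are kept fixed at their bin-rounded initial
values (sub-bin delays are unidentifiable at the grid resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import (
    ArchitectureError,
    HLNArchitecture,
    evaluate,
    forward,
    group_counts,
    sigmoid_slope,
    single_subunit,
)
from .signals import (
    DEFAULT_SUPPORT_FACTOR,
    KernelParams,
    SpikeTrain,
    SpikeTrainSet,
    TimeGrid,
    build_kernel_dlogtau,
    convolve_counts,
)

__all__ = [
    "FitConfig",
    "PriorSpec",
    "FitResult",
    "Parameterization",
    "loss",
    "fit_stage_coupled",
    "pretune_nonlinearities",
    "fit",
    "slice_grid",
    "slice_spikes",
]

_LOG_EPS = 1e-12


# -- configuration ---------------------------------------------------------


@dataclass
class PriorSpec:
    """Log-normal prior on kernel amplitudes and time constants.

    ``means`` maps (population label, component) -> (mu_log_w, mu_log_tau)
    where population is "excitatory"/"inhibitory" and component is
    "fast"/"slow".  The means are normally taken from the coupled-stage
    fit; the standard deviations default to 0.5 log-units.  ``weight``
    converts the penalty into the units of the mean squared error (mV^2).
    """

    means: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    sd_log_w: float = 0.5
    sd_log_tau: float = 0.5
    weight: float = 0.1

    def __post_init__(self) -> None:
        if self.sd_log_w <= 0 or self.sd_log_tau <= 0:
            raise ValueError("prior standard deviations must be positive")

    @classmethod
    def from_kernels(
        cls,
        kernels: dict[str, KernelParams],
        sd_log_w: float = 0.5,
        sd_log_tau: float = 0.5,
        weight: float = 0.1,
    ) -> "PriorSpec":
        """Center the prior on reference (coupled-stage) kernels per label."""
        means: dict[tuple[str, str], tuple[float, float]] = {}
        for label, k in kernels.items():
            means[(label, "fast")] = (
                float(np.log(abs(k.w_fast) + _LOG_EPS)),
                float(np.log(k.tau_fast)),
            )
            if k.has_slow:
                means[(label, "slow")] = (
                    float(np.log(abs(k.w_slow) + _LOG_EPS)),
                    float(np.log(k.effective_tau_slow())),
                )
        return cls(means=means, sd_log_w=sd_log_w, sd_log_tau=sd_log_tau, weight=weight)


@dataclass
class FitConfig:
    """Settings of the staged fitting procedure."""

    coupled: bool = True
    pretune: bool = True
    decoupled: bool = True
    rho_grid: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    prior: PriorSpec | None = None  # built from the coupled stage when None
    use_prior: bool = True
    double_exc_kernel: bool = False
    gtol: float = 1e-7
    max_iter: int = 400
    seed: int = 0
    support_factor: float = DEFAULT_SUPPORT_FACTOR
    test_fraction: float = 0.2
    #: bins at the start of a held-out segment excluded from the VE score;
    #: the target there still carries kernel tails of pre-segment spikes
    #: that the prediction cannot see
    test_burn_in_ms: float = 500.0
    prior_sd_log_w: float = 0.5
    prior_sd_log_tau: float = 0.5
    prior_weight: float = 0.1

    def __post_init__(self) -> None:
        if not self.rho_grid:
            raise ValueError("rho_grid must be non-empty")
        if self.gtol <= 0 or self.max_iter <= 0:
            raise ValueError("optimizer tolerances must be positive")


@dataclass
class FitResult:
    """Outcome of a (staged) fit."""

    arch: HLNArchitecture
    train_mse: float
    variance_explained: float | None = None
    stage_losses: dict[str, float] = field(default_factory=dict)
    trajectory: list[float] = field(default_factory=list)
    seed: int = 0
    converged: bool = True
    message: str = ""
    rho_selected: float | None = None

    def to_dict(self) -> dict:
        return {
            "train_mse": self.train_mse,
            "variance_explained": self.variance_explained,
            "stage_losses": self.stage_losses,
            "seed": self.seed,
            "converged": self.converged,
            "message": self.message,
            "rho_selected": self.rho_selected,
            "architecture": self.arch.to_dict(),
        }


# -- time slicing utilities ------------------------------------------------


def slice_grid(grid: TimeGrid, i0: int, i1: int) -> TimeGrid:
    """Sub-grid covering bins [i0, i1) re-referenced to t=0."""
    return TimeGrid(dt=grid.dt, n_bins=i1 - i0, t0=0.0)


def slice_spikes(spikes: SpikeTrainSet, grid: TimeGrid, i0: int, i1: int) -> SpikeTrainSet:
    """Spike trains restricted to bins [i0, i1), times re-referenced to 0."""
    t_lo = grid.t0 + i0 * grid.dt
    t_hi = grid.t0 + i1 * grid.dt
    out = SpikeTrainSet()
    for sid, tr in spikes.items():
        sel = (tr.times >= t_lo) & (tr.times < t_hi)
        out.add(sid, SpikeTrain(tr.times[sel] - t_lo, tr.label, tr.ensemble_id))
    return out


# -- parameterization and loss ---------------------------------------------


def _group_label(arch: HLNArchitecture, spikes: SpikeTrainSet | None, gid: int) -> str:
    """Population label of a synapse group (from its members, falling back
    to the sign of the kernel amplitude)."""
    grp = arch.groups[gid]
    if spikes is not None:
        for syn in grp.members:
            if syn in spikes.trains:
                return spikes[syn].label
    owner = arch.group_owner(gid)
    k = owner.channels[0].kernels[gid]
    return "excitatory" if k.w_fast >= 0 else "inhibitory"


class Parameterization:
    """Flat free-parameter vector over an architecture, with kernel tying.

    tie:
        "population" — all groups with the same population label share one
            kernel block per channel index (the coupled stage);
        "subunit"    — one kernel block per (subunit, channel, label);
        "none"       — one block per (subunit, channel, group).

    Free parameters: v0; log-couplings (the root's only when its output is
    nonlinear, since a linear root's coupling is redundant with the
    weights); thresholds of nonlinear channels; per kernel block: w_fast,
    log tau_fast, and for two-component kernels w_slow (plus log tau_slow
    when not coupled).  Delays are fixed.
    """

    def __init__(
        self,
        arch: HLNArchitecture,
        spikes: SpikeTrainSet,
        grid: TimeGrid,
        tie: str = "none",
        support_factor: float = DEFAULT_SUPPORT_FACTOR,
        prior: PriorSpec | None = None,
    ) -> None:
        if tie not in ("population", "subunit", "none"):
            raise ValueError(f"unknown tie level {tie!r}")
        self.template = arch.copy()
        self.spikes = spikes
        self.grid = grid
        self.tie = tie
        self.support_factor = support_factor
        self.prior = prior
        self.counts = group_counts(arch, spikes, grid)

        self._slots: list[tuple[int, int, int]] = []  # (subunit, channel, group)
        self._slot_block: dict[tuple[int, int, int], tuple] = {}
        self._slot_label: dict[tuple[int, int, int], str] = {}
        for s in self.template.subunits:
            for ci in range(len(s.channels)):
                for gid in s.synapse_groups:
                    slot = (s.id, ci, gid)
                    label = _group_label(self.template, spikes, gid)
                    self._slots.append(slot)
                    self._slot_label[slot] = label
                    if tie == "population":
                        key = ("pop", ci, label)
                    elif tie == "subunit":
                        key = ("sub", s.id, ci, label)
                    else:
                        key = ("grp", s.id, ci, gid)
                    self._slot_block[slot] = key

        # kernel structure per block must be homogeneous
        self._block_struct: dict[tuple, tuple[bool, bool]] = {}
        for slot, key in self._slot_block.items():
            sid, ci, gid = slot
            k = self.template.subunit(sid).channels[ci].kernels[gid]
            struct = (k.has_slow, k.coupled)
            if key in self._block_struct and self._block_struct[key] != struct:
                raise ArchitectureError(
                    f"kernel block {key}: inconsistent kernel structure across tied groups"
                )
            self._block_struct[key] = struct

        # index layout
        self._index: dict[tuple, int] = {}
        n = 0

        def reg(name: tuple) -> None:
            nonlocal n
            self._index[name] = n
            n += 1

        reg(("v0",))
        root = self.template.root
        self._root_coupling_free = any(ch.has_nonlinearity for ch in root.channels)
        for s in self.template.subunits:
            if s.id == root.id and not self._root_coupling_free:
                continue
            reg(("log_c", s.id))
        for s in self.template.subunits:
            for ci, ch in enumerate(s.channels):
                if ch.has_nonlinearity:
                    reg(("theta", s.id, ci))
        self._blocks = sorted(set(self._slot_block.values()), key=repr)
        for key in self._blocks:
            has_slow, coupled = self._block_struct[key]
            reg(("w_fast",) + key)
            reg(("log_tau_fast",) + key)
            if has_slow:
                reg(("w_slow",) + key)
                if not coupled:
                    reg(("log_tau_slow",) + key)
        self.n_params = n

    # -- vector <-> architecture ------------------------------------------

    def _block_rep(self, key: tuple) -> KernelParams:
        for slot, k in self._slot_block.items():
            if k == key:
                sid, ci, gid = slot
                return self.template.subunit(sid).channels[ci].kernels[gid]
        raise KeyError(key)

    def pack(self, arch: HLNArchitecture | None = None) -> np.ndarray:
        """Parameter vector from an architecture (default: the template).

        With tying, the block value is read from the first slot mapped to it.
        """
        a = self.template if arch is None else arch
        x = np.zeros(self.n_params)
        for name, i in self._index.items():
            kind = name[0]
            if kind == "v0":
                x[i] = a.v0
            elif kind == "log_c":
                x[i] = np.log(a.subunit(name[1]).coupling)
            elif kind == "theta":
                x[i] = a.subunit(name[1]).channels[name[2]].theta
            else:
                key = name[1:]
                for slot, bk in self._slot_block.items():
                    if bk == key:
                        sid, ci, gid = slot
                        k = a.subunit(sid).channels[ci].kernels[gid]
                        break
                else:  # pragma: no cover
                    raise KeyError(key)
                if kind == "w_fast":
                    x[i] = k.w_fast
                elif kind == "log_tau_fast":
                    x[i] = np.log(k.tau_fast)
                elif kind == "w_slow":
                    x[i] = k.w_slow
                elif kind == "log_tau_slow":
                    x[i] = np.log(k.effective_tau_slow())
        return x

    def unpack(self, x: np.ndarray) -> HLNArchitecture:
        """Architecture with the free parameters set from the vector."""
        a = self.template.copy()
        a.v0 = x[self._index[("v0",)]]
        for s in a.subunits:
            if ("log_c", s.id) in self._index:
                s.coupling = float(np.exp(x[self._index[("log_c", s.id)]]))
            for ci, ch in enumerate(s.channels):
                if ("theta", s.id, ci) in self._index:
                    ch.theta = float(x[self._index[("theta", s.id, ci)]])
        for slot, key in self._slot_block.items():
            sid, ci, gid = slot
            k = a.subunit(sid).channels[ci].kernels[gid]
            k.w_fast = float(x[self._index[("w_fast",) + key]])
            k.tau_fast = float(np.exp(x[self._index[("log_tau_fast",) + key]]))
            if self._block_struct[key][0]:
                k.w_slow = float(x[self._index[("w_slow",) + key]])
                if not self._block_struct[key][1]:
                    k.tau_slow = float(np.exp(x[self._index[("log_tau_slow",) + key]]))
        return a

    # -- objective ---------------------------------------------------------

    def _prior_terms(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        if self.prior is None:
            return 0.0, np.zeros(self.n_params)
        p = self.prior
        pen = 0.0
        grad = np.zeros(self.n_params)
        for key in self._blocks:
            # label lives in the block key for pop/sub ties, else look it up
            label = None
            for slot, bk in self._slot_block.items():
                if bk == key:
                    label = self._slot_label[slot]
                    break
            for comp, wname, tname in (
                ("fast", ("w_fast",) + key, ("log_tau_fast",) + key),
                ("slow", ("w_slow",) + key, ("log_tau_slow",) + key),
            ):
                if wname not in self._index:
                    continue
                mu = p.means.get((label, comp))
                if mu is None:
                    continue
                mu_w, mu_tau = mu
                iw = self._index[wname]
                w = x[iw]
                lw = np.log(abs(w) + _LOG_EPS)
                pen += (lw - mu_w) ** 2 / (2 * p.sd_log_w**2)
                grad[iw] += (lw - mu_w) / (p.sd_log_w**2) / (w if w != 0 else _LOG_EPS)
                if tname in self._index:
                    it = self._index[tname]
                    pen += (x[it] - mu_tau) ** 2 / (2 * p.sd_log_tau**2)
                    grad[it] += (x[it] - mu_tau) / (p.sd_log_tau**2)
        return p.weight * pen, p.weight * grad

    def loss_and_grad(self, x: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
        """Penalized mean squared error and its analytic gradient."""
        target = np.asarray(target, dtype=float)
        if target.shape[0] != self.grid.n_bins:
            raise ValueError("target and model grid lengths differ")
        arch = self.unpack(x)
        state = evaluate(arch, self.spikes, self.grid, self.support_factor, counts=self.counts)
        resid = state.v - target
        n = self.grid.n_bins
        mse = float(np.mean(resid**2))
        w_resid = (2.0 / n) * resid  # d mse / d v(t)

        grad = np.zeros(self.n_params)
        root = arch.root

        # adjoints: R[s] = dv/dr_s, g[(s, ci)] = dv/dy_(s,ci)
        R: dict[int, np.ndarray | float] = {root.id: root.coupling}
        g: dict[tuple[int, int], np.ndarray] = {}
        order = arch.topological_order()[::-1]  # root first
        for s in order:
            if s.id not in R:
                parent = arch.subunit(s.parent_id)
                R[s.id] = g[(parent.id, 0)] * s.coupling
            for ci in range(len(s.channels)):
                g[(s.id, ci)] = R[s.id] * state.slope[(s.id, ci)]

        # v0
        grad[self._index[("v0",)]] = float(np.sum(w_resid))

        # couplings
        for s in arch.subunits:
            name = ("log_c", s.id)
            if name not in self._index:
                continue
            if s.id == root.id:
                dv_dc = state.r[root.id]
            else:
                parent = arch.subunit(s.parent_id)
                dv_dc = g[(parent.id, 0)] * state.r[s.id]
            grad[self._index[name]] = float(np.dot(w_resid, dv_dc)) * s.coupling

        # thresholds
        for s in arch.subunits:
            for ci in range(len(s.channels)):
                name = ("theta", s.id, ci)
                if name in self._index:
                    grad[self._index[name]] = -float(np.dot(w_resid, g[(s.id, ci)]))

        # kernels: accumulate over slots sharing each block
        for slot, key in self._slot_block.items():
            sid, ci, gid = slot
            k = arch.subunit(sid).channels[ci].kernels[gid]
            gc = g[(sid, ci)]
            back = w_resid * gc  # dL/dy contribution weights
            phi = state.phi[(sid, ci, gid)]
            grad[self._index[("w_fast",) + key]] += float(np.dot(back, phi["fast"]))
            dker_f = build_kernel_dlogtau(k, self.grid, self.support_factor, "fast")
            dphi_f = convolve_counts(self.counts[gid], dker_f)
            grad[self._index[("log_tau_fast",) + key]] += float(np.dot(back, dphi_f))
            if k.has_slow:
                grad[self._index[("w_slow",) + key]] += float(np.dot(back, phi["slow"]))
                if not k.coupled:
                    dker_s = build_kernel_dlogtau(k, self.grid, self.support_factor, "slow")
                    dphi_s = convolve_counts(self.counts[gid], dker_s)
                    grad[self._index[("log_tau_slow",) + key]] += float(np.dot(back, dphi_s))

        pen, pen_grad = self._prior_terms(x)
        return mse + pen, grad + pen_grad

    def loss(self, x: np.ndarray, target: np.ndarray) -> float:
        return self.loss_and_grad(x, target)[0]

    def optimize(
        self,
        target: np.ndarray,
        x0: np.ndarray | None = None,
        gtol: float = 1e-7,
        max_iter: int = 400,
    ) -> tuple[HLNArchitecture, float, list[float], bool, str]:
        """Quasi-Newton (L-BFGS) descent on the penalized loss."""
        if x0 is None:
            x0 = self.pack()
        trajectory: list[float] = []

        def cb(xk):
            trajectory.append(float(self.loss_and_grad(xk, target)[0]))

        res = minimize(
            self.loss_and_grad,
            x0,
            args=(target,),
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
        )
        f0 = float(self.loss_and_grad(x0, target)[0])
        # descent contract: never return an iterate worse than the start
        if res.fun <= f0:
            best_x, best_f = res.x, float(res.fun)
        else:  # pragma: no cover - L-BFGS-B should not go uphill
            best_x, best_f = x0, f0
        return (
            self.unpack(best_x),
            best_f,
            trajectory,
            bool(res.success),
            str(res.message),
        )


def loss(
    arch: HLNArchitecture,
    spikes: SpikeTrainSet,
    target: np.ndarray,
    grid: TimeGrid,
    prior: PriorSpec | None = None,
    support_factor: float = DEFAULT_SUPPORT_FACTOR,
) -> float:
    """Penalized mean squared error of an architecture on a target trace."""
    p = Parameterization(arch, spikes, grid, tie="none", support_factor=support_factor, prior=prior)
    return p.loss(p.pack(), target)


# -- stage 1: coupled fit --------------------------------------------------


def _lsq_amplitudes(
    param: Parameterization, x: np.ndarray, target: np.ndarray
) -> np.ndarray:
    """Closed-form least-squares amplitudes (and v0) for a linear model with
    the time constants held at their current values; used to initialize the
    coupled stage."""
    arch = param.unpack(x)
    state = evaluate(arch, param.spikes, param.grid, param.support_factor, counts=param.counts)
    cols = []
    names = []
    for name, i in param._index.items():
        if name[0] in ("w_fast", "w_slow"):
            key = name[1:]
            comp = "fast" if name[0] == "w_fast" else "slow"
            col = np.zeros(param.grid.n_bins)
            for slot, bk in param._slot_block.items():
                if bk == key:
                    sid, ci, gid = slot
                    col = col + state.phi[(sid, ci, gid)][comp]
            cols.append(col)
            names.append(i)
    cols.append(np.ones(param.grid.n_bins))
    A = np.column_stack(cols)
    sol, *_ = np.linalg.lstsq(A, target, rcond=None)
    x = x.copy()
    for i, val in zip(names, sol[:-1]):
        x[i] = val
    x[param._index[("v0",)]] = sol[-1]
    return x


def fit_stage_coupled(
    spikes: SpikeTrainSet,
    target: np.ndarray,
    grid: TimeGrid,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit a single-subunit linear model with population-shared kernels.

    All excitatory synapses share one (amplitude, time constant) pair — two
    pairs in double-kernel mode — and all inhibitory synapses another.
    Amplitudes and the offset are initialized by closed-form least squares
    at the initial time constants, then all parameters are refined jointly.
    """
    config = config or FitConfig()
    exc = spikes.excitatory_ids()
    inh = spikes.inhibitory_ids()
    arch = single_subunit(
        exc, inh, nonlinear=False, double_exc_kernel=config.double_exc_kernel,
        v0=float(np.mean(target)),
    )
    param = Parameterization(
        arch, spikes, grid, tie="population", support_factor=config.support_factor
    )
    x0 = _lsq_amplitudes(param, param.pack(), target)
    fitted, mse, traj, ok, msg = param.optimize(
        target, x0, gtol=config.gtol, max_iter=config.max_iter
    )
    return FitResult(
        arch=fitted,
        train_mse=mse,
        stage_losses={"coupled": mse},
        trajectory=traj,
        seed=config.seed,
        converged=ok,
        message=msg,
    )


# -- stage 2: pre-tuning ---------------------------------------------------


def _bypassed(arch: HLNArchitecture) -> HLNArchitecture:
    out = arch.copy()
    for s in out.subunits:
        for ch in s.channels:
            ch.has_nonlinearity = False
    return out


def pretune_nonlinearities(
    arch: HLNArchitecture,
    rho: float,
    spikes: SpikeTrainSet,
    grid: TimeGrid,
    support_factor: float = DEFAULT_SUPPORT_FACTOR,
) -> HLNArchitecture:
    """Initialize sigmoidal subunits to approximate linear integration.

    The architecture is read as a *linear* reference model (all sigmoids
    bypassed).  Proceeding from the leaves, each nonlinear channel's inputs
    (kernel amplitudes and child couplings) are rescaled so that its
    total-input distribution under the training input has mean equal to the
    sigmoid threshold and standard deviation 1/rho; the subunit coupling is
    rescaled to keep the linearized end-to-end gain — and hence every
    per-synapse somatic response amplitude — unchanged, and the offset v0
    absorbs the constant shift so the output matches the linear reference.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    v_ref = forward(_bypassed(arch), spikes, grid, support_factor)

    work = arch.copy()
    # remember which channels want a nonlinearity, then bypass all of them
    wants: dict[int, bool] = {}
    for s in work.subunits:
        if s.multiplexed and any(ch.has_nonlinearity for ch in s.channels):
            raise ArchitectureError(
                "pretuning applies to single-channel subunits; initialize "
                "multiplexed models from a pretuned single-channel fit"
            )
        wants[s.id] = s.channels[0].has_nonlinearity
        s.channels[0].has_nonlinearity = False

    for s in work.topological_order():
        if not wants[s.id]:
            continue
        state = evaluate(work, spikes, grid, support_factor)
        y = state.y[(s.id, 0)]
        m = float(np.mean(y))
        sd = float(np.std(y))
        if sd <= 0:
            raise ValueError(
                f"subunit {s.id}: degenerate (zero-variance) input distribution"
            )
        alpha = 1.0 / (rho * sd)
        ch = s.channels[0]
        for k in ch.kernels.values():
            k.w_fast *= alpha
            if k.w_slow is not None:
                k.w_slow *= alpha
        for c in work.children(s.id):
            c.coupling *= alpha
        ch.theta = alpha * m
        # preserve the linearized gain: sigmoid midpoint slope is 1/4
        s.coupling = s.coupling / (0.25 * alpha)
        ch.has_nonlinearity = True

    v_new = forward(work, spikes, grid, support_factor)
    work.v0 += float(np.mean(v_ref) - np.mean(v_new))
    return work


# -- full staged fit -------------------------------------------------------


def _transfer_coupled_kernels(
    target_arch: HLNArchitecture,
    coupled: FitResult,
    spikes: SpikeTrainSet,
) -> HLNArchitecture:
    """Copy the coupled-stage kernels into every group of the target
    architecture (by population label), reset couplings to the coupled
    model's scale and adopt its offset."""
    ref: dict[str, KernelParams] = {}
    csub = coupled.arch.root
    for gid in csub.synapse_groups:
        label = _group_label(coupled.arch, spikes, gid)
        ref[label] = csub.channels[0].kernels[gid]
    out = target_arch.copy()
    for s in out.subunits:
        s.coupling = 1.0
        for ch in s.channels:
            ch.theta = 0.0
            for gid in s.synapse_groups:
                label = _group_label(out, spikes, gid)
                if label in ref:
                    ch.kernels[gid] = ref[label].copy()
    out.v0 = coupled.arch.v0
    return out


def coupled_reference_kernels(coupled: FitResult, spikes: SpikeTrainSet) -> dict[str, KernelParams]:
    """Per-population kernels fitted by the coupled stage."""
    ref: dict[str, KernelParams] = {}
    csub = coupled.arch.root
    for gid in csub.synapse_groups:
        ref[_group_label(coupled.arch, spikes, gid)] = csub.channels[0].kernels[gid]
    return ref


def fit(
    spikes: SpikeTrainSet,
    target: np.ndarray,
    grid: TimeGrid,
    architecture: HLNArchitecture,
    config: FitConfig | None = None,
    test_spikes: SpikeTrainSet | None = None,
    test_target: np.ndarray | None = None,
) -> FitResult:
    """Staged fit of an hLN architecture to a voltage trace.

    Stages: coupled single-subunit fit; for each rho in the grid, pre-tune
    the nonlinearities and optimize with per-subunit kernels (lowest
    training error wins, ties to smaller rho); decouple kernels to synapse
    groups under the log-normal prior; report cross-validated variance
    explained on held-out data (split off the end of the trace when no
    explicit test set is given).
    """
    config = config or FitConfig()
    target = np.asarray(target, dtype=float)
    if target.shape[0] != grid.n_bins:
        raise ValueError("target and grid lengths differ")

    # held-out split
    if test_spikes is None or test_target is None:
        n_test = int(round(config.test_fraction * grid.n_bins))
        if n_test > 0:
            i_split = grid.n_bins - n_test
            test_spikes = slice_spikes(spikes, grid, i_split, grid.n_bins)
            test_target = target[i_split:]
            test_grid = slice_grid(grid, i_split, grid.n_bins)
            spikes = slice_spikes(spikes, grid, 0, i_split)
            target = target[:i_split]
            grid = slice_grid(grid, 0, i_split)
        else:
            test_grid = None
    else:
        test_grid = TimeGrid(dt=grid.dt, n_bins=len(test_target), t0=0.0)

    stage_losses: dict[str, float] = {}
    trajectory: list[float] = []

    # stage 1 — coupled
    coupled = fit_stage_coupled(spikes, target, grid, config)
    stage_losses["coupled"] = coupled.train_mse
    trajectory.extend(coupled.trajectory)

    current = _transfer_coupled_kernels(architecture, coupled, spikes)
    current_mse = coupled.train_mse
    rho_selected: float | None = None
    converged = coupled.converged
    message = coupled.message

    any_nonlinear = any(
        ch.has_nonlinearity for s in architecture.subunits for ch in s.channels
    )
    multi = len(architecture.subunits) > 1

    # stage 2 — pretune + per-subunit optimization
    if config.pretune and (any_nonlinear or multi):
        best: tuple[float, float, HLNArchitecture, list[float], bool, str] | None = None
        for rho in config.rho_grid:
            if any_nonlinear:
                init = pretune_nonlinearities(
                    current, rho, spikes, grid, config.support_factor
                )
            else:
                init = current.copy()
            param = Parameterization(
                init, spikes, grid, tie="subunit", support_factor=config.support_factor
            )
            fitted, mse, traj, ok, msg = param.optimize(
                target, gtol=config.gtol, max_iter=config.max_iter
            )
            if best is None or mse < best[0] - 1e-15:
                best = (mse, rho, fitted, traj, ok, msg)
            if not any_nonlinear:
                break  # rho has no effect on a fully linear architecture
        current_mse, rho_selected, current, traj, ok, msg = best
        stage_losses["pretuned"] = current_mse
        trajectory.extend(traj)
        converged = converged and ok
        message = msg

    # stage 3 — decoupled kernel groups with log-normal prior
    if config.decoupled:
        n_blocks_subunit = len(
            {(s.id, ci, _group_label(architecture, spikes, gid))
             for s in architecture.subunits
             for ci in range(len(s.channels))
             for gid in s.synapse_groups}
        )
        n_blocks_none = sum(
            len(s.synapse_groups) * len(s.channels) for s in architecture.subunits
        )
        if n_blocks_none > n_blocks_subunit:
            prior = config.prior
            if prior is None and config.use_prior and len(architecture.groups) > len(
                architecture.subunits
            ):
                prior = PriorSpec.from_kernels(
                    coupled_reference_kernels(coupled, spikes),
                    sd_log_w=config.prior_sd_log_w,
                    sd_log_tau=config.prior_sd_log_tau,
                    weight=config.prior_weight,
                )
            param = Parameterization(
                current, spikes, grid, tie="none",
                support_factor=config.support_factor, prior=prior,
            )
            fitted, mse_pen, traj, ok, msg = param.optimize(
                target, gtol=config.gtol, max_iter=config.max_iter
            )
            # report the pure MSE for comparability across stages
            p_clean = Parameterization(
                fitted, spikes, grid, tie="none", support_factor=config.support_factor
            )
            mse = p_clean.loss(p_clean.pack(), target)
            if mse <= current_mse:
                current, current_mse = fitted, mse
            stage_losses["decoupled"] = current_mse
            trajectory.extend(traj)
            converged = converged and ok
            message = msg

    ve: float | None = None
    if test_grid is not None and test_target is not None:
        v_pred = forward(current, test_spikes, test_grid, config.support_factor)
        burn = min(int(round(config.test_burn_in_ms / test_grid.dt)), test_grid.n_bins // 2)
        tt, vp = test_target[burn:], v_pred[burn:]
        var = float(np.var(tt))
        if var > 0:
            ve = 1.0 - float(np.mean((tt - vp) ** 2)) / var

    return FitResult(
        arch=current,
        train_mse=current_mse,
        variance_explained=ve,
        stage_losses=stage_losses,
        trajectory=trajectory,
        seed=config.seed,
        converged=converged,
        message=message,
        rho_selected=rho_selected,
    )
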