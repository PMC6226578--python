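"""Hierarchical linear-nonlinear (hLN) architectures and forward evaluation.

An hLN model is a rooted tree of *subunits*.  Each subunit linearly filters
the spike trains of the synapses assigned to it (through alpha-function
kernels shared within *synapse groups*), adds the coupled outputs of its
child subunits, and passes the total through a static logistic sigmoid
(or the identity, for purely linear subunits).  The root subunit's output,
scaled by its coupling and shifted by an offset ``v0``, models the somatic
subthreshold membrane potential:

    v(t) = c_1 * r_1( sum_k c_k r_k(t) + sum_i w_1i phi_1i(t) ; theta_1 ) + v0

*Multiplexing* gives a subunit two parallel channels, each filtering the
same spike trains with its own kernels and its own sigmoid; the channel
outputs are summed.  Child-subunit outputs feed the first channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .signals import (
    DEFAULT_SUPPORT_FACTOR,
    KernelParams,
    SpikeTrainSet,
    TimeGrid,
    bin_spikes,
    build_kernel,
    convolve_counts,
)

__all__ = [
    "Channel",
    "Subunit",
    "SynapseGroup",
    "HLNArchitecture",
    "ArchitectureError",
    "sigmoid",
    "sigmoid_slope",
    "subunit_output",
    "ForwardState",
    "evaluate",
    "forward",
    "count_params",
    "count_params_canonical",
    "synapse_amplitude",
    "operating_points_from_input",
    "single_subunit",
    "two_layer",
    "add_multiplexing",
]

POSITION_CLASSES = ("proximal", "middle", "distal")


class ArchitectureError(ValueError):
    """Raised for structurally invalid hLN architectures."""


def sigmoid(y, theta: float = 0.0):
    """Logistic subunit nonlinearity ``1 / (1 + exp(-(y - theta)))``.

    The slope is fixed at 1: the effective gain of a subunit is set by the
    synaptic weights and couplings, not by the sigmoid itself.
    """
    out = expit(np.asarray(y, dtype=float) - theta)
    if np.ndim(out) == 0:
        return float(out)
    return out


def sigmoid_slope(y, theta: float = 0.0):
    """Derivative of :func:`sigmoid` with respect to its input."""
    s = sigmoid(y, theta)
    return s * (1.0 - s)


@dataclass
class SynapseGroup:
    """Synapses sharing one kernel parameter set per channel."""

    id: int
    members: list[int] = field(default_factory=list)
    position_class: str = "middle"

    def __post_init__(self) -> None:
        if self.position_class not in POSITION_CLASSES:
            raise ArchitectureError(
                f"position_class must be one of {POSITION_CLASSES}, got {self.position_class!r}"
            )


@dataclass
class Channel:
    """One processing channel of a subunit: per-group kernels + sigmoid."""

    kernels: dict[int, KernelParams] = field(default_factory=dict)
    theta: float = 0.0
    has_nonlinearity: bool = True

    def activation(self, y: np.ndarray) -> np.ndarray:
        if self.has_nonlinearity:
            return sigmoid(y, self.theta)
        return y

    def activation_slope(self, y: np.ndarray) -> np.ndarray:
        if self.has_nonlinearity:
            return sigmoid_slope(y, self.theta)
        return np.ones_like(np.asarray(y, dtype=float))

    def copy(self) -> "Channel":
        return Channel(
            kernels={g: replace(k) for g, k in self.kernels.items()},
            theta=self.theta,
            has_nonlinearity=self.has_nonlinearity,
        )


@dataclass
class Subunit:
    """One node of the hLN tree."""

    id: int
    parent_id: int | None
    channels: list[Channel]
    coupling: float = 1.0
    synapse_groups: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= len(self.channels) <= 2:
            raise ArchitectureError(
                f"subunit {self.id}: needs 1 or 2 channels, got {len(self.channels)}"
            )

    @property
    def multiplexed(self) -> bool:
        return len(self.channels) == 2

    def copy(self) -> "Subunit":
        return Subunit(
            id=self.id,
            parent_id=self.parent_id,
            channels=[ch.copy() for ch in self.channels],
            coupling=self.coupling,
            synapse_groups=list(self.synapse_groups),
        )


@dataclass
class HLNArchitecture:
    """Subunit tree + synapse assignment + output offset.

    ``synapse_assignment`` maps synapse id -> (subunit id, group id); it must
    agree with the group membership lists, which partition each subunit's
    synapses.
    """

    subunits: list[Subunit]
    groups: dict[int, SynapseGroup] = field(default_factory=dict)
    v0: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        ids = [s.id for s in self.subunits]
        if len(set(ids)) != len(ids):
            raise ArchitectureError("duplicate subunit ids")
        by_id = {s.id: s for s in self.subunits}
        roots = [s for s in self.subunits if s.parent_id is None]
        if len(roots) != 1:
            raise ArchitectureError(f"need exactly one root subunit, found {len(roots)}")
        for s in self.subunits:
            if s.parent_id is not None and s.parent_id not in by_id:
                raise ArchitectureError(f"subunit {s.id}: dangling parent {s.parent_id}")
        # cycle check via walk to root
        for s in self.subunits:
            seen = set()
            cur = s
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise ArchitectureError(f"cycle through subunit {cur.id}")
                seen.add(cur.id)
                cur = by_id[cur.parent_id]
        # groups belong to exactly one subunit; members unique
        owner: dict[int, int] = {}
        for s in self.subunits:
            for gid in s.synapse_groups:
                if gid not in self.groups:
                    raise ArchitectureError(f"subunit {s.id}: unknown group {gid}")
                if gid in owner:
                    raise ArchitectureError(f"group {gid} assigned to two subunits")
                owner[gid] = s.id
            for ch in s.channels:
                missing = set(s.synapse_groups) - set(ch.kernels)
                if missing:
                    raise ArchitectureError(
                        f"subunit {s.id}: channel missing kernels for groups {sorted(missing)}"
                    )
        seen_syn: set[int] = set()
        for gid, grp in self.groups.items():
            if gid not in owner:
                raise ArchitectureError(f"group {gid} not attached to any subunit")
            for syn in grp.members:
                if syn in seen_syn:
                    raise ArchitectureError(f"synapse {syn} in more than one group")
                seen_syn.add(syn)

    @property
    def root(self) -> Subunit:
        return next(s for s in self.subunits if s.parent_id is None)

    def subunit(self, subunit_id: int) -> Subunit:
        for s in self.subunits:
            if s.id == subunit_id:
                return s
        raise ArchitectureError(f"no subunit {subunit_id}")

    def children(self, subunit_id: int) -> list[Subunit]:
        return [s for s in self.subunits if s.parent_id == subunit_id]

    def group_owner(self, group_id: int) -> Subunit:
        for s in self.subunits:
            if group_id in s.synapse_groups:
                return s
        raise ArchitectureError(f"group {group_id} not attached")

    @property
    def synapse_assignment(self) -> dict[int, tuple[int, int]]:
        out: dict[int, tuple[int, int]] = {}
        for s in self.subunits:
            for gid in s.synapse_groups:
                for syn in self.groups[gid].members:
                    out[syn] = (s.id, gid)
        return out

    def topological_order(self) -> list[Subunit]:
        """Leaves first, root last."""
        order: list[Subunit] = []
        visited: set[int] = set()

        def visit(s: Subunit) -> None:
            for c in self.children(s.id):
                if c.id not in visited:
                    visit(c)
            visited.add(s.id)
            order.append(s)

        visit(self.root)
        if len(order) != len(self.subunits):
            raise ArchitectureError("disconnected subunits present")
        return order

    def check_assignment(self, spikes: SpikeTrainSet) -> None:
        assigned = set(self.synapse_assignment)
        offenders = [sid for sid in spikes.synapse_ids() if sid not in assigned]
        if offenders:
            raise ArchitectureError(f"unassigned synapses: {offenders[:20]}")

    def copy(self) -> "HLNArchitecture":
        return HLNArchitecture(
            subunits=[s.copy() for s in self.subunits],
            groups={
                g: SynapseGroup(grp.id, list(grp.members), grp.position_class)
                for g, grp in self.groups.items()
            },
            v0=self.v0,
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def kernel_dict(k: KernelParams) -> dict:
            d = {"w_fast": k.w_fast, "tau_fast": k.tau_fast, "delay": k.delay}
            if k.w_slow is not None:
                d["w_slow"] = k.w_slow
            if k.tau_slow is not None:
                d["tau_slow"] = k.tau_slow
            return d

        return {
            "v0": self.v0,
            "groups": [
                {
                    "id": g.id,
                    "members": list(map(int, g.members)),
                    "position_class": g.position_class,
                }
                for g in self.groups.values()
            ],
            "subunits": [
                {
                    "id": s.id,
                    "parent_id": s.parent_id,
                    "coupling": s.coupling,
                    "synapse_groups": list(s.synapse_groups),
                    "channels": [
                        {
                            "theta": ch.theta,
                            "has_nonlinearity": ch.has_nonlinearity,
                            "kernels": {str(g): kernel_dict(k) for g, k in ch.kernels.items()},
                        }
                        for ch in s.channels
                    ],
                }
                for s in self.subunits
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HLNArchitecture":
        groups = {
            int(g["id"]): SynapseGroup(
                int(g["id"]), [int(m) for m in g["members"]], g.get("position_class", "middle")
            )
            for g in d["groups"]
        }
        subunits = []
        for sd in d["subunits"]:
            channels = []
            for cd in sd["channels"]:
                kernels = {
                    int(g): KernelParams(
                        w_fast=float(k["w_fast"]),
                        tau_fast=float(k["tau_fast"]),
                        delay=float(k.get("delay", 0.0)),
                        w_slow=(None if k.get("w_slow") is None else float(k["w_slow"])),
                        tau_slow=(None if k.get("tau_slow") is None else float(k["tau_slow"])),
                    )
                    for g, k in cd["kernels"].items()
                }
                channels.append(
                    Channel(
                        kernels=kernels,
                        theta=float(cd.get("theta", 0.0)),
                        has_nonlinearity=bool(cd.get("has_nonlinearity", True)),
                    )
                )
            subunits.append(
                Subunit(
                    id=int(sd["id"]),
                    parent_id=(None if sd["parent_id"] is None else int(sd["parent_id"])),
                    channels=channels,
                    coupling=float(sd.get("coupling", 1.0)),
                    synapse_groups=[int(g) for g in sd.get("synapse_groups", [])],
                )
            )
        return cls(subunits=subunits, groups=groups, v0=float(d.get("v0", 0.0)))


# -- forward evaluation ----------------------------------------------------


def subunit_output(
    subunit: Subunit,
    filtered_inputs: dict[tuple[int, int], np.ndarray],
    child_input: np.ndarray | None = None,
) -> np.ndarray:
    """Output r_j(t) of one subunit.

    ``filtered_inputs`` maps (channel index, group id) to the already
    weighted filtered signal ``w * phi`` of that group in that channel;
    ``child_input`` is the summed, coupling-weighted output of the child
    subunits (added to channel 0).
    """
    out = None
    for ci, ch in enumerate(subunit.channels):
        y = None
        for gid in subunit.synapse_groups:
            sig = filtered_inputs.get((ci, gid))
            if sig is None:
                raise ArchitectureError(
                    f"subunit {subunit.id}: missing filtered input for channel {ci}, group {gid}"
                )
            y = sig.copy() if y is None else y + sig
        if ci == 0 and child_input is not None:
            y = child_input.copy() if y is None else y + child_input
        if y is None:
            raise ArchitectureError(f"subunit {subunit.id}: channel {ci} has no input")
        act = ch.activation(y)
        out = act if out is None else out + act
    return out


@dataclass
class ForwardState:
    """All intermediate signals of one forward sweep (used for gradients)."""

    v: np.ndarray
    # keyed by (subunit_id, channel_index)
    y: dict[tuple[int, int], np.ndarray]
    act: dict[tuple[int, int], np.ndarray]
    slope: dict[tuple[int, int], np.ndarray]
    # keyed by subunit_id
    r: dict[int, np.ndarray]
    # unweighted filtered signals keyed by (subunit_id, channel_index, group_id)
    phi: dict[tuple[int, int, int], dict[str, np.ndarray]]


def group_counts(arch: HLNArchitecture, spikes: SpikeTrainSet, grid: TimeGrid) -> dict[int, np.ndarray]:
    """Summed per-bin spike counts of each synapse group's members."""
    counts: dict[int, np.ndarray] = {}
    for gid, grp in arch.groups.items():
        c = np.zeros(grid.n_bins)
        for syn in grp.members:
            if syn in spikes.trains:
                c += bin_spikes(spikes[syn].times, grid)
        counts[gid] = c
    return counts


def evaluate(
    arch: HLNArchitecture,
    spikes: SpikeTrainSet,
    grid: TimeGrid,
    support_factor: float = DEFAULT_SUPPORT_FACTOR,
    counts: dict[int, np.ndarray] | None = None,
    extra_root_input: np.ndarray | None = None,
) -> ForwardState:
    """Leaf-to-root forward sweep returning all intermediate signals.

    ``counts`` may carry precomputed per-group binned spike counts (the fit
    loop reuses them across iterations).  ``extra_root_input`` is an
    additional signal summed into the root subunit's first channel (the
    spiking extension's adaptation term enters here).
    """
    arch.check_assignment(spikes)
    if counts is None:
        counts = group_counts(arch, spikes, grid)
    if extra_root_input is not None and extra_root_input.shape[0] != grid.n_bins:
        raise ValueError("extra_root_input length does not match the grid")

    y_map: dict[tuple[int, int], np.ndarray] = {}
    act_map: dict[tuple[int, int], np.ndarray] = {}
    slope_map: dict[tuple[int, int], np.ndarray] = {}
    r_map: dict[int, np.ndarray] = {}
    phi_map: dict[tuple[int, int, int], dict[str, np.ndarray]] = {}

    for s in arch.topological_order():
        child_input = None
        for c in arch.children(s.id):
            contrib = c.coupling * r_map[c.id]
            child_input = contrib if child_input is None else child_input + contrib
        out = None
        for ci, ch in enumerate(s.channels):
            y = np.zeros(grid.n_bins)
            for gid in s.synapse_groups:
                k = ch.kernels[gid]
                # unit-amplitude component signals; weights applied afterwards
                # so the fit loop can reuse them for w-gradients.  Components
                # keep the full kernel's truncation horizon so gradients and
                # forward values see identical truncation.
                kf = build_kernel(
                    k.copy(w_fast=1.0, w_slow=(0.0 if k.has_slow else None)),
                    grid,
                    support_factor,
                )
                phi_fast = convolve_counts(counts[gid], kf)
                comp = {"fast": phi_fast}
                y = y + k.w_fast * phi_fast
                if k.has_slow:
                    ks = build_kernel(k.copy(w_fast=0.0, w_slow=1.0), grid, support_factor)
                    phi_slow = convolve_counts(counts[gid], ks)
                    comp["slow"] = phi_slow
                    y = y + k.w_slow * phi_slow
                phi_map[(s.id, ci, gid)] = comp
            if ci == 0 and child_input is not None:
                y = y + child_input
            if ci == 0 and s.parent_id is None and extra_root_input is not None:
                y = y + extra_root_input
            y_map[(s.id, ci)] = y
            act = ch.activation(y)
            slope_map[(s.id, ci)] = ch.activation_slope(y)
            act_map[(s.id, ci)] = act
            out = act if out is None else out + act
        r_map[s.id] = out

    root = arch.root
    v = root.coupling * r_map[root.id] + arch.v0
    return ForwardState(v=v, y=y_map, act=act_map, slope=slope_map, r=r_map, phi=phi_map)


def forward(
    arch: HLNArchitecture,
    spikes: SpikeTrainSet,
    grid: TimeGrid,
    support_factor: float = DEFAULT_SUPPORT_FACTOR,
) -> np.ndarray:
    """Model somatic voltage v(t) (mV) in response to the input spikes."""
    return evaluate(arch, spikes, grid, support_factor).v


# -- parameter counting ----------------------------------------------------


def count_params_canonical(n_syn: int, m: int) -> int:
    """Parameter count of the canonical single-kernel nonlinear-output
    configuration: ``Np = 1 + 3*N_syn + 2*M`` (offset; amplitude, time
    constant and delay per independently fitted synapse group; coupling and
    threshold per subunit)."""
    return 1 + 3 * n_syn + 2 * m


def count_params(arch: HLNArchitecture) -> int:
    """Parameter count by explicit enumeration.

    Counts v0; one coupling per subunit; one threshold per nonlinear
    channel; and per (channel, group) kernel: amplitude + time constant +
    delay, plus one extra amplitude for a two-component kernel and one
    extra time constant when the slow component is not coupled to the fast
    one.  Reduces to ``1 + 3*N_syn + 2*M`` in the canonical configuration.
    """
    n = 1  # v0
    for s in arch.subunits:
        n += 1  # coupling
        for ch in s.channels:
            if ch.has_nonlinearity:
                n += 1  # theta
            for gid in s.synapse_groups:
                k = ch.kernels[gid]
                n += 3  # w_fast, tau_fast, delay
                if k.has_slow:
                    n += 1  # w_slow
                    if not k.coupled:
                        n += 1  # independent tau_slow
    return n


# -- somatic response amplitude (per-synapse gain) -------------------------


def operating_points_from_input(
    arch: HLNArchitecture,
    spikes: SpikeTrainSet,
    grid: TimeGrid,
    support_factor: float = DEFAULT_SUPPORT_FACTOR,
) -> dict[tuple[int, int], float]:
    """Mean total input of every (subunit, channel) under the given spikes.

    Used as the operating point at which subunit gains (sigmoid slopes) are
    evaluated for per-synapse somatic amplitudes.
    """
    state = evaluate(arch, spikes, grid, support_factor)
    return {key: float(np.mean(y)) for key, y in state.y.items()}


def synapse_amplitude(
    arch: HLNArchitecture,
    synapse_id: int,
    operating_points: dict[tuple[int, int], float] | None = None,
) -> float:
    """Somatic response amplitude a_ji of one synapse (mV).

    The amplitude is the synaptic weight multiplied by the gain of every
    subunit on the path to the root: ``a = w * prod_k c_k * r'_k``, with the
    sigmoid slopes r' evaluated at the supplied operating points (the mean
    of each channel's total-input distribution; linear channels have slope
    1).  Without operating points all slopes are taken at the sigmoid
    midpoint (0.25) for nonlinear channels.

    For two-component kernels the amplitude uses ``w_fast + w_slow``; for
    multiplexed subunits contributions through both channels are summed.
    """
    assignment = arch.synapse_assignment
    if synapse_id not in assignment:
        raise ArchitectureError(f"synapse {synapse_id} not assigned in this architecture")
    sub_id, gid = assignment[synapse_id]
    sub = arch.subunit(sub_id)

    def channel_slope(s: Subunit, ci: int) -> float:
        ch = s.channels[ci]
        if not ch.has_nonlinearity:
            return 1.0
        if operating_points is None:
            return 0.25
        y = operating_points[(s.id, ci)]
        return float(sigmoid_slope(np.asarray(y), ch.theta))

    total = 0.0
    for ci, ch in enumerate(sub.channels):
        k = ch.kernels[gid]
        w = k.w_fast + (k.w_slow or 0.0)
        gain = sub.coupling * channel_slope(sub, ci)
        # ancestors: child output always enters the parent's first channel
        cur = sub
        while cur.parent_id is not None:
            parent = arch.subunit(cur.parent_id)
            gain *= parent.coupling * channel_slope(parent, 0)
            cur = parent
        total += w * gain
    return total


# -- architecture builders -------------------------------------------------


def _default_exc_kernel(double: bool) -> KernelParams:
    if double:
        return KernelParams(w_fast=0.2, tau_fast=2.0, w_slow=0.1)
    return KernelParams(w_fast=0.2, tau_fast=5.0)


def _default_inh_kernel() -> KernelParams:
    return KernelParams(w_fast=-0.2, tau_fast=8.0)


def single_subunit(
    exc_ids: list[int],
    inh_ids: list[int],
    *,
    nonlinear: bool = False,
    double_exc_kernel: bool = False,
    exc_kernel: KernelParams | None = None,
    inh_kernel: KernelParams | None = None,
    v0: float = 0.0,
    theta: float = 0.0,
    coupling: float = 1.0,
) -> HLNArchitecture:
    """One-subunit hLN: all excitation in one group, all inhibition in
    another, with a linear or global-nonlinear output."""
    groups: dict[int, SynapseGroup] = {}
    kernels: dict[int, KernelParams] = {}
    gid = 0
    if exc_ids:
        groups[gid] = SynapseGroup(gid, list(exc_ids))
        kernels[gid] = exc_kernel or _default_exc_kernel(double_exc_kernel)
        gid += 1
    if inh_ids:
        groups[gid] = SynapseGroup(gid, list(inh_ids))
        kernels[gid] = inh_kernel or _default_inh_kernel()
    sub = Subunit(
        id=0,
        parent_id=None,
        channels=[Channel(kernels=kernels, theta=theta, has_nonlinearity=nonlinear)],
        coupling=coupling,
        synapse_groups=sorted(groups),
    )
    return HLNArchitecture(subunits=[sub], groups=groups, v0=v0)


def two_layer(
    child_exc_ids: list[list[int]],
    inh_ids: list[int],
    *,
    nonlinear_root: bool = False,
    nonlinear_children: bool = True,
    double_exc_kernel: bool = False,
    v0: float = 0.0,
) -> HLNArchitecture:
    """Root subunit (holding the inhibitory group) with one nonlinear child
    subunit per excitatory cluster."""
    groups: dict[int, SynapseGroup] = {}
    subunits: list[Subunit] = []
    gid = 0
    root_groups: list[int] = []
    if inh_ids:
        groups[gid] = SynapseGroup(gid, list(inh_ids))
        root_groups = [gid]
        root_kernels = {gid: _default_inh_kernel()}
        gid += 1
    else:
        root_kernels = {}
    subunits.append(
        Subunit(
            id=0,
            parent_id=None,
            channels=[Channel(kernels=root_kernels, theta=0.0, has_nonlinearity=nonlinear_root)],
            coupling=1.0,
            synapse_groups=root_groups,
        )
    )
    for j, ids in enumerate(child_exc_ids, start=1):
        groups[gid] = SynapseGroup(gid, list(ids))
        subunits.append(
            Subunit(
                id=j,
                parent_id=0,
                channels=[
                    Channel(
                        kernels={gid: _default_exc_kernel(double_exc_kernel)},
                        theta=0.0,
                        has_nonlinearity=nonlinear_children,
                    )
                ],
                coupling=1.0,
                synapse_groups=[gid],
            )
        )
        gid += 1
    return HLNArchitecture(subunits=subunits, groups=groups, v0=v0)


def add_multiplexing(arch: HLNArchitecture, second_channel_scale: float = 0.1) -> HLNArchitecture:
    """Clone every subunit's channel into a second parallel channel.

    The clone starts with down-scaled weights (and a slower fast time
    constant) so the multiplexed model initially reproduces the original one
    closely while giving the optimizer an asymmetric starting point.
    """
    out = arch.copy()
    for s in out.subunits:
        if s.multiplexed:
            continue
        base = s.channels[0]
        clone = base.copy()
        for k in clone.kernels.values():
            k.w_fast *= second_channel_scale
            if k.w_slow is not None:
                k.w_slow *= second_channel_scale
            k.tau_fast *= 3.0
        s.channels = [base, clone]
    out.validate()
    return out
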