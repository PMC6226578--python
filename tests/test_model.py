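"""Architecture validation, forward evaluation, parameter counting."""

import numpy as np
import pytest

from hln.model import (
    ArchitectureError,
    Channel,
    HLNArchitecture,
    Subunit,
    SynapseGroup,
    add_multiplexing,
    count_params,
    count_params_canonical,
    evaluate,
    forward,
    operating_points_from_input,
    sigmoid,
    sigmoid_slope,
    single_subunit,
    subunit_output,
    synapse_amplitude,
    two_layer,
)
from hln.signals import KernelParams, SpikeTrain, SpikeTrainSet, TimeGrid, convolve_spikes

from .conftest import random_spike_set


class TestSigmoid:
    def test_midpoint_limits_monotonicity(self):
        assert sigmoid(3.0, theta=3.0) == pytest.approx(0.5)
        assert sigmoid(500.0, theta=0.0) == pytest.approx(1.0)
        assert sigmoid(-500.0, theta=0.0) == pytest.approx(0.0)
        y = np.linspace(-10, 10, 201)
        assert np.all(np.diff(sigmoid(y, theta=1.3)) > 0)

    def test_midpoint_slope_is_quarter(self):
        assert sigmoid_slope(0.0, theta=0.0) == pytest.approx(0.25)


class TestSubunitOutput:
    def test_linear_channel_passes_summed_input(self, grid):
        sub = Subunit(
            id=0, parent_id=None,
            channels=[Channel(kernels={0: KernelParams(1.0, 5.0)}, has_nonlinearity=False)],
            synapse_groups=[0],
        )
        sig = np.sin(np.linspace(0, 10, grid.n_bins))
        out = subunit_output(sub, {(0, 0): sig})
        np.testing.assert_allclose(out, sig)

    def test_zero_input_nonlinear_gives_half(self, grid):
        sub = Subunit(
            id=0, parent_id=None,
            channels=[Channel(kernels={0: KernelParams(1.0, 5.0)}, theta=0.0)],
            synapse_groups=[0],
        )
        out = subunit_output(sub, {(0, 0): np.zeros(grid.n_bins)})
        np.testing.assert_allclose(out, 0.5)

    def test_duplicate_channels_double_the_output(self, grid):
        ch = Channel(kernels={0: KernelParams(1.0, 5.0)}, theta=0.4)
        sig = {(0, 0): np.cos(np.linspace(0, 7, grid.n_bins)), (1, 0): None}
        single = Subunit(id=0, parent_id=None, channels=[ch], synapse_groups=[0])
        duo = Subunit(id=0, parent_id=None, channels=[ch, ch.copy()], synapse_groups=[0])
        one = subunit_output(single, {(0, 0): sig[(0, 0)]})
        two = subunit_output(duo, {(0, 0): sig[(0, 0)], (1, 0): sig[(0, 0)]})
        np.testing.assert_allclose(two, 2 * one)


class TestForward:
    def test_no_spikes_zero_kernels_gives_offset(self, grid):
        arch = single_subunit([0], [], nonlinear=False,
                              exc_kernel=KernelParams(0.0, 5.0), v0=-70.0)
        ss = SpikeTrainSet({0: SpikeTrain([])})
        np.testing.assert_allclose(forward(arch, ss, grid), -70.0)

    def test_single_spike_linear_root_is_shifted_kernel(self, grid):
        k = KernelParams(w_fast=0.8, tau_fast=6.0, delay=2.0)
        arch = single_subunit([0], [], nonlinear=False, exc_kernel=k,
                              v0=-70.0, coupling=1.0)
        tr = SpikeTrain([100.0])
        ss = SpikeTrainSet({0: tr})
        v = forward(arch, ss, grid)
        np.testing.assert_allclose(v, -70.0 + convolve_spikes(tr, k, grid), atol=1e-12)

    def test_zero_coupling_child_is_invisible(self, grid, rng):
        ss = random_spike_set(rng, 4, 2, grid.duration)
        exc, inh = ss.excitatory_ids(), ss.inhibitory_ids()
        nested = two_layer([exc[:2], exc[2:]], inh, nonlinear_root=False, v0=-70.0)
        nested.subunits[2].coupling = 0.0  # second child silenced
        pruned = nested.copy()
        for k in pruned.subunits[2].channels[0].kernels.values():
            k.w_fast = 0.0
        np.testing.assert_allclose(
            forward(nested, ss, grid), forward(pruned, ss, grid), atol=1e-12
        )

    def test_unassigned_synapse_is_reported(self, grid):
        arch = single_subunit([0], [], nonlinear=False)
        ss = SpikeTrainSet({0: SpikeTrain([1.0]), 7: SpikeTrain([2.0])})
        with pytest.raises(ArchitectureError, match="7"):
            forward(arch, ss, grid)

    def test_invariant_to_subunit_list_order(self, grid, rng):
        ss = random_spike_set(rng, 4, 0, grid.duration)
        arch = two_layer([[0, 1], [2, 3]], [], nonlinear_root=True, v0=-70.0)
        v1 = forward(arch, ss, grid)
        shuffled = HLNArchitecture(
            subunits=[s.copy() for s in arch.subunits[::-1]],
            groups=arch.copy().groups, v0=arch.v0,
        )
        np.testing.assert_allclose(forward(shuffled, ss, grid), v1, atol=1e-12)

    def test_nested_model_reproduced_with_extra_silent_subunit(self, grid, rng):
        """An (M+1)-subunit model with the extra subunit's weights zeroed and
        output linear reproduces the M-subunit model exactly."""
        ss = random_spike_set(rng, 4, 2, grid.duration)
        base = single_subunit(ss.excitatory_ids(), ss.inhibitory_ids(),
                              nonlinear=True, v0=-70.0, theta=0.5)
        small = forward(base, ss, grid)
        # same synapses plus an extra child with zero kernels, linear output
        groups = base.copy().groups
        gid_extra = max(groups) + 1
        groups[gid_extra] = SynapseGroup(gid_extra, [])
        root = base.subunits[0].copy()
        root.synapse_groups = sorted(base.groups)
        extra = Subunit(
            id=1, parent_id=0,
            channels=[Channel(kernels={gid_extra: KernelParams(0.0, 5.0)},
                              has_nonlinearity=False)],
            coupling=0.7, synapse_groups=[gid_extra],
        )
        big = HLNArchitecture(subunits=[root, extra], groups=groups, v0=base.v0)
        np.testing.assert_allclose(forward(big, ss, grid), small, atol=1e-12)


class TestValidation:
    def test_dangling_parent(self):
        with pytest.raises(ArchitectureError, match="dangling"):
            HLNArchitecture(
                subunits=[
                    Subunit(id=0, parent_id=None, channels=[Channel()]),
                    Subunit(id=1, parent_id=5, channels=[Channel()]),
                ],
                groups={},
            )

    def test_two_roots(self):
        with pytest.raises(ArchitectureError, match="root"):
            HLNArchitecture(
                subunits=[
                    Subunit(id=0, parent_id=None, channels=[Channel()]),
                    Subunit(id=1, parent_id=None, channels=[Channel()]),
                ],
                groups={},
            )

    def test_synapse_in_two_groups(self):
        groups = {0: SynapseGroup(0, [1, 2]), 1: SynapseGroup(1, [2])}
        ker = {0: KernelParams(1.0, 5.0), 1: KernelParams(1.0, 5.0)}
        with pytest.raises(ArchitectureError, match="more than one group"):
            HLNArchitecture(
                subunits=[Subunit(id=0, parent_id=None,
                                  channels=[Channel(kernels=ker)],
                                  synapse_groups=[0, 1])],
                groups=groups,
            )


class TestCountParams:
    @pytest.mark.parametrize("n_syn,m,expected", [(1, 1, 6), (13, 1, 42), (0, 1, 3)])
    def test_canonical_formula(self, n_syn, m, expected):
        assert count_params_canonical(n_syn, m) == expected

    def test_enumeration_matches_canonical_single_kernel_nonlinear(self):
        arch = single_subunit([0, 1], [2], nonlinear=True)
        # 2 groups, 1 subunit, single kernels, nonlinear output
        assert count_params(arch) == count_params_canonical(2, 1)

    def test_enumeration_counts_extra_kernel_components(self):
        plain = single_subunit([0], [1], nonlinear=True)
        double = single_subunit([0], [1], nonlinear=True, double_exc_kernel=True)
        # coupled slow component adds exactly one amplitude parameter
        assert count_params(double) == count_params(plain) + 1

    def test_linear_output_drops_threshold(self):
        nl = single_subunit([0], [1], nonlinear=True)
        lin = single_subunit([0], [1], nonlinear=False)
        assert count_params(nl) == count_params(lin) + 1


class TestSynapseAmplitude:
    def test_all_linear_is_weight_times_couplings(self, grid):
        arch = two_layer([[0], [1]], [], nonlinear_root=False,
                         nonlinear_children=False, v0=0.0)
        arch.subunits[1].coupling = 0.5
        arch.subunits[0].coupling = 2.0
        k = arch.subunits[1].channels[0].kernels
        gid = next(iter(k))
        k[gid].w_fast = 0.3
        assert synapse_amplitude(arch, 0) == pytest.approx(0.3 * 0.5 * 2.0)

    def test_zero_weight_zero_amplitude(self):
        arch = single_subunit([0], [], nonlinear=True,
                              exc_kernel=KernelParams(0.0, 5.0))
        assert synapse_amplitude(arch, 0) == 0.0

    def test_nonlinear_midpoint_slope_matches_numeric_derivative(self, grid):
        # at the threshold operating point the sigmoid gain is ~0.25,
        # independently verified by numerically differentiating the sigmoid
        arch = single_subunit([0], [], nonlinear=True,
                              exc_kernel=KernelParams(0.4, 5.0), theta=1.0,
                              coupling=1.7)
        ops = {(0, 0): 1.0}
        eps = 1e-6
        num_slope = (sigmoid(1.0 + eps, 1.0) - sigmoid(1.0 - eps, 1.0)) / (2 * eps)
        assert synapse_amplitude(arch, 0, ops) == pytest.approx(0.4 * 1.7 * num_slope)

    def test_unknown_synapse_raises(self):
        arch = single_subunit([0], [], nonlinear=True)
        with pytest.raises(ArchitectureError):
            synapse_amplitude(arch, 99)


class TestSerialization:
    def test_dict_round_trip(self, grid, rng):
        ss = random_spike_set(rng, 4, 2, grid.duration)
        arch = two_layer([[0, 1], [2, 3]], [4, 5], nonlinear_root=True,
                         double_exc_kernel=True, v0=-68.5)
        arch.subunits[1].coupling = 0.37
        arch.subunits[0].channels[0].theta = 1.2
        back = HLNArchitecture.from_dict(arch.to_dict())
        np.testing.assert_allclose(
            forward(back, ss, grid), forward(arch, ss, grid), atol=1e-14
        )

    def test_multiplexed_round_trip(self, grid, rng):
        ss = random_spike_set(rng, 3, 1, grid.duration)
        arch = add_multiplexing(
            single_subunit(ss.excitatory_ids(), ss.inhibitory_ids(), nonlinear=True)
        )
        assert arch.subunits[0].multiplexed
        back = HLNArchitecture.from_dict(arch.to_dict())
        np.testing.assert_allclose(
            forward(back, ss, grid), forward(arch, ss, grid), atol=1e-14
        )


class TestOperatingPoints:
    def test_means_of_filtered_input(self, grid, rng):
        ss = random_spike_set(rng, 4, 2, grid.duration)
        arch = single_subunit(ss.excitatory_ids(), ss.inhibitory_ids(), nonlinear=True)
        ops = operating_points_from_input(arch, ss, grid)
        state = evaluate(arch, ss, grid)
        assert ops[(0, 0)] == pytest.approx(float(np.mean(state.y[(0, 0)])))
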