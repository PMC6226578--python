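"""Loss, gradients, pretuning, and the staged fitting procedure."""

import numpy as np
import pytest

from hln.fitting import (
    FitConfig,
    Parameterization,
    PriorSpec,
    fit,
    fit_stage_coupled,
    loss,
    pretune_nonlinearities,
    slice_grid,
    slice_spikes,
)
from hln.model import (
    evaluate,
    forward,
    operating_points_from_input,
    single_subunit,
    synapse_amplitude,
    two_layer,
)
from hln.signals import KernelParams, SpikeTrain, SpikeTrainSet, TimeGrid

from .conftest import random_spike_set


def make_linear_truth(exc_ids, inh_ids):
    return single_subunit(
        exc_ids, inh_ids, nonlinear=False, v0=-70.0,
        exc_kernel=KernelParams(w_fast=0.25, tau_fast=4.0),
        inh_kernel=KernelParams(w_fast=-0.2, tau_fast=9.0),
    )


class TestLoss:
    def test_perfect_prediction_zero_loss(self, grid, rng):
        ss = random_spike_set(rng, 3, 1, grid.duration)
        arch = make_linear_truth(ss.excitatory_ids(), ss.inhibitory_ids())
        target = forward(arch, ss, grid)
        assert loss(arch, ss, target, grid) == pytest.approx(0.0, abs=1e-20)

    def test_constant_offset_squared(self, grid, rng):
        ss = random_spike_set(rng, 3, 1, grid.duration)
        arch = make_linear_truth(ss.excitatory_ids(), ss.inhibitory_ids())
        target = forward(arch, ss, grid) + 1.0
        assert loss(arch, ss, target, grid) == pytest.approx(1.0)

    def test_grid_mismatch_raises(self, grid, rng):
        ss = random_spike_set(rng, 2, 0, grid.duration)
        arch = make_linear_truth(ss.excitatory_ids(), [])
        with pytest.raises(ValueError):
            loss(arch, ss, np.zeros(grid.n_bins + 5), grid)


class TestGradient:
    @pytest.mark.parametrize("tie,with_prior", [
        ("none", False), ("none", True), ("subunit", False), ("population", False),
    ])
    def test_matches_central_finite_differences(self, tie, with_prior):
        """Analytic gradient agrees with central differences to 1e-5
        relative on every parameter class (amplitudes, log-taus,
        log-couplings, thresholds, offset)."""
        rng = np.random.default_rng(11)
        g = TimeGrid(dt=1.0, n_bins=1500)
        ss = random_spike_set(rng, 5, 2, g.duration)
        arch = two_layer(
            [[0, 1], [2, 3, 4]], [5, 6], nonlinear_root=True,
            double_exc_kernel=True, v0=-66.0,
        )
        for s in arch.subunits:
            s.coupling = 0.9 + 0.05 * s.id
            s.channels[0].theta = 0.2
        prior = None
        if with_prior:
            prior = PriorSpec.from_kernels({
                "excitatory": KernelParams(0.2, 2.0, w_slow=0.1),
                "inhibitory": KernelParams(-0.2, 8.0),
            })
        target = rng.normal(-66, 1.5, g.n_bins)
        p = Parameterization(arch, ss, g, tie=tie, prior=prior)
        x0 = p.pack() + rng.normal(0, 0.05, p.n_params)
        _, grad = p.loss_and_grad(x0, target)
        eps = 1e-6
        for i in range(p.n_params):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (p.loss(xp, target) - p.loss(xm, target)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-9), f"param {i}"


class TestCoupledStage:
    def test_recovers_generating_kernels_noiseless(self):
        rng = np.random.default_rng(5)
        g = TimeGrid(dt=1.0, n_bins=20000)
        ss = random_spike_set(rng, 10, 5, g.duration, rate_hz=8.0)
        truth = make_linear_truth(ss.excitatory_ids(), ss.inhibitory_ids())
        target = forward(truth, ss, g)
        res = fit_stage_coupled(ss, target, g, FitConfig())
        fitted = res.arch.subunits[0].channels[0].kernels
        true_k = truth.subunits[0].channels[0].kernels
        for gid in true_k:
            assert fitted[gid].w_fast == pytest.approx(true_k[gid].w_fast, rel=1e-3)
            assert fitted[gid].tau_fast == pytest.approx(true_k[gid].tau_fast, rel=1e-3)
        assert res.arch.v0 == pytest.approx(-70.0, abs=1e-3)

    def test_zero_target_drives_amplitudes_to_zero(self, grid, rng):
        ss = random_spike_set(rng, 4, 2, grid.duration)
        target = np.zeros(grid.n_bins)
        res = fit_stage_coupled(ss, target, grid, FitConfig())
        for k in res.arch.subunits[0].channels[0].kernels.values():
            assert abs(k.w_fast) < 1e-4
        assert abs(res.arch.v0) < 1e-4

    def test_descent_property(self, grid, rng):
        ss = random_spike_set(rng, 4, 2, grid.duration)
        target = rng.normal(-70, 1, grid.n_bins)
        res = fit_stage_coupled(ss, target, grid, FitConfig())
        init = single_subunit(ss.excitatory_ids(), ss.inhibitory_ids(),
                              nonlinear=False, v0=float(np.mean(target)))
        assert res.train_mse <= loss(init, ss, target, grid) + 1e-12


class TestPretune:
    @pytest.fixture
    def setup(self):
        rng = np.random.default_rng(21)
        g = TimeGrid(dt=1.0, n_bins=12000)
        ss = random_spike_set(rng, 8, 4, g.duration)
        arch = two_layer([[0, 1, 2, 3], [4, 5, 6, 7]],
                         ss.inhibitory_ids(), nonlinear_root=True, v0=-70.0)
        return g, ss, arch

    @pytest.mark.parametrize("rho", [1, 2, 4, 8])
    def test_input_distribution_centered_with_sd_one_over_rho(self, setup, rho):
        g, ss, arch = setup
        tuned = pretune_nonlinearities(arch, rho, ss, g)
        state = evaluate(tuned, ss, g)
        for s in tuned.subunits:
            ch = s.channels[0]
            if not ch.has_nonlinearity:
                continue
            y = state.y[(s.id, 0)]
            assert float(np.mean(y)) == pytest.approx(ch.theta, abs=0.02 / rho)
            assert float(np.std(y)) == pytest.approx(1.0 / rho, rel=0.02)

    def test_somatic_amplitudes_preserved(self, setup):
        g, ss, arch = setup
        lin = arch.copy()
        for s in lin.subunits:
            s.channels[0].has_nonlinearity = False
        tuned = pretune_nonlinearities(arch, 3.0, ss, g)
        ops = operating_points_from_input(tuned, ss, g)
        for sid in ss.synapse_ids():
            before = synapse_amplitude(lin, sid)
            after = synapse_amplitude(tuned, sid, ops)
            assert after == pytest.approx(before, rel=0.01)

    def test_large_rho_approaches_linear_model_pointwise(self, setup):
        g, ss, arch = setup
        lin = arch.copy()
        for s in lin.subunits:
            s.channels[0].has_nonlinearity = False
        v_lin = forward(lin, ss, g)
        err = []
        for rho in (10.0, 100.0):
            v_nl = forward(pretune_nonlinearities(arch, rho, ss, g), ss, g)
            err.append(float(np.max(np.abs(v_nl - v_lin))))
        assert err[1] < err[0]
        assert err[1] < 1e-3

    def test_zero_variance_input_raises(self, grid):
        ss = SpikeTrainSet({0: SpikeTrain([])})
        arch = single_subunit([0], [], nonlinear=True)
        with pytest.raises(ValueError, match="degenerate"):
            pretune_nonlinearities(arch, 2.0, ss, grid)


class TestStagedFit:
    def test_stage_losses_non_increasing(self):
        rng = np.random.default_rng(3)
        g = TimeGrid(dt=1.0, n_bins=12000)
        ss = random_spike_set(rng, 8, 4, g.duration)
        truth = make_linear_truth(ss.excitatory_ids(), ss.inhibitory_ids())
        target = forward(truth, ss, g) + rng.normal(0, 0.05, g.n_bins)
        arch = single_subunit(ss.excitatory_ids(), ss.inhibitory_ids(), nonlinear=True)
        res = fit(ss, target, g, arch, FitConfig(rho_grid=(2, 6)))
        losses = list(res.stage_losses.values())
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))
        assert res.variance_explained is not None

    def test_positivity_preserved(self):
        rng = np.random.default_rng(9)
        g = TimeGrid(dt=1.0, n_bins=8000)
        ss = random_spike_set(rng, 6, 2, g.duration)
        truth = make_linear_truth(ss.excitatory_ids(), ss.inhibitory_ids())
        target = forward(truth, ss, g)
        arch = single_subunit(ss.excitatory_ids(), ss.inhibitory_ids(), nonlinear=True)
        res = fit(ss, target, g, arch, FitConfig(rho_grid=(2,)))
        for s in res.arch.subunits:
            assert s.coupling > 0
            for ch in s.channels:
                for k in ch.kernels.values():
                    assert k.tau_fast > 0
                    assert k.delay >= 0

    def test_variance_explained_stable_across_data_seeds(self):
        """Well-conditioned synthetic data: VE spread across independently
        generated datasets stays under one percentage point."""
        ves = []
        for seed in (101, 202):
            rng = np.random.default_rng(seed)
            g = TimeGrid(dt=1.0, n_bins=12000)
            ss = random_spike_set(rng, 8, 4, g.duration)
            truth = make_linear_truth(ss.excitatory_ids(), ss.inhibitory_ids())
            target = forward(truth, ss, g)
            arch = single_subunit(ss.excitatory_ids(), ss.inhibitory_ids(),
                                  nonlinear=True)
            res = fit(ss, target, g, arch, FitConfig(rho_grid=(2, 6), seed=seed))
            ves.append(res.variance_explained)
        assert abs(ves[0] - ves[1]) < 0.01


class TestSlicing:
    def test_slice_preserves_and_shifts(self, grid, rng):
        ss = random_spike_set(rng, 3, 1, grid.duration)
        sub = slice_spikes(ss, grid, 500, 1500)
        g2 = slice_grid(grid, 500, 1500)
        assert g2.n_bins == 1000
        for sid, tr in sub.items():
            if len(tr):
                assert tr.times.min() >= 0 and tr.times.max() < g2.duration
            orig = ss[sid].times
            n_in_window = int(((orig >= 500) & (orig < 1500)).sum())
            assert len(tr) == n_in_window
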