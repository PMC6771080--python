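"""Pennes solver: perfusion model, steady states, transient oracles, conservation."""

import numpy as np
import pytest

from conftest import uniform_block
from mfhplan.bioheat import (
    BioheatParams,
    PerfusionModel,
    StabilityError,
    _Discretisation,
    mnp_source_map,
    simulate,
    steady_state,
    tumour_perfusion,
)
from mfhplan.phantom import (
    Label,
    PhantomConfig,
    PhantomError,
    TissueProperties,
    builtin_tissue_table,
    embed_tumour,
    generate_phantom,
)

MUSCLE = builtin_tissue_table()[Label.MUSCLE]


class TestTumourPerfusion:
    def test_baseline(self):
        assert tumour_perfusion(37.0) == pytest.approx(0.832, abs=1e-12)

    def test_high_temperature_asymptote(self):
        assert tumour_perfusion(60.0) == pytest.approx(0.416, abs=1e-9)
        assert tumour_perfusion(1000.0) == 0.416

    def test_non_increasing_above_baseline(self):
        T = np.linspace(37.0, 50.0, 200)
        w = tumour_perfusion(T)
        assert np.all(np.diff(w) <= 0)
        assert np.all(w >= 0.416 - 1e-12)

    def test_configurable_exponent(self):
        model = PerfusionModel(power=2.0, denom=10.0)
        assert tumour_perfusion(38.0, model) == pytest.approx(
            0.416 + 0.416 * np.exp(-0.1), rel=1e-12
        )


class TestSteadyState:
    def test_uniform_insulated_balance(self, muscle_block, insulated_params):
        """With only metabolic heat, T settles at Tb + rho*HGR/HTR everywhere."""
        T = steady_state(muscle_block, insulated_params)
        expected = 37.0 + MUSCLE.rho * MUSCLE.hgr / MUSCLE.htr
        np.testing.assert_allclose(T, expected, rtol=1e-8)
        assert expected - 37.0 == pytest.approx(0.365, abs=0.001)

    def test_no_metabolism_rests_at_blood_temperature(self, insulated_params):
        props = TissueProperties(1000.0, 0.3, 3500.0, 0.5, 0.0, 2500.0)
        ph = uniform_block(props=props)
        T = steady_state(ph, insulated_params)
        np.testing.assert_allclose(T, 37.0, atol=1e-9)

    def test_singular_without_any_coupling(self, insulated_params):
        props = TissueProperties(1000.0, 0.0, 3500.0, 0.5, 0.0, 0.0)
        ph = uniform_block(props=props)
        with pytest.raises(RuntimeError, match="singular"):
            steady_state(ph, insulated_params)

    def test_1d_slab_linear_profile(self):
        """Conduction-only slab between two fixed temperatures is linear in z."""
        props = TissueProperties(1000.0, 0.3, 3500.0, 0.5, 0.0, 0.0)
        n = 10
        labels = np.full((n, n, n + 2), Label.MUSCLE, dtype=np.uint8)
        labels[:, :, -2:] = Label.EXTERIOR  # air above the slab
        from mfhplan.phantom import VoxelPhantom

        ph = VoxelPhantom(labels, 2.0e-3, {Label.MUSCLE: props})
        # bottom clamped at Tb, top strongly convected to T_ext: near-Dirichlet
        params = BioheatParams(h_conv=1e8, T_ext=25.0, chest_wall="dirichlet",
                               perfusion=PerfusionModel(kind="constant"))
        T = steady_state(ph, params)
        profile = T[5, 5, :n]
        assert profile[0] == pytest.approx(37.0)
        assert profile[-1] == pytest.approx(25.0, abs=0.05)
        # straight line to solver tolerance (strong-Robin conditioning)
        assert np.abs(np.diff(profile, 2)).max() < 1e-3


class TestSimulate:
    def test_fixed_point_without_sources(self, muscle_block, insulated_params):
        T0 = steady_state(muscle_block, insulated_params)
        run = simulate(muscle_block, T0, None, insulated_params, duration=30.0)
        assert np.nanmax(np.abs(run.final - T0)) < 1e-9

    def test_lumped_heating_without_perfusion(self, insulated_params):
        """Insulated block, no perfusion: T rises linearly at Q/(rho c)."""
        props = TissueProperties(1000.0, 0.3, 3500.0, 0.5, 0.0, 0.0)
        ph = uniform_block(props=props)
        Q = 4.0e4
        run = simulate(ph, np.full(ph.shape, 37.0), np.full(ph.shape, Q),
                       insulated_params, duration=120.0)
        expected = 37.0 + Q * 120.0 / (1000.0 * 3500.0)
        np.testing.assert_allclose(run.final, expected, rtol=1e-12)

    def test_lumped_exponential_approach(self, muscle_block, insulated_params):
        """Uniform block with perfusion and source follows the scalar ODE."""
        T0 = steady_state(muscle_block, insulated_params)
        Q = 5.0e4
        duration = 600.0
        run = simulate(muscle_block, T0, np.full(muscle_block.shape, Q),
                       insulated_params, duration=duration)
        rc = MUSCLE.rho * MUSCLE.c
        T_inf = 37.0 + (MUSCLE.rho * MUSCLE.hgr + Q) / MUSCLE.htr
        expected = T_inf + (T0[5, 5, 5] - T_inf) * np.exp(-MUSCLE.htr * duration / rc)
        assert run.final[5, 5, 5] == pytest.approx(expected, abs=1e-3 * (expected - 37.0))

    def test_energy_balance_each_step(self, muscle_block):
        """d/dt of thermal energy equals boundary flux + volumetric sources."""
        params = BioheatParams(h_conv=15.0, T_ext=22.0, chest_wall="insulated",
                               perfusion=PerfusionModel(kind="constant"), dt=0.5)
        disc = _Discretisation(muscle_block, params)
        T0 = steady_state(muscle_block, params)
        src = np.full(muscle_block.shape, 1.0e4)
        run = simulate(muscle_block, T0, src, params, duration=5.0, save_every=0.5)
        h3 = muscle_block.spacing**3
        for a, b in zip(run.snapshots[:-1], run.snapshots[1:]):
            lhs = np.sum(disc.rho_c * (b - a)) * h3 / params.dt
            rhs = np.sum(disc.rhs(a, src)) * h3
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_step_refinement_convergence(self, muscle_block, insulated_params):
        from dataclasses import replace

        T0 = steady_state(muscle_block, insulated_params)
        src = np.full(muscle_block.shape, 3.0e4)
        coarse = simulate(muscle_block, T0, src, replace(insulated_params, dt=1.0), duration=60.0)
        fine = simulate(muscle_block, T0, src, replace(insulated_params, dt=0.1), duration=60.0)
        assert np.nanmax(np.abs(coarse.final - fine.final)) < 5e-3

    def test_unstable_step_rejected(self, muscle_block, insulated_params):
        from dataclasses import replace

        params = replace(insulated_params, dt=1.0e3)
        with pytest.raises(StabilityError, match="stability"):
            simulate(muscle_block, np.full(muscle_block.shape, 37.0), None, params, duration=10.0)

    def test_tumour_heating_monotone_in_concentration(self):
        """More ferrofluid never lowers the tumour-centre temperature."""
        ph = generate_phantom(PhantomConfig(grid=32, spacing=4.0e-3), seed=1)
        ph = embed_tumour(ph, (0.064, 0.064, 0.045), 2e-6)
        params = BioheatParams(dt=2.0)
        T0 = steady_state(ph, params)
        disc = _Discretisation(ph, params)
        finals = []
        for phi in (0.35, 0.5, 1.0):
            src = mnp_source_map(ph, 243.0e3 * phi)
            run = simulate(ph, T0, src, params, duration=120.0)
            finals.append(run.final[disc.tumour_centre_idx])
        assert finals[0] < finals[1] < finals[2]


class TestSourceMap:
    def test_uniform_on_tumour_only(self):
        ph = generate_phantom(PhantomConfig(grid=32, spacing=4.0e-3), seed=1)
        ph = embed_tumour(ph, (0.064, 0.064, 0.045), 2e-6)
        src = mnp_source_map(ph, 243.0e3)
        assert np.all(src[ph.tumour_mask] == 243.0e3)
        assert np.all(src[~ph.tumour_mask] == 0.0)
        total = src.sum() * ph.spacing**3
        # ~0.49 W deposited; coarse 4 mm voxelisation of the 7.8 mm sphere
        assert total == pytest.approx(243.0e3 * 2e-6, rel=0.25)

    def test_zero_power(self):
        ph = generate_phantom(PhantomConfig(grid=32, spacing=4.0e-3), seed=1)
        ph = embed_tumour(ph, (0.064, 0.064, 0.045), 2e-6)
        assert np.all(mnp_source_map(ph, 0.0) == 0.0)

    def test_missing_tumour_rejected(self, small_phantom):
        with pytest.raises(PhantomError, match="tumour"):
            mnp_source_map(small_phantom, 1.0e3)
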