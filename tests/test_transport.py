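"""Physics of the two-layer bean simulation and the analysis helpers."""

import numpy as np
import pytest

from cocoadry import geometry as G
from cocoadry import properties as P
from cocoadry import transport as T


class TestBeanRunInvariants:
    def test_maximum_principle(self, bean_short_run):
        res = bean_short_run
        span_T = res.bc.air.temperature - res.ic.To
        span_c = res.ic.co - res.bc.c_inf
        assert res.T_min >= res.ic.To - 1e-6 * span_T
        assert res.T_max <= res.bc.air.temperature + 1e-6 * span_T
        assert res.c_min >= res.bc.c_inf - 1e-6 * span_c
        assert res.c_max <= res.ic.co + 1e-6 * span_c

    def test_water_conservation_audit(self, bean_short_run):
        assert bean_short_run.conservation_error() < 0.005

    def test_mean_moisture_non_increasing(self, bean_short_run):
        assert np.all(np.diff(bean_short_run.c_mean) <= 1e-12)

    def test_core_heats_and_bean_dries(self, bean_short_run):
        res = bean_short_run
        assert res.T_core[-1] > res.ic.To + 5.0
        assert res.c_mean[-1] < 0.9 * res.ic.co

    def test_determinism_bit_identical(self, bean_geometry, coarse_bean_mesh, default_mats):
        ic = T.InitialConditions()
        bc = T.BoundaryConditions.from_air(
            P.AirState(temperature=50.0), bean_geometry, ic, default_mats
        )
        cfg = T.SolverConfig(dt=10.0, t_end=600.0, store_snapshots=False)
        r1 = T.run(coarse_bean_mesh, default_mats, bc, ic, cfg)
        r2 = T.run(coarse_bean_mesh, default_mats, bc, ic, cfg)
        assert np.array_equal(r1.T_core, r2.T_core)
        assert np.array_equal(r1.c_mean, r2.c_mean)
        assert np.array_equal(r1.cumulative_outflow, r2.cumulative_outflow)


class TestSingleStep:
    def test_boundary_responds_before_core(self, bean_geometry, coarse_bean_mesh, default_mats):
        ic = T.InitialConditions()
        bc = T.BoundaryConditions.from_air(
            P.AirState(temperature=50.0), bean_geometry, ic, default_mats
        )
        problem = T.TransportProblem(
            coarse_bean_mesh, default_mats, bc, ic, T.SolverConfig(dt=5.0, t_end=5.0)
        )
        problem.step()
        assert problem.T[problem.surface_node] > ic.To + 1e-3
        assert problem.c[problem.surface_node] < ic.co - 1e-3
        # implicit stepping couples the whole domain, so "unchanged" is to
        # tolerance: the core moves by ~5e-3 °C while the surface moves by ~10 °C
        assert problem.T[problem.core_node] == pytest.approx(ic.To, abs=0.05)
        assert problem.c[problem.core_node] == pytest.approx(ic.co, rel=1e-6)

    def test_missing_material_rejected(self, coarse_bean_mesh, default_mats):
        ic = T.InitialConditions()
        bc = T.BoundaryConditions(air=P.AirState(temperature=50.0), h=30.0,
                                  hm=0.03, c_inf=0.9)
        with pytest.raises(ValueError, match="shell"):
            T.TransportProblem(coarse_bean_mesh, {"core": default_mats["core"]}, bc, ic)


class TestLatentClosure:
    def test_inventory_calibrated_mass_exceeds_molar(self, bean_geometry, default_mats):
        ic = T.InitialConditions()
        bc = T.BoundaryConditions.from_air(
            P.AirState(temperature=50.0), bean_geometry, ic, default_mats,
            latent_basis="inventory",
        )
        # co = 10,878 mol/m^3 under-counts the water, so each model-mole
        # carries several times the molar mass of water
        assert 2 * T.M_WATER < bc.latent_mass_per_mol < 6 * T.M_WATER

    def test_molar_basis_option(self, bean_geometry, default_mats):
        bc = T.BoundaryConditions.from_air(
            P.AirState(temperature=50.0), bean_geometry,
            T.InitialConditions(), default_mats, latent_basis="molar",
        )
        assert bc.latent_mass_per_mol == T.M_WATER

    def test_early_drying_is_vapor_limited(self, bean_geometry, coarse_bean_mesh, default_mats):
        """At the start the surface flux sits at the carrying-capacity cap
        (constant-rate period), well below the raw Robin flux."""
        ic = T.InitialConditions()
        bc = T.BoundaryConditions.from_air(
            P.AirState(temperature=50.0), bean_geometry, ic, default_mats
        )
        problem = T.TransportProblem(
            coarse_bean_mesh, default_mats, bc, ic, T.SolverConfig(dt=5.0, t_end=5.0)
        )
        out_rate, _, _ = problem.step()
        area = coarse_bean_mesh.exterior_edge_areas().sum()
        raw_robin = bc.hm * (ic.co - bc.c_inf) * area
        cap = (
            (T.M_WATER / bc.latent_mass_per_mol)
            * bc.hm
            * (P.saturation_vapor_concentration(ic.To) - bc.c_inf)
            * area
        )
        assert out_rate < 0.01 * raw_robin
        assert out_rate == pytest.approx(cap, rel=0.05)


class TestComparisonsAndTraces:
    def test_identical_materials_make_domains_coincide(
        self, bean_geometry, coarse_bean_mesh, default_mats
    ):
        ic = T.InitialConditions()
        bc = T.BoundaryConditions.from_air(
            P.AirState(temperature=50.0), bean_geometry, ic, default_mats
        )
        cfg = T.SolverConfig(dt=10.0, t_end=1200.0, store_snapshots=False)
        mats = {"core": default_mats["core"], "shell": default_mats["core"]}
        cmp = T.compare_single_vs_multidomain(coarse_bean_mesh, mats, bc, ic, cfg)
        assert cmp["max_dT_core"] < 1e-9
        assert cmp["max_dc_mean"] < 1e-6

    def test_two_layer_vs_homogenized_differ_but_both_dry(
        self, bean_geometry, coarse_bean_mesh, default_mats
    ):
        ic = T.InitialConditions()
        bc = T.BoundaryConditions.from_air(
            P.AirState(temperature=50.0), bean_geometry, ic, default_mats
        )
        cfg = T.SolverConfig(dt=10.0, t_end=2400.0, store_snapshots=False)
        cmp = T.compare_single_vs_multidomain(
            coarse_bean_mesh, default_mats, bc, ic, cfg
        )
        assert cmp["max_dT_core"] > 0
        for key in ("multidomain", "single_domain"):
            assert np.all(np.diff(cmp[key].c_mean) <= 1e-12)

    def test_mcdb_calibration_anchor(self, bean_short_run):
        mcdb = bean_short_run.mcdb_trace(1.82)
        assert mcdb[0] == pytest.approx(1.82, rel=1e-9)  # uniform c = co at t=0
        assert np.all(np.diff(mcdb) <= 1e-12)
        with pytest.raises(ValueError):
            T.moisture_trace_to_mcdb(bean_short_run, -1.0)

    def test_mr_trace_limits(self, bean_short_run):
        mr = bean_short_run.mr_trace()
        assert mr[0] == pytest.approx(1.0)
        assert np.all(mr >= -1e-12) and np.all(mr <= 1.0 + 1e-12)


class TestAverageRelativeError:
    def test_identical_traces(self):
        t = np.linspace(0, 10, 20)
        assert T.average_relative_error(t, np.cos(t) + 2, t, np.cos(t) + 2) == 0.0

    def test_ten_percent_offset(self):
        t = np.linspace(0, 10, 20)
        y = np.cos(t) + 2
        assert T.average_relative_error(t, 1.1 * y, t, y) == pytest.approx(10.0)

    def test_noisy_reference_folded_normal(self):
        rng = np.random.default_rng(42)
        t = np.arange(4000.0)
        ref = np.ones_like(t)
        model = 1.0 + rng.normal(0.0, 0.05, t.shape)
        # E|N(0, 0.05)| = 0.05 sqrt(2/pi) ~ 3.99%
        assert T.average_relative_error(t, model, t, ref) == pytest.approx(4.0, abs=0.3)

    def test_zero_reference_samples_excluded(self):
        t = np.arange(5.0)
        ref = np.array([1.0, 0.0, 1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="zero"):
            err = T.average_relative_error(t, np.full(5, 1.1), t, ref)
        assert err == pytest.approx(10.0)


class TestGridConvergence:
    def test_core_trace_stabilizes_under_refinement(self, bean_geometry, default_mats):
        ic = T.InitialConditions()
        bc = T.BoundaryConditions.from_air(
            P.AirState(temperature=50.0), bean_geometry, ic, default_mats
        )
        cfg = T.SolverConfig(dt=10.0, t_end=1800.0, store_snapshots=False)
        report = T.grid_convergence_study(
            bean_geometry, default_mats, bc, ic,
            sizes=[1.6e-3, 1.0e-3, 6e-4], config=cfg, shell_layers=2,
        )
        assert report.max_deviation_finest_pair < 0.5  # °C, between finest grids
        dev = report.pairwise_max_deviation()
        assert dev[0, 2] >= dev[1, 2]  # coarser grid sits farther from finest

    def test_too_few_sizes_rejected(self, bean_geometry, default_mats):
        ic = T.InitialConditions()
        bc = T.BoundaryConditions.from_air(
            P.AirState(temperature=50.0), bean_geometry, ic, default_mats
        )
        with pytest.raises(ValueError, match="3"):
            T.grid_convergence_study(bean_geometry, default_mats, bc, ic, sizes=[1e-3])
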