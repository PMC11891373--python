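"""Load case, interfaces, FE backend against closed forms, reduced order."""

import numpy as np
import pytest

from fnstab.bone_materials import MaterialMap
from fnstab.config_grid import FNSConfiguration, standard_configuration
from fnstab.construct_mechanics import (
    InterfaceSpec,
    LoadCase,
    assemble_and_solve,
    convergence_study,
    default_interfaces,
    interface_tractions,
    reduced_order_metrics,
    single_leg_load,
)
from fnstab.synth_femur import SurrogateFemurSpec, toy_fixture_cases


def _uniform_materials(mesh, E, nu):
    n = mesh.n_elements
    return MaterialMap(np.full(n, float(E)), np.full(n, float(nu)), np.full(n, 1.0))


class TestLoadCase:
    def test_default_magnitude_is_three_body_weights(self):
        assert single_leg_load().magnitude_N == pytest.approx(2100.0)
        assert single_leg_load(80.0, 2.5).magnitude_N == pytest.approx(2000.0)

    def test_direction_unit_norm(self):
        d = LoadCase().direction()
        assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-12)

    def test_direction_matches_rotation_matrix_oracle(self):
        load = LoadCase(sagittal_angle_deg=8.0, coronal_angle_deg=13.0)
        th, ph = np.deg2rad(-8.0), np.deg2rad(-13.0)
        Rx = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]])
        Ry = np.array([[np.cos(ph), 0, np.sin(ph)], [0, 1, 0], [-np.sin(ph), 0, np.cos(ph)]])
        expected = Ry @ Rx @ np.array([0.0, 0.0, -1.0])
        assert np.linalg.norm(load.direction() - expected) < 1e-12
        # posterior and lateral components have the stated signs
        assert load.direction()[1] < 0 and load.direction()[0] > 0

    def test_invalid_angles_rejected(self):
        with pytest.raises(ValueError):
            LoadCase(sagittal_angle_deg=95.0)


def test_default_interfaces_carry_published_frictions():
    spec = {s.pair_tag: s for s in default_interfaces()}
    assert spec["fracture"].friction_coefficient == 0.46
    assert spec["bolt_bone"].friction_coefficient == 0.30
    assert spec["plate_bolt"].friction_coefficient == 0.20
    assert spec["plate_screw"].friction_coefficient == 0.20
    assert spec["screw_bone"].model == "bonded"
    for s in spec.values():
        assert s.model in ("bonded", "frictional")


class TestFEOracles:
    @pytest.fixture(scope="class")
    def fixtures(self):
        return {f.name: f for f in toy_fixture_cases(h=2.5)}

    def test_axial_rod_stiffness_within_one_percent(self, fixtures):
        fx = fixtures["axial_rod"]
        mats = _uniform_materials(fx.mesh, fx.E_MPa, fx.nu)
        sol = assemble_and_solve(
            fx.mesh, mats, [], LoadCase(), order=1, external_forces=fx.loads, dirichlet=fx.dirichlet
        )
        w = sol.u_mm[fx.mesh.node_sets["top"], 2].mean()
        k = fx.answer["force_N"] / w
        assert k == pytest.approx(fx.answer["stiffness_N_mm"], rel=0.01)

    def test_cantilever_tip_deflection_within_two_percent(self, fixtures):
        fx = fixtures["cantilever"]
        mats = _uniform_materials(fx.mesh, fx.E_MPa, fx.nu)
        sol = assemble_and_solve(
            fx.mesh, mats, [], LoadCase(), order=2, external_forces=fx.loads, dirichlet=fx.dirichlet
        )
        d = sol.u_mm[fx.mesh.node_sets["tip"], 0].mean()
        assert d == pytest.approx(fx.answer["tip_deflection_mm"], rel=0.02)

    def test_prescribed_gap_fixture(self, fixtures):
        fx = fixtures["two_block_gap"]
        mats = _uniform_materials(fx.mesh, fx.E_MPa, fx.nu)
        sol = assemble_and_solve(
            fx.mesh,
            mats,
            [InterfaceSpec("fracture", "frictional", 0.46)],
            LoadCase(),
            order=1,
            external_forces=fx.loads,
            dirichlet=fx.dirichlet,
        )
        _, _, gap = interface_tractions(sol, "fracture")
        assert gap.max() == pytest.approx(0.5, abs=1e-9)
        # fully open interface transmits nothing
        tn, tt, _ = interface_tractions(sol, "fracture")
        assert np.all(tn == 0.0) and np.all(np.abs(tt) < 1e-12)

    def test_zero_load_gives_zero_displacement(self, fixtures):
        fx = fixtures["axial_rod"]
        mats = _uniform_materials(fx.mesh, fx.E_MPa, fx.nu)
        sol = assemble_and_solve(
            fx.mesh, mats, [], LoadCase(), order=1,
            external_forces=np.zeros((fx.mesh.n_nodes, 3)),
            dirichlet=fx.dirichlet,
        )
        assert np.abs(sol.u_mm).max() == 0.0

    def test_energy_consistency_on_bonded_problem(self, fixtures):
        fx = fixtures["axial_rod"]
        mats = _uniform_materials(fx.mesh, fx.E_MPa, fx.nu)
        sol = assemble_and_solve(
            fx.mesh, mats, [], LoadCase(), order=1, external_forces=fx.loads, dirichlet=fx.dirichlet
        )
        ratio = sol.meta["external_work_N_mm"] / sol.meta["strain_energy_N_mm"]
        assert ratio == pytest.approx(2.0, abs=1e-8)


class TestConstructSolution:
    def test_linearity_under_load_scaling(self, standard_construct):
        from fnstab.bone_materials import assign_materials

        mesh, hu, _, _ = standard_construct
        mats = assign_materials(mesh, hu)
        ifs = default_interfaces()
        base = LoadCase(magnitude_N=2100.0, preload_N=224.0)
        double = LoadCase(magnitude_N=4200.0, preload_N=448.0)
        s1 = assemble_and_solve(mesh, mats, ifs, base, cap_model="linear")
        s2 = assemble_and_solve(mesh, mats, ifs, double, cap_model="linear")
        scale = np.abs(s1.u_mm).max()
        assert np.abs(s2.u_mm - 2.0 * s1.u_mm).max() / scale < 1e-10

    def test_coulomb_cap_inequality_on_all_interfaces(self, standard_solution):
        mesh, load, sol, mats = standard_solution
        specs = {s.pair_tag: s for s in default_interfaces()}
        for tag, st in sol.interface_state.items():
            mu = specs[tag].friction_coefficient
            tn, tt, gap = interface_tractions(sol, tag)
            assert np.all(tt <= mu * tn + 1e-6 + 0.02 * tt.max())
            assert np.all(tn[st["open"]] == 0.0)

    def test_solver_report_residual_below_tolerance(self, standard_solution):
        _, _, sol, _ = standard_solution
        assert sol.solver_report["residual"] < 1e-8

    def test_unconstrained_system_raises(self, standard_construct):
        from fnstab.bone_materials import assign_materials

        mesh, hu, _, _ = standard_construct
        mats = assign_materials(mesh, hu)
        with pytest.raises((RuntimeError, ValueError)):
            assemble_and_solve(
                mesh, mats, default_interfaces(), LoadCase(constrained_surface="nonexistent")
            )

    def test_missing_interface_tag_raises(self, standard_solution):
        _, _, sol, _ = standard_solution
        with pytest.raises(KeyError):
            interface_tractions(sol, "no_such_pair")


class TestReducedOrder:
    def test_standard_stiffer_than_short_bolt(self):
        std = reduced_order_metrics(standard_configuration())
        short = reduced_order_metrics(FNSConfiguration("len75", bolt_length_mm=75.0))
        assert std.stiffness_N_mm >= short.stiffness_N_mm

    def test_inferior_offsets_monotonically_softer(self):
        ks = [
            reduced_order_metrics(FNSConfiguration(f"off{o}", offset_mm=o)).stiffness_N_mm
            for o in (0.0, -5.0, -10.0, -15.0)
        ]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_linear_in_elastic_moduli(self):
        from fnstab.construct_mechanics import ReducedOrderParams

        p1 = ReducedOrderParams()
        p2 = ReducedOrderParams(E_implant_MPa=2 * p1.E_implant_MPa, E_bone_MPa=2 * p1.E_bone_MPa)
        cfg = standard_configuration()
        k1 = reduced_order_metrics(cfg, p1).stiffness_N_mm
        k2 = reduced_order_metrics(cfg, p2).stiffness_N_mm
        assert k2 == pytest.approx(2.0 * k1, rel=1e-12)

    def test_invalid_calibration_rejected(self):
        from fnstab.construct_mechanics import ReducedOrderParams

        with pytest.raises(ValueError):
            reduced_order_metrics(
                standard_configuration(), ReducedOrderParams(E_bone_MPa=-1.0)
            )

    def test_runs_fast(self):
        import time

        t0 = time.perf_counter()
        for _ in range(20):
            reduced_order_metrics(standard_configuration())
        assert (time.perf_counter() - t0) / 20 < 0.01


class TestConvergenceStudy:
    def test_relative_change_column_and_flag(self, coarse_spec):
        df = convergence_study(
            coarse_spec,
            standard_configuration(),
            default_interfaces(),
            LoadCase(),
            sizes=[5.0, 6.0],
            order=1,
        )
        assert list(df["size_mm"]) == [5.0, 6.0]
        vm = df["max_implant_von_mises_MPa"].to_numpy()
        # arithmetic oracle: recompute the relative-change column
        assert df["relative_change"].iloc[1] == pytest.approx(abs(vm[1] - vm[0]) / vm[0])
        assert np.isnan(df["relative_change"].iloc[0])

    def test_single_size_rejected(self, coarse_spec):
        with pytest.raises(ValueError):
            convergence_study(
                coarse_spec, standard_configuration(), default_interfaces(), LoadCase(), sizes=[5.0]
            )
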