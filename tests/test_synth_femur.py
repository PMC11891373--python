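"""Surrogate femur generation, fracture cut, implant embedding, fixtures."""

from dataclasses import replace

import numpy as np
import pytest

import fnstab._mesh as M
from fnstab.config_grid import (
    FNSConfiguration,
    fracture_plane,
    implant_axis,
    standard_configuration,
)
from fnstab.synth_femur import (
    SurrogateFemurSpec,
    SyntheticDecisionSpec,
    apply_fracture_cut,
    embed_implant,
    generate_metric_table,
    generate_surrogate_femur,
    hounsfield_field,
    toy_fixture_cases,
    _bone_classify,
    _implant_classify,
)


@pytest.fixture(scope="module")
def fine_spec():
    return SurrogateFemurSpec(target_edge_length_mm=2.5, element_order=1, seed=3)


@pytest.fixture(scope="module")
def fine_femur(fine_spec):
    return generate_surrogate_femur(fine_spec)


class TestGeneration:
    def test_bit_identical_repeats(self, fine_spec, fine_femur):
        mesh, hu = fine_femur
        mesh2, hu2 = generate_surrogate_femur(fine_spec)
        assert np.array_equal(mesh.nodes, mesh2.nodes)
        assert np.array_equal(mesh.elems, mesh2.elems)
        assert np.array_equal(hu.values, hu2.values)

    def test_zero_sd_gives_exact_region_means(self):
        spec = SurrogateFemurSpec(
            target_edge_length_mm=4.0,
            hu_cortical_mean_sd=(1500.0, 0.0),
            hu_cancellous_mean_sd=(300.0, 0.0),
        )
        mesh, hu = generate_surrogate_femur(spec)
        cort = mesh.region[hu.element_ids] == M.CORTICAL
        assert np.all(hu.values[cort] == 1500.0)
        assert np.all(hu.values[~cort] == 300.0)

    def test_cortical_shell_fraction_matches_tube_oracle(self, fine_spec, fine_femur):
        # in a z-window away from the neck junction and the distal face the
        # geometry is a plain tube: closed-form shell area fraction
        mesh, _ = fine_femur
        c = mesh.element_centroids()
        v = mesh.element_volumes()
        win = (c[:, 2] > 15.0) & (c[:, 2] < 70.0)
        frac = v[win & (mesh.region == M.CORTICAL)].sum() / v[win].sum()
        R, t = fine_spec.shaft_outer_radius_mm, fine_spec.cortical_thickness_mm
        analytic = (R**2 - (R - t) ** 2) / R**2
        assert frac == pytest.approx(analytic, rel=0.05)

    def test_articular_head_is_cancellous(self, fine_femur):
        mesh, _ = fine_femur
        head = mesh.part == M.HEAD_PART
        assert head.any()
        assert np.all(mesh.region[head] == M.CANCELLOUS)

    def test_quality_gate_catches_inverted_elements(self, fine_femur):
        mesh, _ = fine_femur
        mesh.validate()  # healthy mesh passes
        e0 = mesh.elems[0]
        saved = mesh.nodes[e0[0]].copy()
        mesh.nodes[e0[0]] = mesh.nodes[e0[1]] + (mesh.nodes[e0[1]] - mesh.nodes[e0[0]])
        try:
            with pytest.raises(ValueError):
                mesh.validate()
        finally:
            mesh.nodes[e0[0]] = saved

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SurrogateFemurSpec(neck_radius_mm=-1.0)
        with pytest.raises(ValueError):
            SurrogateFemurSpec(cortical_thickness_mm=20.0, shaft_outer_radius_mm=15.0)


class TestFractureCut:
    def test_cut_partitions_into_two_connected_fragments(self, fine_spec, fine_femur):
        mesh, _ = generate_surrogate_femur(fine_spec)
        plane = fracture_plane(fine_spec.head_center(), fine_spec.horizontal_normal(), 70.0)
        vol0 = mesh.element_volumes().sum()
        cut = apply_fracture_cut(mesh, plane)
        head = cut.fragment == 1
        shaft = (cut.fragment == 0) & cut.bone_mask()
        assert head.any() and shaft.any()
        assert M.connected_fragment_count(cut, head) == 1
        assert M.connected_fragment_count(cut, shaft) == 1
        # element reassignment conserves volume (snapping bounded by 0.5 %)
        assert cut.element_volumes().sum() == pytest.approx(vol0, rel=0.005)
        assert len(cut.interfaces["fracture"]) > 0
        assert "fracture_face_head" in cut.facet_sets

    def test_plane_missing_the_neck_raises(self, fine_spec):
        mesh, _ = generate_surrogate_femur(fine_spec)
        plane = fracture_plane(
            fine_spec.head_center() + np.array([0.0, 0.0, 300.0]),
            fine_spec.horizontal_normal(),
            70.0,
        )
        with pytest.raises(ValueError, match="does not intersect"):
            apply_fracture_cut(mesh, plane)


class TestEmbedImplant:
    def test_all_implant_regions_present_and_interfaces_split(self, standard_construct):
        mesh, _, _, _ = standard_construct
        for name in ("bolt", "antirotation_screw", "plate", "locking_screw"):
            assert mesh.region_mask(name).any(), name
        for tag in ("bolt_bone", "plate_bolt", "plate_bone", "fracture"):
            assert tag in mesh.interfaces and len(mesh.interfaces[tag]) > 0

    def test_reembedding_is_deterministic(self, coarse_spec):
        mesh, _ = generate_surrogate_femur(coarse_spec)
        cfg = standard_configuration()
        ax = implant_axis(cfg, coarse_spec.neck_axis(), coarse_spec.shaft_direction(), coarse_spec.coronal_normal())
        m1 = embed_implant(mesh, cfg, ax)
        m2 = embed_implant(mesh, cfg, ax)
        assert np.array_equal(m1.region, m2.region)
        assert np.array_equal(m1.nodes, m2.nodes)

    def test_bone_loss_matches_monte_carlo_channel_oracle(self, fine_spec):
        mesh, _ = generate_surrogate_femur(fine_spec)
        cfg = standard_configuration()
        ax = implant_axis(cfg, fine_spec.neck_axis(), fine_spec.shaft_direction(), fine_spec.coronal_normal())
        emb = embed_implant(mesh, cfg, ax)
        # independent oracle: Monte-Carlo volume of (bone ∩ implant)
        rng = np.random.default_rng(42)
        lo, hi = np.array([-70.0, -30, 0]), np.array([40.0, 35, 170])
        pts = rng.uniform(lo, hi, size=(800_000, 3))
        bone_in, _, _ = _bone_classify(fine_spec, pts)
        imp = _implant_classify(fine_spec, cfg, ax, pts)
        vol_mc = (bone_in & (imp >= 0)).mean() * np.prod(hi - lo)
        assert emb.meta["bone_loss_volume_mm3"] == pytest.approx(vol_mc, rel=0.05)

    def test_breach_refused_without_override(self, coarse_spec):
        mesh, _ = generate_surrogate_femur(coarse_spec)
        cfg = FNSConfiguration("long", bolt_length_mm=130.0)
        ax = implant_axis(cfg, coarse_spec.neck_axis(), coarse_spec.shaft_direction(), coarse_spec.coronal_normal())
        with pytest.raises(ValueError, match="breach"):
            embed_implant(mesh, cfg, ax)


class TestMetricTableGenerator:
    def test_defaults_match_study_size(self):
        table = generate_metric_table(SyntheticDecisionSpec())
        assert len(table) == 17

    def test_symmetric_plant_recovers_equal_weights(self):
        from fnstab.entropy_ranking import orient_normalize, entropy_weights

        spec = SyntheticDecisionSpec(planted_weights=(0.25, 0.25, 0.25, 0.25), noise_sd=0.0)
        Z = orient_normalize(generate_metric_table(spec))
        w = entropy_weights(Z).weight_w
        assert np.all(np.abs(w - 0.25) < 1e-6)

    def test_dominant_plant_gets_largest_weight(self):
        from fnstab.entropy_ranking import orient_normalize, entropy_weights

        spec = SyntheticDecisionSpec(planted_weights=(0.1, 0.15, 0.15, 0.6), noise_sd=0.0, seed=5)
        Z = orient_normalize(generate_metric_table(spec))
        w = entropy_weights(Z).weight_w
        assert np.argmax(w) == 3

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            SyntheticDecisionSpec(planted_weights=(0.5, 0.5, 0.5, -0.5))


class TestToyFixtures:
    def test_closed_form_answers_attached(self):
        cases = {f.name: f for f in toy_fixture_cases()}
        assert cases["axial_rod"].answer["stiffness_N_mm"] == pytest.approx(1000.0)
        # PL^3/3EI evaluated independently: 1 * 1e6 / (3 * 1000 * 833.33)
        assert cases["cantilever"].answer["tip_deflection_mm"] == pytest.approx(
            1.0 * 100.0**3 / (3.0 * 1000.0 * (10.0 * 1000.0 / 12.0)), rel=1e-12
        )
        assert cases["cantilever"].answer["tip_deflection_mm"] == pytest.approx(0.4, abs=1e-12)
        assert cases["two_block_gap"].answer["max_gap_mm"] == 0.5
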