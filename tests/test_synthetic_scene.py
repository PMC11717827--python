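import numpy as np
import pytest

from dentofuse.rigid_geometry import maxilla_center
from dentofuse.synthetic_scene import (
    MODALITY_TAGS,
    AcquisitionNoise,
    PhantomSpec,
    make_phantom,
    perturb_transform,
    simulate_all,
    simulate_modality,
)

ZERO_NOISE = AcquisitionNoise(vertex_sd=0.0, seed=7)


class TestMakePhantom:
    def test_same_seed_is_bit_identical(self):
        a = make_phantom(PhantomSpec(seed=5))
        b = make_phantom(PhantomSpec(seed=5))
        np.testing.assert_array_equal(a.head.vertices, b.head.vertices)
        np.testing.assert_array_equal(a.dentition.vertices, b.dentition.vertices)
        np.testing.assert_array_equal(a.tracer.vertices, b.tracer.vertices)

    def test_different_seeds_differ(self):
        a = make_phantom(PhantomSpec(seed=5))
        b = make_phantom(PhantomSpec(seed=6))
        assert not np.array_equal(a.head.vertices, b.head.vertices)

    def test_all_workflow_regions_present(self, phantom):
        for name in ("forehead", "zygoma", "cheeks", "lips"):
            assert len(phantom.head.regions[name]) > 10
        for name in ("anterior_teeth", "occlusal", "maxilla"):
            assert len(phantom.dentition.regions[name]) > 0
        for name in ("tracer_body", "impression"):
            assert len(phantom.tracer.regions[name]) > 0

    def test_tooth_count_respected(self):
        ph = make_phantom(PhantomSpec(tooth_count=10))
        # occlusal region has one bottom-face patch (9 welded grid points) per tooth
        assert len(ph.dentition.regions["occlusal"]) == 10 * 9

    def test_stored_center_matches_computed(self, phantom):
        np.testing.assert_allclose(
            phantom.maxilla_center, maxilla_center(phantom.dentition), atol=1e-6
        )

    def test_center_invariant_under_mesh_refinement(self):
        coarse = make_phantom(PhantomSpec(edge_length=5.0))
        fine = make_phantom(PhantomSpec(edge_length=2.5))
        assert np.linalg.norm(coarse.maxilla_center - fine.maxilla_center) < 0.01

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(arch_width=150.0, head_width=140.0)
        with pytest.raises(ValueError):
            PhantomSpec(tooth_count=4)


class TestSimulateModality:
    def test_zero_noise_ios_matches_dentition_after_true_transform(self, phantom):
        scan = simulate_modality(phantom, "IOS", ZERO_NOISE)
        moved = phantom.dentition.transformed(scan.true_transform.matrix())
        np.testing.assert_allclose(scan.mesh.vertices, moved.vertices, atol=1e-9)

    def test_retractor_photo_exposes_anterior_teeth(self, phantom):
        retr = simulate_modality(phantom, "PHOTO_RETRACTOR", ZERO_NOISE)
        rest = simulate_modality(phantom, "PHOTO_REST", ZERO_NOISE)
        assert "anterior_teeth" in retr.mesh.regions
        assert "anterior_teeth" not in rest.mesh.regions

    def test_retractor_deforms_cheeks_but_not_forehead(self, phantom):
        noise = AcquisitionNoise(vertex_sd=0.0, retractor_amplitude=8.0, seed=7)
        retr = simulate_modality(phantom, "PHOTO_RETRACTOR", noise)
        # undo the acquisition frame to compare against the phantom head
        back = retr.mesh.transformed(
            np.linalg.inv(retr.true_transform.matrix())
        )
        head = phantom.head
        n = head.n_vertices
        disp = np.linalg.norm(back.vertices[:n] - head.vertices, axis=1)
        cheeks = head.regions["cheeks"]
        forehead = head.regions["forehead"]
        assert disp[cheeks].max() > 4.0
        assert disp[forehead].max() < 1e-9

    def test_cbct_skin_truncated_above_plane(self, phantom):
        noise = AcquisitionNoise(vertex_sd=0.0, truncation_height=45.0, seed=7)
        skin = simulate_modality(phantom, "CBCT_SKIN", noise)
        back = skin.mesh.transformed(np.linalg.inv(skin.true_transform.matrix()))
        y_cut = phantom.head.vertices[:, 1].max() - 45.0
        assert back.vertices[:, 1].max() <= y_cut + 1e-9
        rest = simulate_modality(phantom, "PHOTO_REST", ZERO_NOISE)
        back_rest = rest.mesh.transformed(np.linalg.inv(rest.true_transform.matrix()))
        assert back_rest.vertices[:, 1].max() > y_cut

    def test_cbct_skin_and_teeth_share_one_frame(self, phantom):
        skin = simulate_modality(phantom, "CBCT_SKIN", ZERO_NOISE)
        teeth = simulate_modality(phantom, "CBCT_TEETH", ZERO_NOISE)
        np.testing.assert_allclose(
            skin.true_transform.matrix(), teeth.true_transform.matrix(), atol=1e-12
        )
        rest = simulate_modality(phantom, "PHOTO_REST", ZERO_NOISE)
        assert not np.allclose(skin.true_transform.matrix(), rest.true_transform.matrix())

    def test_tracer_wax_carries_impression_surface(self, phantom):
        wax = simulate_modality(phantom, "TRACER_WAX", ZERO_NOISE)
        assert "impression" in wax.mesh.regions
        assert "tracer_body" in wax.mesh.regions

    def test_unknown_tag_rejected(self, phantom):
        with pytest.raises(ValueError):
            simulate_modality(phantom, "MRI", ZERO_NOISE)

    def test_full_dataset_is_deterministic(self, phantom):
        a = simulate_all(phantom, AcquisitionNoise(seed=3))
        b = simulate_all(phantom, AcquisitionNoise(seed=3))
        for tag in MODALITY_TAGS:
            np.testing.assert_array_equal(a[tag].mesh.vertices, b[tag].mesh.vertices)

    def test_scans_are_rigid_images_plus_bounded_noise(self, phantom):
        noise = AcquisitionNoise(vertex_sd=0.05, seed=11)
        for tag in ("IOS", "PHOTO_REST", "CBCT_TEETH", "TRACER_WAX"):
            scan = simulate_modality(phantom, tag, noise)
            back = scan.mesh.transformed(np.linalg.inv(scan.true_transform.matrix()))
            base = {
                "IOS": phantom.dentition,
                "PHOTO_REST": phantom.head,
                "CBCT_TEETH": phantom.dentition,
                "TRACER_WAX": phantom.tracer,
            }[tag]
            disp = np.linalg.norm(back.vertices - base.vertices, axis=1)
            assert disp.max() < 0.05 * 6  # noise bounded at a few sigma


class TestPerturbTransform:
    def test_zero_sds_give_identity(self):
        T = perturb_transform(0.0, 0.0, seed=1)
        assert np.abs(T.matrix() - np.eye(4)).max() == 0.0

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            perturb_transform(-1.0, 0.0, seed=1)

    def test_translation_magnitude_matches_chi_distribution(self):
        # |t| for an isotropic 3D normal is chi(3): mean = sd * 2*sqrt(2/pi)
        sd = 0.3
        rng = np.random.default_rng(42)
        mags = np.array(
            [np.linalg.norm(perturb_transform(sd, 0.0, rng).translation) for _ in range(100_000)]
        )
        expected = sd * 2 * np.sqrt(2 / np.pi)
        assert abs(mags.mean() - expected) / expected < 0.01

    def test_per_axis_translation_sd(self):
        sd = 0.3
        rng = np.random.default_rng(43)
        t = np.array([perturb_transform(sd, 0.0, rng).translation for _ in range(50_000)])
        assert np.abs(t.std(axis=0) - sd).max() / sd < 0.02

    def test_rotation_angle_scale(self):
        rng = np.random.default_rng(44)
        angs = []
        for _ in range(20_000):
            T = perturb_transform(0.0, 0.5, rng)
            angs.append(np.rad2deg(np.arccos(np.clip((np.trace(T.rotation) - 1) / 2, -1, 1))))
        # |N(0, 0.5^2)| has mean 0.5*sqrt(2/pi)
        expected = 0.5 * np.sqrt(2 / np.pi)
        assert abs(np.mean(angs) - expected) / expected < 0.02
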