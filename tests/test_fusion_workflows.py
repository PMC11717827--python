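import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dentofuse.fusion_workflows import (
    FusionModel,
    WorkflowParams,
    compare_methods,
    deviations_for_subject,
    fuse_subject,
    run_cohort,
    run_method_a,
    run_method_b,
    run_method_c,
)
from dentofuse.rigid_geometry import RigidTransform, compose, invert, maxilla_center
from dentofuse.synthetic_scene import (
    AcquisitionNoise,
    PhantomSpec,
    make_phantom,
    simulate_all,
)


@pytest.fixture(scope="module")
def noiseless_subject():
    ph = make_phantom(PhantomSpec(seed=21))
    scans = simulate_all(ph, AcquisitionNoise(vertex_sd=0.0, seed=21))
    models = fuse_subject(scans, WorkflowParams())
    return ph, scans, models


class TestChains:
    def test_chain_lengths_match_workflow_definitions(self, noiseless_subject):
        _, _, models = noiseless_subject
        assert models["A"].chain_length == 2
        assert models["B"].chain_length == 3
        assert models["C"].chain_length == 2

    def test_noiseless_fusions_recover_ground_truth(self, noiseless_subject):
        _, scans, models = noiseless_subject
        devs = deviations_for_subject(
            models, scans["IOS"].mesh, scans["PHOTO_REST"].true_transform
        )
        for pair in ("A-C", "B-C", "A-B"):
            for name, value in devs[pair].components().items():
                assert abs(value) < 0.1, f"{pair} {name} = {value}"

    def test_missing_scan_raises(self, noiseless_subject):
        _, scans, _ = noiseless_subject
        partial = {k: v for k, v in scans.items() if k != "IOS"}
        with pytest.raises(ValueError, match="IOS"):
            run_method_a(partial)
        with pytest.raises(ValueError, match="TRACER_WAX"):
            run_method_b({k: v for k, v in scans.items() if k != "TRACER_WAX"})
        with pytest.raises(ValueError, match="CBCT_SKIN"):
            run_method_c({k: v for k, v in scans.items() if k != "CBCT_SKIN"})

    def test_reference_compared_to_itself_is_zero(self, noiseless_subject):
        _, scans, models = noiseless_subject
        center = maxilla_center(scans["IOS"].mesh)
        d = compare_methods(models["C"], models["C"], center)
        assert all(abs(v) < 1e-9 for v in d.components().values())


class TestCompareMethods:
    def test_injected_vertical_offset_recovered(self, noiseless_subject):
        # shift the experimental pose by 1 mm along the anatomical vertical
        _, scans, models = noiseless_subject
        F = scans["PHOTO_REST"].true_transform
        shift_anat = RigidTransform(np.eye(3), [0.0, 1.0, 0.0])
        shift_rest = compose(F, compose(shift_anat, invert(F)))
        shifted = FusionModel(
            "A",
            compose(shift_rest, models["C"].maxilla_pose),
            models["C"].chain,
            models["C"].injected,
        )
        devs = deviations_for_subject(
            {"A": shifted, "B": models["B"], "C": models["C"]},
            scans["IOS"].mesh,
            F,
        )
        d = devs["A-C"]
        assert abs(d.dy - 1.0) < 1e-6
        assert abs(d.dx) < 1e-6 and abs(d.dz) < 1e-6
        assert abs(d.euclidean - 1.0) < 1e-6

    def test_euclidean_consistent_with_own_components(self, noiseless_subject):
        _, scans, models = noiseless_subject
        params = WorkflowParams(step_translation_sd=0.3, step_rotation_sd=0.2, seed=5)
        noisy = fuse_subject(scans, params)
        devs = deviations_for_subject(
            noisy, scans["IOS"].mesh, scans["PHOTO_REST"].true_transform
        )
        for d in devs.values():
            assert abs(d.euclidean - np.sqrt(d.dx**2 + d.dy**2 + d.dz**2)) < 1e-9

    def test_deviations_absolutized(self, noiseless_subject):
        _, scans, _ = noiseless_subject
        params = WorkflowParams(step_translation_sd=0.3, step_rotation_sd=0.2, seed=5)
        noisy = fuse_subject(scans, params)
        devs = deviations_for_subject(
            noisy, scans["IOS"].mesh, scans["PHOTO_REST"].true_transform
        )
        for d in devs.values():
            assert not d.signed
            assert min(d.dx, d.dy, d.dz, d.roll, d.pitch, d.yaw) >= 0


class TestPipelineEquivariance:
    def test_global_rigid_motion_leaves_deviations_unchanged(self):
        # deterministic fusions (no step noise): the registration error from
        # the baked-in scanner noise must move rigidly with the scene
        ph = make_phantom(PhantomSpec(seed=31))
        scans = simulate_all(ph, AcquisitionNoise(vertex_sd=0.05, seed=31))
        params = WorkflowParams()
        base = deviations_for_subject(
            fuse_subject(scans, params),
            scans["IOS"].mesh,
            scans["PHOTO_REST"].true_transform,
        )
        G = RigidTransform(
            Rotation.from_euler("xyz", [10, -20, 5], degrees=True).as_matrix(),
            np.array([30.0, -10.0, 25.0]),
        )
        moved = {}
        for tag, scan in scans.items():
            m = scan.mesh.transformed(G.matrix())
            moved[tag] = type(scan)(tag, m, compose(G, scan.true_transform))
        shifted = deviations_for_subject(
            fuse_subject(moved, params),
            moved["IOS"].mesh,
            moved["PHOTO_REST"].true_transform,
        )
        for pair in base:
            for k, v in base[pair].components().items():
                assert abs(v - shifted[pair].components()[k]) < 5e-4, (pair, k)


class TestAnteriorOnlyMatching:
    def test_anterior_matching_is_less_stable_in_pitch_than_full_arch(self):
        # the retractor workflow registers on the anterior crowns only; under
        # scanner noise its pitch is less constrained than the full-arch
        # registration the CBCT route performs
        from dentofuse.registration import IcpParams, coarse_align, icp_register
        from dentofuse.rigid_geometry import decompose_rotation

        ph = make_phantom(PhantomSpec(seed=41))
        dent = ph.dentition
        rng = np.random.default_rng(41)
        pitch_anterior, pitch_full = [], []
        p2p = IcpParams(metric="point_to_point", trim_fraction=0.0)
        for _ in range(15):
            target = dent.copy()
            target.vertices = target.vertices + rng.normal(0, 0.05, target.vertices.shape)
            for region, sink in (("anterior_teeth", pitch_anterior), (None, pitch_full)):
                res = icp_register(dent, target, region, region, None, p2p)
                _, pitch, _ = decompose_rotation(res.transform)
                sink.append(abs(pitch))
        assert np.mean(pitch_anterior) > np.mean(pitch_full)


class TestRunCohort:
    def test_zero_noise_cohort_is_accurate(self):
        coh = run_cohort(2, noise=AcquisitionNoise(vertex_sd=0.0), base_seed=51)
        assert not coh.config["failed_subjects"]
        vals = coh.table[["dx", "dy", "dz", "roll", "pitch", "yaw", "euclidean"]]
        assert vals.abs().max().max() < 0.1

    def test_same_base_seed_reproduces_cohort(self):
        a = run_cohort(3, base_seed=52)
        b = run_cohort(3, base_seed=52)
        assert a.table.equals(b.table)

    def test_replicate_run_differs_only_by_fusion_seed(self):
        params = WorkflowParams(step_translation_sd=0.3, step_rotation_sd=0.2)
        a = run_cohort(3, base_seed=53, params=params, fusion_seed=1)
        b = run_cohort(3, base_seed=53, params=params, fusion_seed=2)
        assert not a.table.drop(columns=["subject", "pair"]).equals(
            b.table.drop(columns=["subject", "pair"])
        )
        assert a.subject_seeds == b.subject_seeds

    def test_small_cohorts_rejected(self):
        with pytest.raises(ValueError):
            run_cohort(1)

    def test_three_rows_per_subject(self):
        coh = run_cohort(2, noise=AcquisitionNoise(vertex_sd=0.0), base_seed=54)
        assert len(coh.table) == 6
        assert set(coh.table["pair"]) == {"A-C", "B-C", "A-B"}
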