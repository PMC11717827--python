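"""The three fusion chains and cohort simulation.

Each method places the intra-oral scan (IOS) in the rest-face frame via a
chain of region-restricted rigid superimpositions:

* **Method A** (cheek retractors, 2 steps): rest face -> retractor photo on
  the forehead; IOS -> retractor photo on the exposed anterior tooth
  crowns.
* **Method B** (bite-fork tracer, 3 steps): rest face -> tracer photo on
  the forehead; tracer-with-wax scan -> tracer photo on the tracer body;
  IOS -> wax scan on the occlusal surfaces vs. their impression.
* **Method C** (CBCT gold standard, 2 steps): IOS -> CBCT teeth surface;
  rest face -> CBCT skin on forehead + zygomatic arch (the CBCT field of
  view truncates the upper forehead, hence the extended matching area).

Accuracy is assessed by comparing the maxilla pose of an experimental
model with the reference model at the maxilla's measuring point, giving a
6-DOF :class:`~dentofuse.rigid_geometry.PoseDeviation` per subject and
method pair.

When simulating, an optional per-step perturbation models the residual
error a human-driven registration step leaves behind; it is drawn about
the matching region's centroid, so a rotational error on the tracer plate
translates the dentition in proportion to the lever arm — the "lever
principle" that penalises tracers far from the dentition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mesh_core import TriMesh
from .registration import IcpParams, RegistrationResult, icp_register, coarse_align
from .rigid_geometry import (
    PoseDeviation,
    RigidTransform,
    absolutize,
    compose,
    invert,
    maxilla_center,
    pose_deviation,
)
from .synthetic_scene import (
    AcquisitionNoise,
    ModalityScan,
    PhantomSpec,
    make_phantom,
    perturb_transform,
    simulate_all,
)

__all__ = [
    "WorkflowParams",
    "FusionModel",
    "CohortResult",
    "run_method_a",
    "run_method_b",
    "run_method_c",
    "compare_methods",
    "run_cohort",
    "OUTCOMES",
    "PAIRS",
]

OUTCOMES = ("dx", "dy", "dz", "euclidean", "roll", "pitch", "yaw")
PAIRS = ("A-C", "B-C", "A-B")


@dataclass
class WorkflowParams:
    """Registration settings and the per-step error model.

    ``surface_icp`` drives the large smooth matching areas (forehead,
    zygoma, skin, tracer body); ``teeth_icp`` the sparse dental regions
    (anterior crowns, occlusal surfaces) where point-to-point is more
    stable.  ``step_translation_sd`` / ``step_rotation_sd`` inject a random
    residual after every registration step (0 = ideal software operator);
    the gold-standard method C is perturbed with the same model unless
    ``perturb_reference`` is False.
    """

    surface_icp: IcpParams = field(default_factory=lambda: IcpParams(metric="point_to_plane"))
    teeth_icp: IcpParams = field(
        default_factory=lambda: IcpParams(metric="point_to_point", trim_fraction=0.0)
    )
    step_translation_sd: float = 0.0
    step_rotation_sd: float = 0.0
    perturb_reference: bool = True
    seed: int = 0


@dataclass
class FusionModel:
    """Result of one fusion chain for one subject."""

    method: str
    maxilla_pose: RigidTransform  # maps the IOS frame into the rest-face frame
    chain: list[RegistrationResult]
    injected: list[RigidTransform]

    @property
    def chain_length(self) -> int:
        return len(self.chain)


class FusionStepError(RuntimeError):
    """A registration step failed; names the step."""


def _register_step(
    step_name: str,
    source: TriMesh,
    target: TriMesh,
    source_region,
    target_region,
    icp: IcpParams,
    rng: np.random.Generator | None,
    t_sd: float,
    r_sd: float,
    chain: list[RegistrationResult],
    injected: list[RigidTransform],
    invert_direction: bool = False,
    init_source_region=None,
    init_target_region=None,
) -> RigidTransform:
    """One superimposition plus optional per-step perturbation about the
    matching-region centroid (in the target frame).

    ``invert_direction`` runs the ICP from target to source and inverts
    the result, which is more robust when the nominal source only partly
    overlaps the target (every ICP source point then has a true match);
    the returned transform still maps source into target.
    ``init_source_region`` / ``init_target_region`` override the regions
    used for the coarse alignment (e.g. a stable sub-area fully visible on
    both surfaces).
    """
    isr = init_source_region if init_source_region is not None else source_region
    itr = init_target_region if init_target_region is not None else target_region
    try:
        if invert_direction:
            init = coarse_align(target, source, itr, isr)
            res = icp_register(target, source, target_region, source_region, init, icp)
            T = invert(res.transform)
        else:
            init = coarse_align(source, target, isr, itr)
            res = icp_register(source, target, source_region, target_region, init, icp)
            T = res.transform
    except Exception as exc:
        raise FusionStepError(f"registration step {step_name!r} failed: {exc}") from exc
    chain.append(res)
    if rng is not None and (t_sd > 0 or r_sd > 0):
        pivot = _region_centroid(target, target_region)
        P0 = perturb_transform(t_sd, r_sd, rng)
        shift = RigidTransform(np.eye(3), pivot)
        P = compose(shift, compose(P0, invert(shift)))
        injected.append(P)
        T = compose(P, T)
    else:
        injected.append(RigidTransform.identity())
    return T


def _region_centroid(mesh: TriMesh, region) -> np.ndarray:
    if region is None:
        return mesh.vertices.mean(axis=0)
    names = [region] if isinstance(region, str) else list(region)
    idx = np.unique(np.concatenate([mesh.region_index(n) for n in names]))
    return mesh.vertices[idx].mean(axis=0)


def _rng_for(params: WorkflowParams, method: str) -> np.random.Generator | None:
    if params.step_translation_sd == 0 and params.step_rotation_sd == 0:
        return None
    ss = np.random.SeedSequence([params.seed, "ABC".index(method)])
    return np.random.default_rng(ss)


def run_method_a(scans: dict[str, ModalityScan], params: WorkflowParams | None = None) -> FusionModel:
    """Cheek-retractor fusion (2 steps)."""
    params = params or WorkflowParams()
    for tag in ("IOS", "PHOTO_REST", "PHOTO_RETRACTOR"):
        if tag not in scans:
            raise ValueError(f"method A requires scan {tag}")
    rng = _rng_for(params, "A")
    chain: list[RegistrationResult] = []
    injected: list[RigidTransform] = []
    rest, retr, ios = scans["PHOTO_REST"].mesh, scans["PHOTO_RETRACTOR"].mesh, scans["IOS"].mesh

    t_rest_to_retr = _register_step(
        "A1 rest->retractor (forehead)", rest, retr, "forehead", "forehead",
        params.surface_icp, rng, params.step_translation_sd, params.step_rotation_sd,
        chain, injected,
    )
    t_ios_to_retr = _register_step(
        "A2 IOS->retractor (anterior teeth)", ios, retr, "anterior_teeth", "anterior_teeth",
        params.teeth_icp, rng, params.step_translation_sd, params.step_rotation_sd,
        chain, injected,
    )
    pose = compose(invert(t_rest_to_retr), t_ios_to_retr)
    return FusionModel("A", pose, chain, injected)


def run_method_b(scans: dict[str, ModalityScan], params: WorkflowParams | None = None) -> FusionModel:
    """Bite-fork tracer fusion (3 steps)."""
    params = params or WorkflowParams()
    for tag in ("IOS", "PHOTO_REST", "PHOTO_TRACER", "TRACER_WAX"):
        if tag not in scans:
            raise ValueError(f"method B requires scan {tag}")
    rng = _rng_for(params, "B")
    chain: list[RegistrationResult] = []
    injected: list[RigidTransform] = []
    rest = scans["PHOTO_REST"].mesh
    photo = scans["PHOTO_TRACER"].mesh
    wax = scans["TRACER_WAX"].mesh
    ios = scans["IOS"].mesh

    t_rest_to_photo = _register_step(
        "B1 rest->tracer photo (forehead)", rest, photo, "forehead", "forehead",
        params.surface_icp, rng, params.step_translation_sd, params.step_rotation_sd,
        chain, injected,
    )
    t_wax_to_photo = _register_step(
        "B2 wax scan->tracer photo (tracer body)", wax, photo, "tracer_body", "tracer_body",
        params.surface_icp, rng, params.step_translation_sd, params.step_rotation_sd,
        chain, injected,
    )
    t_ios_to_wax = _register_step(
        "B3 IOS->wax impression (occlusal)", ios, wax, "occlusal", "impression",
        params.teeth_icp, rng, params.step_translation_sd, params.step_rotation_sd,
        chain, injected,
    )
    pose = compose(invert(t_rest_to_photo), compose(t_wax_to_photo, t_ios_to_wax))
    return FusionModel("B", pose, chain, injected)


def run_method_c(scans: dict[str, ModalityScan], params: WorkflowParams | None = None) -> FusionModel:
    """CBCT gold-standard fusion (2 steps)."""
    params = params or WorkflowParams()
    for tag in ("IOS", "PHOTO_REST", "CBCT_SKIN", "CBCT_TEETH"):
        if tag not in scans:
            raise ValueError(f"method C requires scan {tag}")
    rng = _rng_for(params, "C") if params.perturb_reference else None
    chain: list[RegistrationResult] = []
    injected: list[RigidTransform] = []
    ios = scans["IOS"].mesh
    rest = scans["PHOTO_REST"].mesh
    skin = scans["CBCT_SKIN"].mesh
    teeth = scans["CBCT_TEETH"].mesh

    t_ios_to_cbct = _register_step(
        "C1 IOS->CBCT teeth", ios, teeth, None, None,
        params.teeth_icp, rng, params.step_translation_sd, params.step_rotation_sd,
        chain, injected,
    )
    # the CBCT field of view truncates the forehead, so the ICP runs from
    # the (smaller) CBCT matching area onto the full rest face and is
    # inverted; the step still maps the rest photo into the CBCT frame.
    # coarse alignment uses the zygomatic area only — the stable region
    # fully visible on both surfaces (the truncated forehead would bias a
    # centroid match)
    t_rest_to_cbct = _register_step(
        "C2 rest->CBCT skin (forehead+zygoma)", rest, skin,
        ["forehead", "zygoma"], ["forehead", "zygoma"],
        params.surface_icp, rng, params.step_translation_sd, params.step_rotation_sd,
        chain, injected, invert_direction=True,
        init_source_region=["zygoma"], init_target_region=["zygoma"],
    )
    pose = compose(invert(t_rest_to_cbct), t_ios_to_cbct)
    return FusionModel("C", pose, chain, injected)


def compare_methods(
    exp: FusionModel, ref: FusionModel, center: np.ndarray
) -> PoseDeviation:
    """Absolutized 6-DOF deviation of *exp* from *ref* at the maxilla
    measuring point (given in the IOS frame both poses act on)."""
    center = np.asarray(center, dtype=np.float64).reshape(3)
    # evaluate at the maxilla center as placed by the reference model
    center_ref = ref.maxilla_pose.apply(center)
    dev = pose_deviation(exp.maxilla_pose, ref.maxilla_pose, center_ref)
    return absolutize(dev)


@dataclass
class CohortResult:
    """Per-subject deviations for the three method pairs."""

    table: pd.DataFrame  # columns: subject, pair, dx..yaw, euclidean
    subject_seeds: list[int]
    config: dict

    def series(self, pair: str, outcome: str) -> np.ndarray:
        sel = self.table[self.table["pair"] == pair].sort_values("subject")
        return sel[outcome].to_numpy()


def fuse_subject(
    scans: dict[str, ModalityScan], params: WorkflowParams
) -> dict[str, FusionModel]:
    return {
        "A": run_method_a(scans, params),
        "B": run_method_b(scans, params),
        "C": run_method_c(scans, params),
    }


def deviations_for_subject(
    models: dict[str, FusionModel],
    ios_mesh: TriMesh,
    anatomical_frame: RigidTransform | None = None,
) -> dict[str, PoseDeviation]:
    """A-C, B-C, A-B deviations at one shared measuring point per subject.

    If ``anatomical_frame`` (the true transform carrying the phantom into
    the rest-photo frame) is supplied — available in simulation, where the
    anatomical axes of the phantom are known — the deviations are
    expressed along those axes; otherwise along the rest scan's own axes.
    """
    center = maxilla_center(ios_mesh)
    if anatomical_frame is not None:
        inv_f = invert(anatomical_frame)
        models = {
            m: FusionModel(fm.method, compose(inv_f, fm.maxilla_pose), fm.chain, fm.injected)
            for m, fm in models.items()
        }
    return {
        "A-C": compare_methods(models["A"], models["C"], center),
        "B-C": compare_methods(models["B"], models["C"], center),
        "A-B": compare_methods(models["A"], models["B"], center),
    }


def run_cohort(
    n_subjects: int,
    spec: PhantomSpec | None = None,
    noise: AcquisitionNoise | None = None,
    base_seed: int = 0,
    params: WorkflowParams | None = None,
    fusion_seed: int | None = None,
) -> CohortResult:
    """Simulate a cohort: per subject a fresh phantom, seven scans, three
    fusion models, and the three absolutized deviation rows.

    ``fusion_seed`` controls only the per-step perturbation draws, so
    replicate analyses can re-fuse identical scans with a different
    operator realisation.  A subject whose fusion fails is recorded in
    ``config['failed_subjects']`` and skipped.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    spec = spec or PhantomSpec()
    noise = noise or AcquisitionNoise()
    params = params or WorkflowParams()
    if fusion_seed is None:
        fusion_seed = base_seed

    rows = []
    seeds = []
    failed: list[int] = []
    for i in range(n_subjects):
        subject_seed = int((base_seed + 1) * 100003 + i) % (2**31 - 1)
        seeds.append(subject_seed)
        phantom = make_phantom(replace(spec, seed=subject_seed))
        scans = simulate_all(phantom, replace(noise, seed=subject_seed))
        p = replace(params, seed=int((fusion_seed + 1) * 99991 + i) % (2**31 - 1))
        try:
            models = fuse_subject(scans, p)
            devs = deviations_for_subject(
                models, scans["IOS"].mesh, scans["PHOTO_REST"].true_transform
            )
        except FusionStepError as exc:
            failed.append(i)
            continue
        for pair, d in devs.items():
            rows.append({"subject": i, "pair": pair, **d.components()})
    table = pd.DataFrame(rows)
    config = {
        "spec": spec.__dict__ | {},
        "noise": {k: v for k, v in noise.__dict__.items() if k != "vertex_sd_by_tag"},
        "step_translation_sd": params.step_translation_sd,
        "step_rotation_sd": params.step_rotation_sd,
        "base_seed": base_seed,
        "fusion_seed": fusion_seed,
        "failed_subjects": failed,
        "absolutized": True,
    }
    return CohortResult(table=table, subject_seeds=seeds, config=config)
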