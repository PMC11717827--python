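"""Ground-truth craniofacial phantoms and simulated acquisitions.

No patient scans ship with this package, so every workflow is exercised on
a parametric phantom: a superellipsoid head, a maxillary dental arch of
box-like tooth crowns placed along a parabola, and a bite-fork tracer — a
fork under the occlusal plane, a stalk leaving the mouth, and a matching
plate with three registration knobs (the "transmission balls" of physical
tracers) at a configurable lever-arm distance from the dentition.
Everything is analytic, so the ground-truth maxilla pose is exact.

:func:`simulate_modality` derives the seven acquisitions a clinical
dataset would contain: the intra-oral scan, facial photos at rest / with
cheek retractors (lower face deformed outward, anterior crowns exposed) /
with the tracer in situ, CBCT skin (forehead truncated, as cone-beam
fields of view do) and teeth surfaces, and a scan of the tracer with the
occlusal wax impression.  Each scan lives in its own random acquisition
frame; the true frame transform is stored for oracles and hidden from the
workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh_core import TriMesh
from .rigid_geometry import RigidTransform, maxilla_center

__all__ = [
    "PhantomSpec",
    "Phantom",
    "AcquisitionNoise",
    "ModalityScan",
    "MODALITY_TAGS",
    "make_phantom",
    "simulate_modality",
    "simulate_all",
    "perturb_transform",
]

MODALITY_TAGS = (
    "IOS",
    "PHOTO_REST",
    "PHOTO_RETRACTOR",
    "PHOTO_TRACER",
    "CBCT_SKIN",
    "CBCT_TEETH",
    "TRACER_WAX",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Physical parameters of one synthetic subject (all lengths in mm)."""

    head_width: float = 140.0
    head_height: float = 180.0
    head_depth: float = 150.0
    superellipse_power: float = 2.4  # 2 = ellipsoid; larger = boxier skull
    arch_width: float = 60.0
    arch_depth: float = 45.0
    tooth_count: int = 14
    tooth_width: float = 7.0
    tooth_height: float = 9.0
    tooth_depth: float = 7.0
    lever_arm: float = 60.0  # dentition to tracer matching plate
    tracer_plate_size: float = 40.0
    bite_fork_thickness: float = 3.0
    edge_length: float = 5.0  # target mesh resolution
    subject_variation: float = 0.05  # fractional anatomy jitter per seed
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "head_width",
            "head_height",
            "head_depth",
            "arch_width",
            "arch_depth",
            "tooth_width",
            "tooth_height",
            "tooth_depth",
            "lever_arm",
            "tracer_plate_size",
            "edge_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tooth_count < 6:
            raise ValueError("tooth_count must be >= 6 (canine-to-canine visibility)")
        if self.arch_width >= self.head_width:
            raise ValueError("dental arch cannot be wider than the head")


@dataclass
class Phantom:
    """One synthetic subject, all components in a single ground-truth frame."""

    spec: PhantomSpec
    head: TriMesh
    dentition: TriMesh
    tracer: TriMesh
    maxilla_pose: RigidTransform  # pose of the maxilla in the head frame
    maxilla_center: np.ndarray


@dataclass(frozen=True)
class AcquisitionNoise:
    """Imperfection model for the simulated acquisitions.

    vertex_sd is scanner surface noise (mm) applied per modality
    (overridable per tag); retractor_amplitude the outward cheek
    deformation; step_translation_sd / step_rotation_sd the per-
    registration-step perturbation used by the fusion workflows;
    truncation_height how far below the top of the skull the CBCT field of
    view is cut.  frame_translation / frame_rotation bound the random
    acquisition frames.
    """

    vertex_sd: float = 0.05
    vertex_sd_by_tag: dict[str, float] = field(default_factory=dict)
    retractor_amplitude: float = 8.0
    step_translation_sd: float = 0.30
    step_rotation_sd: float = 0.2  # degrees
    truncation_height: float = 45.0
    frame_translation: float = 20.0
    frame_rotation: float = 15.0  # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vertex_sd", "step_translation_sd", "step_rotation_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def sd_for(self, tag: str) -> float:
        return self.vertex_sd_by_tag.get(tag, self.vertex_sd)


@dataclass
class ModalityScan:
    """One simulated acquisition.

    Workflows may read ``mesh`` and ``tag`` only; ``true_transform`` (the
    acquisition frame: mesh = true_transform applied to phantom-frame
    surface) exists for ground-truth oracles.
    """

    tag: str
    mesh: TriMesh
    true_transform: RigidTransform


# ---------------------------------------------------------------------------
# geometry builders
# ---------------------------------------------------------------------------


def _superellipsoid_head(spec: PhantomSpec, rng: np.random.Generator) -> TriMesh:
    a = spec.head_width / 2
    b = spec.head_height / 2
    c = spec.head_depth / 2
    jit = 1.0 + spec.subject_variation * rng.uniform(-1, 1, size=3)
    a, b, c = a * jit[0], b * jit[1], c * jit[2]
    mean_r = (a + b + c) / 3
    n_lon = max(24, int(np.ceil(2 * np.pi * mean_r / spec.edge_length)))
    n_lat = max(12, int(np.ceil(np.pi * mean_r / spec.edge_length)))

    lat = np.linspace(-np.pi / 2, np.pi / 2, n_lat + 1)[1:-1]  # poles added below
    lon = np.linspace(-np.pi, np.pi, n_lon, endpoint=False)
    LON, LAT = np.meshgrid(lon, lat)
    # direction on the unit sphere; y up, z anterior at lon = 0
    d = np.stack(
        [np.cos(LAT) * np.sin(LON), np.sin(LAT), np.cos(LAT) * np.cos(LON)], axis=-1
    ).reshape(-1, 3)
    p = spec.superellipse_power
    scale = (
        np.abs(d[:, 0] / a) ** p + np.abs(d[:, 1] / b) ** p + np.abs(d[:, 2] / c) ** p
    ) ** (-1.0 / p)
    verts = d * scale[:, None]

    bottom = np.array([[0.0, -b, 0.0]])
    top = np.array([[0.0, b, 0.0]])
    verts = np.vstack([verts, bottom, top])
    i_bot, i_top = len(verts) - 2, len(verts) - 1

    def vid(i_lat: int, i_lon: int) -> int:
        return i_lat * n_lon + (i_lon % n_lon)

    faces = []
    n_rows = n_lat - 1
    for i in range(n_rows - 1):
        for j in range(n_lon):
            v00, v01 = vid(i, j), vid(i, j + 1)
            v10, v11 = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append([v00, v01, v11])
            faces.append([v00, v11, v10])
    for j in range(n_lon):
        faces.append([i_bot, vid(0, j + 1), vid(0, j)])
        faces.append([i_top, vid(n_rows - 1, j), vid(n_rows - 1, j + 1)])

    mesh = TriMesh(verts, np.asarray(faces))
    _label_head_regions(mesh, b, c)
    return mesh


def _label_head_regions(mesh: TriMesh, half_height: float, half_depth: float) -> None:
    v = mesh.vertices
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    front = z > 0.25 * half_depth
    mesh.regions["forehead"] = np.flatnonzero(
        front & (y > 0.33 * half_height) & (y < 0.80 * half_height) & (np.abs(x) < 50)
    )
    mesh.regions["zygoma"] = np.flatnonzero(
        front & (y > 0.05 * half_height) & (y < 0.30 * half_height) & (np.abs(x) > 25)
    )
    mesh.regions["cheeks"] = np.flatnonzero(
        (z > 0.15 * half_depth) & (y > -0.72 * half_height) & (y < -0.05 * half_height)
    )
    mesh.regions["lips"] = np.flatnonzero(
        (z > 0.80 * half_depth)
        & (y > -0.50 * half_height)
        & (y < -0.24 * half_height)
        & (np.abs(x) < 22)
    )


def _unit_box_grid(n: int = 2):
    """Unit-cube surface grid with n segments per edge, welded.

    Returns (vertices, faces); faces wind outward.
    """
    u = np.linspace(0.0, 1.0, n + 1)
    patches = []
    for axis in range(3):
        for side in (0.0, 1.0):
            UU, VV = np.meshgrid(u, u)
            flat = np.full(UU.size, side)
            cols = [None, None, None]
            cols[axis] = flat
            other = [k for k in range(3) if k != axis]
            cols[other[0]] = UU.ravel()
            cols[other[1]] = VV.ravel()
            pts = np.stack(cols, axis=-1)
            f = []
            for i in range(n):
                for j in range(n):
                    v00 = i * (n + 1) + j
                    v01 = v00 + 1
                    v10 = v00 + (n + 1)
                    v11 = v10 + 1
                    if (side == 1.0) ^ (axis == 1):
                        f.append([v00, v01, v11])
                        f.append([v00, v11, v10])
                    else:
                        f.append([v00, v11, v01])
                        f.append([v00, v10, v11])
            patches.append((pts, np.asarray(f)))
    verts = np.vstack([p for p, _ in patches])
    offs = np.cumsum([0] + [len(p) for p, _ in patches[:-1]])
    faces = np.vstack([f + o for (_, f), o in zip(patches, offs)])
    key = np.round(verts / 1e-9).astype(np.int64)
    _, first, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return verts[first], inv[faces]


def _merge(meshes: list[TriMesh]) -> TriMesh:
    verts = []
    faces = []
    regions: dict[str, list[np.ndarray]] = {}
    off = 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        for name, idx in m.regions.items():
            regions.setdefault(name, []).append(idx + off)
        off += m.n_vertices
    return TriMesh(
        np.vstack(verts),
        np.vstack(faces),
        {k: np.concatenate(v) for k, v in regions.items()},
    )


def _dental_arch(spec: PhantomSpec, rng: np.random.Generator) -> TriMesh:
    """Maxillary dentition: tooth crowns along a parabolic arch.

    Arch apex (incisors) sits anterior in the mouth; crowns hang downward
    from the gum line with the occlusal surfaces at the bottom.
    """
    jit = 1.0 + spec.subject_variation * rng.uniform(-1, 1, size=2)
    w = spec.arch_width * jit[0]
    d = spec.arch_depth * jit[1]
    z_front = 0.78 * spec.head_depth / 2  # incisor plane inside the face
    y_gum = -0.30 * spec.head_height / 2

    # equal arc-length placement along z = z_front - d s^2, x = (w/2) s
    s_fine = np.linspace(-1, 1, 512)
    dx = w / 2
    dzds = -2 * d * s_fine
    ds = s_fine[1] - s_fine[0]
    arc = np.concatenate([[0], np.cumsum(np.hypot(dx, dzds)[:-1] * ds)])
    total = arc[-1]
    centers_arc = (np.arange(spec.tooth_count) + 0.5) / spec.tooth_count * total
    s_teeth = np.interp(centers_arc, arc, s_fine)

    bv, bf = _unit_box_grid(2)
    n_ant = 6
    i_lo = (spec.tooth_count - n_ant) // 2
    anterior_set = set(range(i_lo, i_lo + n_ant))

    teeth = []
    for i, s in enumerate(s_teeth):
        tx, tz = dx, -2 * d * s
        tl = np.hypot(tx, tz)
        tang = np.array([tx / tl, 0.0, tz / tl])
        up = np.array([0.0, 1.0, 0.0])
        outward = np.cross(tang, up)  # points away from the arch interior
        R = np.stack([tang, up, outward], axis=1)
        local = bv.copy()
        local[:, 0] = (local[:, 0] - 0.5) * spec.tooth_width
        local[:, 1] = (local[:, 1] - 1.0) * spec.tooth_height  # crown below gum
        local[:, 2] = (local[:, 2] - 0.5) * spec.tooth_depth
        pos = np.array([w / 2 * s, y_gum, z_front - d * s * s])
        world = local @ R.T + pos
        m = TriMesh(world, bf.copy())
        occl = np.flatnonzero(np.abs(bv[:, 1]) < 1e-9)  # local bottom face
        m.regions["occlusal"] = occl
        if i in anterior_set:
            m.regions["anterior_teeth"] = np.flatnonzero(np.abs(bv[:, 2] - 1.0) < 1e-9)
        teeth.append(m)

    dent = _merge(teeth)
    dent.regions["maxilla"] = np.arange(dent.n_vertices)
    return dent


def _tracer(spec: PhantomSpec, dentition: TriMesh) -> TriMesh:
    """Bite-fork tracer: fork under the occlusal plane, stalk out of the
    mouth, matching plate with three knobs at the lever-arm distance, and
    the wax impression surface (a negative of the occlusal region)."""
    occ_idx = dentition.region_index("occlusal")
    occ_pts = dentition.vertices[occ_idx]
    y_occ = occ_pts[:, 1].min()
    z_ant = occ_pts[:, 2].max()
    x_mid = 0.0

    bv, bf = _unit_box_grid(2)

    def box(cx, cy, cz, sx, sy, sz) -> TriMesh:
        v = bv.copy()
        v[:, 0] = (v[:, 0] - 0.5) * sx + cx
        v[:, 1] = (v[:, 1] - 0.5) * sy + cy
        v[:, 2] = (v[:, 2] - 0.5) * sz + cz
        return TriMesh(v, bf.copy())

    t = spec.bite_fork_thickness
    fork = box(x_mid, y_occ - t / 2, z_ant - 12.0, 44.0, t, 30.0)
    stalk = box(x_mid, y_occ - t / 2, z_ant + spec.lever_arm / 2, 10.0, t, spec.lever_arm)
    plate_z = z_ant + spec.lever_arm
    ps = spec.tracer_plate_size
    plate = box(x_mid, y_occ - t / 2, plate_z + 2.0, ps, ps, 4.0)
    knobs = []
    for kx, ky in ((-ps / 3, -ps / 3), (ps / 3, -ps / 3), (0.0, ps / 3)):
        knobs.append(box(kx, y_occ - t / 2 + ky, plate_z + 6.0, 6.0, 6.0, 6.0))
    for part in (plate, *knobs):
        part.regions["tracer_body"] = np.arange(part.n_vertices)

    # wax impression: replica of the occlusal surface geometry in situ
    from .mesh_core import extract_region

    impression = extract_region(dentition, "occlusal")
    impression.regions = {"impression": np.arange(impression.n_vertices)}

    return _merge([fork, stalk, plate, *knobs, impression])


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build one subject; bit-identical for identical spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    head = _superellipsoid_head(spec, rng)
    dentition = _dental_arch(spec, rng)
    tracer = _tracer(spec, dentition)
    return Phantom(
        spec=spec,
        head=head,
        dentition=dentition,
        tracer=tracer,
        maxilla_pose=RigidTransform.identity(),
        maxilla_center=maxilla_center(dentition),
    )


# ---------------------------------------------------------------------------
# acquisition simulation
# ---------------------------------------------------------------------------


def perturb_transform(
    translation_sd: float, rotation_sd: float, seed: int | np.random.Generator
) -> RigidTransform:
    """Random small rigid motion: per-axis normal translation, rotation by
    |N(0, rotation_sd^2)| degrees about a uniformly random axis."""
    if translation_sd < 0 or rotation_sd < 0:
        raise ValueError("perturbation sds must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = rng.normal(0.0, translation_sd, size=3) if translation_sd > 0 else np.zeros(3)
    if rotation_sd > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(abs(rng.normal(0.0, rotation_sd)))
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(axis * angle).as_matrix()
    else:
        R = np.eye(3)
    return RigidTransform(R, t)


def _random_frame(noise: AcquisitionNoise, rng: np.random.Generator) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    t = rng.uniform(-noise.frame_translation, noise.frame_translation, size=3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-noise.frame_rotation, noise.frame_rotation))
    return RigidTransform(Rotation.from_rotvec(axis * angle).as_matrix(), t)


def _retractor_deform(head: TriMesh, amplitude: float) -> TriMesh:
    """Smooth outward radial bump on the lower-face band (cheek retractors)."""
    out = head.copy()
    v = out.vertices
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    y_lo, y_hi = y.min() * 0.80, y.max() * (-0.02)
    wy = np.clip((y - y_lo) / (y_hi - y_lo), 0, 1)
    wy = np.sin(np.pi * wy) ** 2
    phi = np.arctan2(x, z)  # 0 at the front of the face
    wphi = np.where(np.abs(phi) < np.deg2rad(75), np.cos(phi * (90 / 75)) ** 2, 0.0)
    w = amplitude * wy * wphi
    r = np.hypot(x, z)
    r_safe = np.where(r < 1e-9, 1.0, r)
    v[:, 0] += w * x / r_safe
    v[:, 2] += w * z / r_safe
    return out


def _truncate_above(mesh: TriMesh, y_cut: float) -> TriMesh:
    keep_v = mesh.vertices[:, 1] <= y_cut
    face_keep = keep_v[mesh.faces].all(axis=1)
    faces = mesh.faces[face_keep]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    regions = {}
    for name, idx in mesh.regions.items():
        kept = remap[idx]
        kept = kept[kept >= 0]
        if len(kept):
            regions[name] = kept
    return TriMesh(mesh.vertices[used], remap[faces], regions)


def _base_surface(phantom: Phantom, tag: str, noise: AcquisitionNoise) -> TriMesh:
    from .mesh_core import extract_region

    if tag == "IOS":
        return phantom.dentition.copy()
    if tag == "PHOTO_REST":
        return phantom.head.copy()
    if tag == "PHOTO_RETRACTOR":
        deformed = _retractor_deform(phantom.head, noise.retractor_amplitude)
        crowns = extract_region(phantom.dentition, "anterior_teeth")
        crowns.regions = {"anterior_teeth": np.arange(crowns.n_vertices)}
        return _merge([deformed, crowns])
    if tag == "PHOTO_TRACER":
        head = phantom.head.copy()
        head.regions.pop("lips", None)  # lips occluded around the bite fork
        visible = extract_region(phantom.tracer, "tracer_body")
        visible.regions = {"tracer_body": np.arange(visible.n_vertices)}
        return _merge([head, visible])
    if tag == "CBCT_SKIN":
        y_cut = phantom.head.vertices[:, 1].max() - noise.truncation_height
        return _truncate_above(phantom.head, y_cut)
    if tag == "CBCT_TEETH":
        return phantom.dentition.copy()
    if tag == "TRACER_WAX":
        return phantom.tracer.copy()
    raise ValueError(f"unknown modality tag {tag!r}")


def simulate_modality(
    phantom: Phantom, tag: str, noise: AcquisitionNoise
) -> ModalityScan:
    """Simulate one acquisition: select/deform the surface, add vertex
    noise, and place it in a random acquisition frame (seeded by
    ``noise.seed`` and the tag, so each modality is independent but the
    whole dataset is reproducible).

    The CBCT skin and teeth surfaces are segmented from one volume, so
    they share a single acquisition frame; every other modality gets its
    own."""
    if tag not in MODALITY_TAGS:
        raise ValueError(f"unknown modality tag {tag!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([noise.seed, MODALITY_TAGS.index(tag)])
    )
    frame_key = "CBCT" if tag in ("CBCT_SKIN", "CBCT_TEETH") else tag
    frame_rng = np.random.default_rng(
        np.random.SeedSequence([noise.seed, 1000 + MODALITY_TAGS.index(
            "CBCT_SKIN" if frame_key == "CBCT" else tag)])
    )
    mesh = _base_surface(phantom, tag, noise)
    sd = noise.sd_for(tag)
    if sd > 0:
        mesh.vertices = mesh.vertices + rng.normal(0.0, sd, size=mesh.vertices.shape)
    frame = _random_frame(noise, frame_rng)
    mesh = mesh.transformed(frame.matrix())
    return ModalityScan(tag=tag, mesh=mesh, true_transform=frame)


def simulate_all(phantom: Phantom, noise: AcquisitionNoise) -> dict[str, ModalityScan]:
    """All seven acquisitions for one subject."""
    return {tag: simulate_modality(phantom, tag, noise) for tag in MODALITY_TAGS}
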