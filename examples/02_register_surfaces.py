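"""Region-restricted rigid registration of two facial surfaces.

Displaces a phantom head by a known rigid motion, then recovers that
motion by trimmed ICP restricted to the forehead — the matching area used
whenever the lower face cannot be trusted (cheek retractors, tracer).
"""

import numpy as np
from scipy.spatial.transform import Rotation

from dentofuse import PhantomSpec, RigidTransform, make_phantom
from dentofuse.registration import coarse_align, icp_register
from dentofuse.rigid_geometry import compose, invert

head = make_phantom(PhantomSpec(seed=2)).head

truth = RigidTransform(
    Rotation.from_euler("xyz", [4.0, -9.0, 2.0], degrees=True).as_matrix(),
    np.array([12.0, -5.0, 18.0]),
)
target = head.transformed(truth.matrix())
target.vertices = target.vertices + np.random.default_rng(2).normal(0, 0.05, target.vertices.shape)

init = coarse_align(head, target, "forehead", "forehead")
result = icp_register(head, target, "forehead", "forehead", init)

err = compose(result.transform, invert(truth))
t_err = np.linalg.norm(err.translation)
r_err = np.rad2deg(np.arccos(np.clip((np.trace(err.rotation) - 1) / 2, -1, 1)))
print(f"converged: {result.converged} after {result.n_iterations} iterations")
print(f"RMS residual:      {result.rms_residual:.4f} mm")
print(f"recovery error:    {t_err:.4f} mm, {r_err:.4f} deg")

# With 0.05 mm scanner noise the forehead-only registration recovers the
# true motion to a few hundredths of a millimetre/degree — well inside the
# ~0.3 mm error budget of one superimposition step.
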