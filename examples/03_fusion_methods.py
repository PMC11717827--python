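"""Run the three fusion workflows on one subject and compare them.

Method A (cheek retractors) and method B (bite-fork tracer) place the
intra-oral scan in the rest-face frame without ionizing imaging; method C
does it through a CBCT and serves as the reference.  The 6-DOF deviation
of A and B from C at the maxilla's measuring point is the accuracy
readout.
"""

from dentofuse import (
    AcquisitionNoise,
    PhantomSpec,
    WorkflowParams,
    deviations_for_subject,
    fuse_subject,
    make_phantom,
    simulate_all,
)

phantom = make_phantom(PhantomSpec(seed=4))
scans = simulate_all(phantom, AcquisitionNoise(vertex_sd=0.05, seed=4))

# 0.30 mm / 0.2 deg residual error per registration step, as a careful
# operator leaves behind
params = WorkflowParams(step_translation_sd=0.30, step_rotation_sd=0.2, seed=4)
models = fuse_subject(scans, params)
for m, fm in models.items():
    print(f"method {m}: {fm.chain_length} registration steps, "
          f"residuals {[round(r.rms_residual, 3) for r in fm.chain]} mm")

devs = deviations_for_subject(
    models, scans["IOS"].mesh, scans["PHOTO_REST"].true_transform
)
print("\npair   dX     dY     dZ    eucl   roll  pitch   yaw   (mm / deg, absolutized)")
for pair, d in devs.items():
    c = d.components()
    print("%s  %5.2f  %5.2f  %5.2f  %5.2f  %5.2f  %5.2f  %5.2f" % (
        pair, c["dx"], c["dy"], c["dz"], c["euclidean"], c["roll"], c["pitch"], c["yaw"]))

# Deviations are the displacement of the maxilla centre along the
# transversal (X), vertical (Y) and sagittal (Z) axes plus the relative
# roll/pitch/yaw; values under 2 mm / 2 deg are clinically acceptable.
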