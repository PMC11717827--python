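"""Build a synthetic subject and simulate its seven acquisitions.

The phantom is a parametric head with a maxillary dental arch and a
bite-fork tracer; the simulator derives from it the scans a clinical
fusion dataset would contain, each in its own random acquisition frame.
"""

from dentofuse import AcquisitionNoise, PhantomSpec, make_phantom, simulate_all

phantom = make_phantom(PhantomSpec(seed=1))
print("head:      %5d vertices, regions %s" % (
    phantom.head.n_vertices, sorted(phantom.head.regions)))
print("dentition: %5d vertices, regions %s" % (
    phantom.dentition.n_vertices, sorted(phantom.dentition.regions)))
print("maxilla measuring point (mm):", phantom.maxilla_center.round(2))

scans = simulate_all(phantom, AcquisitionNoise(vertex_sd=0.05, seed=1))
for tag, scan in scans.items():
    print(f"{tag:15s} {scan.mesh.n_vertices:5d} vertices, "
          f"frame shift {abs(scan.true_transform.translation).max():5.1f} mm")

# Each scan is the corresponding phantom surface (with 0.05 mm scanner
# noise) carried into a random rigid acquisition frame; the workflows see
# only the meshes, while the true frames stay available as ground truth.
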