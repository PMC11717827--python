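"""Demonstrate the lever principle on the tracer workflow.

A rotational residual in the tracer-plate registration displaces the
dentition in proportion to the distance between the plate and the teeth.
Sweeping that lever arm with fixed rotational step noise makes the
amplification visible in the tracer workflow's translational deviation.
"""

from dentofuse import PhantomSpec, WorkflowParams, run_cohort

params = WorkflowParams(step_translation_sd=0.0, step_rotation_sd=0.2)
print("lever arm (mm)   mean B-C euclidean deviation (mm)")
for lever in (40.0, 60.0, 90.0, 120.0):
    cohort = run_cohort(
        20, spec=PhantomSpec(lever_arm=lever), base_seed=3, params=params
    )
    print(f"{lever:10.0f}       {cohort.series('B-C', 'euclidean').mean():.3f}")

# The deviation grows with the lever arm: designing a tracer whose
# matching surface sits close to the dentition directly improves accuracy.
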