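"""Generate a small synthetic cine cohort and write it to disk.

Builds six phantom patients (four with a hypokinetic scar sector, two
controls), renders each slice as a NIfTI cine loop with a JSON contour
sidecar, and prints the manifest summary.
"""

from pathlib import Path

from cinescar import PhantomConfig, generate_cohort, read_manifest, write_cohort

base = PhantomConfig(
    grid_size=64, n_frames=30, center=(32.0, 32.0), r_endo_ed=12.0,
    wall_thickness_ed=6.0, contraction_fraction=0.25,
    scar_motion_ratio=0.1, noise_sigma=6.0,
)
patients = generate_cohort(
    n_scar_patients=4, n_control_patients=2, slices_per_patient=2,
    base_config=base, seed=42,
)
out_dir = Path("scratch/example_cohort")
manifest = write_cohort(patients, out_dir)
records = read_manifest(manifest)

print(f"wrote {len(records)} slices for {len(patients)} patients -> {manifest}")
for rec in records:
    print(f"  {rec.patient_id} slice {rec.slice_index}: {rec.gt_label}")
# SCAR slices carry an angular sector whose wall moves at 10% of normal
# excursion; NL slices contract uniformly. Labels come from the generator.
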