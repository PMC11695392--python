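"""Train the residual CNN on the reference synthetic study, P1 vs P2.

Generates the desk-scale cohort (32 scar + 20 control patients, 3 slices
each), splits it patient-wise with stratification, trains one model per
protocol and prints slice- and patient-level test metrics.  P1 sees only
the static myocardium-masked ED frame; P2 adds the Fourier amplitude map,
which carries the wall-motion deficit of the scar sector.

Takes a few minutes on one CPU core.
"""

from cinescar.pipeline import run_experiment, small_study_conditions

seed = 0
patients, pipe_cfg, model_cfg, train_cfg = small_study_conditions(seed)
print(f"cohort: {len(patients)} patients, "
      f"{sum(len(p.slices) for p in patients)} slices")

for proto in ("P1", "P2"):
    result = run_experiment(patients, proto, pipe_cfg, model_cfg, train_cfg, seed)
    s, p = result.slice_report, result.patient_report
    print(f"\n{proto} ({result.n_train} train / {result.n_val} val / "
          f"{result.n_test} test slices, {len(result.history['val_loss'])} epochs)")
    print(f"  slice:   acc {s.accuracy:.3f}  F1 {s.f1:.3f}  sens {s.sensitivity:.3f}"
          f"  spec {s.specificity:.3f}  AUC {s.auc:.3f}")
    print(f"  patient: acc {p.accuracy:.3f}  sens {p.sensitivity:.3f}"
          f"  spec {p.specificity:.3f}")
# Expected pattern: P2 clearly outperforms P1 at slice level because the
# static ED frame alone carries no motion information - in the phantom the
# scar is *only* visible through its reduced contraction.
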