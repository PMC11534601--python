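"""The staged curriculum vs the gold-only baseline on a small synthetic
cohort (a few minutes on one CPU at these miniature settings).

Run:  python examples/03_train_curriculum.py
"""
import warnings

from m3sl import TrainConfig, generate_cohort, run_baseline, run_m3sl

warnings.filterwarnings("ignore")

cohort = generate_cohort(n=16, master_seed=11, cube_edge=64)
print(f"cohort: {len(cohort.unannotated())} un-annotated subjects "
      f"(bronze/silver tiers), {len(cohort.annotated())} expert-annotated")

cfg = TrainConfig.desk_scale(seed=11)
cfg.folds = 3
cfg.epochs_by_stage = {"bronze": 3, "silver": 2, "gold": 2}

m3sl_run = run_m3sl(cohort.unannotated(), cohort.unannotated(),
                    cohort.annotated(), cfg)
base_run = run_baseline(cohort.annotated(), cfg)

print(f"curriculum  mean F = {m3sl_run.mean_f():.3f}, "
      f"mean IoU = {m3sl_run.mean_iou():.3f}")
print(f"baseline    mean F = {base_run.mean_f():.3f}, "
      f"mean IoU = {base_run.mean_iou():.3f}")
print("Pre-training on the noisy bronze tier and the STAPLE silver tier, "
      "with progressive encoder freezing, gives the curriculum its head "
      "start over training on the small gold tier alone.")
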