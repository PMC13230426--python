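"""Train a small professor network and watch it repair teacher masks.

Generates a 14-phantom cohort, trains the dual-channel (CT + teacher mask)
correction network for a couple of minutes of CPU time on the
Underestimation Focuser scheme with two patient-grouped folds, and compares
teacher vs professor-corrected Dice on the out-of-fold cases.
"""

import pandas as pd

from profcorrect import ErrorModel, PhantomConfig, SCHEMES, generate_cohort
from profcorrect.nets import AugmentParams, TrainConfig, preset_configs
from profcorrect.orchestrate import assign_folds, phase2_professor

manifest = generate_cohort(14, PhantomConfig(), ErrorModel(), seed=11,
                           out_dir="scratch/example_professor/cohort")
folds = assign_folds(manifest["patient_id"].tolist(), k=2, seed=11)

result = phase2_professor(
    manifest, [SCHEMES["underestimation_focuser"]],
    preset_configs()["tiny_test"],
    TrainConfig(epochs=4, iters_per_epoch=25, batch_size=2, folds=2, seed=11,
                validate_every=10 ** 9,
                augmentation=AugmentParams(p_spatial=0.1, p_blur=0.0, p_noise=0.15,
                                           gaussian_noise_sd=0.05)),
    folds, "scratch/example_professor/phase2")

print("\ncross-validated scheme ranking (out-of-fold corrected DSC):")
print(result.ranking[["scheme", "mean_dsc", "sd_dsc"]].to_string(index=False))
# The CV DSC is measured on cases the fold model never trained on; with the
# erosion-dominant error model the learned corrector typically lifts the
# teacher's ~0.6 Dice into the 0.85-0.95 range.
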