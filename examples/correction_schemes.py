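"""The four correction schemes on a toy teacher/ground-truth pair.

Builds a 1-D "scan line" with every voxel category (TN, FN, TP, FP),
encodes it under each published scheme and applies the resulting map back
to the teacher mask. The printout shows which teacher errors each scheme
can represent — and therefore repair — and which it deliberately drops.
"""

import numpy as np

from profcorrect import BinaryMask, SCHEMES, apply_correction, decode_table, encode

y_true = BinaryMask(np.array([0, 1, 1, 0], np.uint8).reshape(1, 1, 4))
y_teach = BinaryMask(np.array([0, 0, 1, 1], np.uint8).reshape(1, 1, 4))

print("voxel categories:    [TN, FN, TP, FP]")
print(f"ground truth y_true: {y_true.data.ravel().tolist()}")
print(f"teacher y_teach:     {y_teach.data.ravel().tolist()}\n")

for scheme in SCHEMES.values():
    corr = encode(y_teach, y_true, scheme)
    y_prof = apply_correction(y_teach, corr)
    print(f"{scheme.name:24s} codes FN={scheme.fn_code} FP={scheme.fp_code} "
          f"TP={scheme.tp_code}")
    print(f"  y_corr map:   {corr.data.ravel().tolist()}")
    print(f"  decode table: {decode_table(scheme)}")
    print(f"  y_prof:       {y_prof.data.ravel().tolist()} "
          f"(ground truth is {y_true.data.ravel().tolist()})\n")

# Expected: pattern_discerner and inclusive_correction recover the ground
# truth exactly; underestimation_focuser fixes the missed voxel but keeps the
# teacher's false positive (its FP code collides with background);
# precision_priority reproduces the teacher unchanged.
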