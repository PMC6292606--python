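"""Derive the detection rates of the original study from its counts.

The published evaluation reports object-level confusion counts per cell
line (e.g. the combined set: 263 frames, 632 tumor cells, 587 detected, 45
missed, 51 false alarms).  This example reruns that arithmetic, including
the estimated negative class of 1270 cells per frame.
"""

from ctcdf import ConfusionCounts, compute_metrics

lines = {
    "HS 578T ": (83, 230, 5, 1),
    "MCF7    ": (60, 185, 15, 14),
    "DLD-1   ": (120, 168, 29, 36),
    "combined": (263, 587, 45, 51),
}

print("line      images   TP   FN  FP   sens%    FN%   estFP-rate  estSpec%")
for name, (n_images, tp, fn, fp) in lines.items():
    r = compute_metrics(ConfusionCounts(TP=tp, FN=fn, FP=fp, n_images=n_images))
    p = r.printed()
    print(f"{name}  {n_images:5d}  {tp:4d} {fn:4d} {fp:3d}  "
          f"{p['sensitivity_pct']:6.2f} {p['fn_rate_pct']:6.2f}   "
          f"{p['est_fp_rate']:8.4f}    {p['est_specificity_pct']:6.2f}")
# Rates are truncated at the printed precision (2 decimals; 4 for the
# estimated FP rate), the convention under which they are consistent with
# the integer counts.
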