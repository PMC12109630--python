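"""The two-round false-positive-relabeling procedure on corrupted labels.

A fraction q of true gland nuclei is relabeled stroma (one-sided
annotation misses, as happens in manual gland delineation).  Round 1
trains on those labels; its validation "false positives" — stroma-labeled
nuclei the model calls gland — are harvested and added to the training
set as positives; round 2 retrains.  The false-negative rate against the
HIDDEN truth should drop.
"""

from glandcell.experiments import recovery_trial

trial = recovery_trial(q=0.3, seed=0)

print(f"miss rate q = {trial.q}: round-1 FNR {100 * trial.fnr_round1:.1f}% "
      f"-> round-2 FNR {100 * trial.fnr_round2:.1f}% (vs hidden truth)")
print(f"harvested {trial.harvest_size} validation false positives, "
      f"{trial.harvest_true_flips} of them truly mislabeled gland nuclei "
      f"(precision {trial.harvest_precision:.2f}, base rate {trial.q})")
print("the drop mirrors, directionally, the validation FNR reductions the "
      "full-scale study reports for this procedure")
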