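"""Static vs dynamic stopping: the accuracy / selection-time trade-off.

Static stopping decides after a fixed number of sequences; dynamic stopping
ends the trial at the first stimulus where the leading class's scores beat
the pooled rest in a one-sided Welch test (alpha 0.05) after a minimum
sequence count.  ITR (bits/min) rewards faster selections.
"""

from asme.harness import ExperimentConfig, run_stopping_sweep, select_optimal
from asme.metrics import TimingInputs, itr, trial_duration

# the full-protocol arithmetic first
t_full = trial_duration(TimingInputs(450, 0.2, 1.0))
print(f"full online trial: {t_full:.1f} s -> perfect accuracy gives "
      f"{itr(30, 1.0, t_full):.2f} bits/min")

config = ExperimentConfig(seed=9, n_sequences=8)
sweep = run_stopping_sweep(config)
cols = ["strategy", "ns", "selection_time_s", "accuracy", "itr_bits_per_min"]
print("\nsweep over stopping rules (one synthetic participant):")
print(sweep[cols].round(3).to_string(index=False))

best = select_optimal(sweep)
print("\noptimal rows per criterion:")
print(best[cols + ["criterion"]].round(3).to_string(index=False))
print("\ndynamic stopping shortens selections once evidence accumulates, "
      "raising ITR at little accuracy cost.")
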