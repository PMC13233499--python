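"""Build the 30-class layout and one pseudorandomized trial schedule.

The speller maps QWERTY rows to pitch streams (top=high, middle=mid,
bottom=low).  A sequence presents all 30 classes once as ten low/mid/high
triplets; a trial repeats 15 sequences attending one target at an SOA of
0.2 s, i.e. 450 stimuli in ~90 s.
"""

from asme.paradigm import default_layout, make_trial_schedule

layout = default_layout()
target = next(c for c in layout if c.label == "T")
print(f"target: {target.label!r} (class {target.class_id}, "
      f"{target.row} row -> {target.stream} stream)")

sched = make_trial_schedule(layout, target.class_id, n_sequences=15, soa_s=0.2, rng_seed=1)
print(f"{len(sched)} stimuli, last onset {sched.events[-1].onset_s:.1f} s, "
      f"{sum(e.is_target for e in sched.events)} target presentations")

frame = sched.to_frame(layout)
print("\nfirst triplet of sequence 1 (streams cycle low, mid, high):")
print(frame.head(3)[["onset_s", "slot", "label", "stream", "is_target"]].to_string(index=False))

# each class appears exactly once per sequence
counts = frame.groupby("sequence")["class_id"].nunique()
print(f"\ndistinct classes per sequence: {counts.unique()}  (always 30)")
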