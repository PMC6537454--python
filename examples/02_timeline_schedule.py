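"""Event timeline: durations, the 15-s mount rule and the sampling schedule.

One annotated trial (times in seconds from recording start) is turned into
courtship/copulation durations and the posture-measurement schedule; the
periodic grid step depends on the species' mean copulation duration.
"""

from copasym import EventTimes, durations, is_valid_copulation, sampling_schedule

events = EventTimes(
    courtship_start_s=12.0,
    copulation_start_s=292.2,
    settling_s=352.2,
    copulation_end_s=1006.2,
)
court_min, cop_min = durations(events)
print(f"courtship {court_min:.2f} min, copulation {cop_min:.2f} min, "
      f"valid copulation: {is_valid_copulation(cop_min * 60)}")

for species, mean_min in [("D. nannoptera", 11.9), ("D. bromeliae", 0.92),
                          ("D. acanthoptera", 88.49)]:
    sched = sampling_schedule(events, species_mean_copulation_min=mean_min)
    pts = ", ".join(f"{lbl}@{t:.0f}s" for lbl, t in sched.timepoints)
    print(f"{species:16s} (mean {mean_min:6.2f} min): {pts}")
print("-> settling and the 10% stable-copulation point are always measured; species")
print("   with mean copulations over 2.5/15/60 min add a 2.5/5/10-min grid.")
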