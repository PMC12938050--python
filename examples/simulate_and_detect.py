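"""Simulate an olfactory-impaired-like group hour and detect its huddles.

Four agents wander a 76.2 cm arena at 30 fps; scheduled huddles grow
dyad -> triad -> quartet at corner-biased sites. The detector classifies
each frame's group state from the 5 cm / 1 min criteria.
"""

import huddlekit as hk
from huddlekit.proximity import events_table

rec, truth = hk.simulate_group(hk.SimConfig(phenotype="impaired", seed=7))
states, events = hk.classify_state_series(rec)

frac = hk.huddling_fraction(rec, states=None)
print(f"scheduled huddles: {len(truth.schedule.entries)}")
print(f"huddling fraction of the hour: {frac:.3f} "
      "(share of frames in any dyad/triad/quartet state)")
print()
print(events_table(events, rec).to_string(index=False))
print()
print("Each row is one constant-membership huddle segment; parent_id links a")
print("growth step (e.g. dyad -> triad) to the segment it grew out of, and")
print("region_class locates its centroid on the 4x4 arena grid.")
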