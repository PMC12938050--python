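"""Locomotion summaries and arena occupancy, with a screened two-sample test.

Impaired-phenotype groups travel less than controls (they spend minutes
stationed in huddles) while their top speeds stay comparable; occupancy maps
concentrate in the corner cells hosting the huddle sites.
"""

import numpy as np

import huddlekit as hk

dist = {"control": [], "impaired": []}
vmax = {"control": [], "impaired": []}
for phenotype in dist:
    for seed in range(4):
        rec, _ = hk.simulate_group(hk.SimConfig(phenotype=phenotype, seed=seed))
        for t in rec.trajectories:
            k = hk.kinematics(t)
            dist[phenotype].append(k["path_length"] / 100)  # m
            vmax[phenotype].append(k["max_speed"])

print("distance traveled (m, per mouse-hour):",
      {k: round(float(np.median(v)), 1) for k, v in dist.items()})
res = hk.choose_and_run_two_sample(dist["impaired"], dist["control"])
print(f"  {res.test}: stat={res.statistic:.1f}, p={res.p:.2g}, "
      f"{res.effect_convention}={res.effect_size:.2f}")

print("maximum speed (cm/s):",
      {k: round(float(np.median(v)), 1) for k, v in vmax.items()})

rec, _ = hk.simulate_group(hk.SimConfig(phenotype="impaired", seed=0))
occ = hk.occupancy_map(rec.trajectories[0], bins=4, arena=rec.arena)
print("\n4x4 occupancy (fraction of frames) for one impaired mouse:")
print(np.round(occ.T / occ.sum(), 2))  # transpose: rows = y (image convention)
print("High-mass corner cells mark the huddle sites.")
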