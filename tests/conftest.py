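import pytest

import huddlekit as hk


@pytest.fixture(scope="session")
def impaired_hour():
    """One impaired-phenotype hour with its detection output."""
    rec, gt = hk.simulate_group(hk.SimConfig(phenotype="impaired", seed=3))
    states, events = hk.classify_state_series(rec)
    return rec, gt, states, events


@pytest.fixture(scope="session")
def control_hour():
    rec, gt = hk.simulate_group(hk.SimConfig(phenotype="control", seed=11))
    return rec, gt


@pytest.fixture(scope="session")
def dyad_sims():
    """Dyad-only impaired simulations until >= 50 scheduled dyadic huddles."""
    sims = []
    n_entries = 0
    seed = 0
    while n_entries < 50:
        cfg = hk.SimConfig(
            phenotype="impaired", huddle_size=2, huddle_duration_range=(120.0, 300.0), seed=seed
        )
        rec, gt = hk.simulate_group(cfg)
        states, events = hk.classify_state_series(rec)
        sims.append((rec, gt, states, events))
        n_entries += len(gt.schedule.entries)
        seed += 1
    return sims


def dyadic_role_cases(sims):
    """(recording, scheduled entry, first overlapping dyadic event) triples."""
    cases = []
    for rec, gt, states, events in sims:
        fps = rec.fps
        for ent in gt.schedule.entries:
            s, e = int(ent.start * fps), int(ent.end * fps)
            dy = [
                ev
                for ev in events
                if ev.state == 2 and min(ev.end_frame, e) > max(ev.start_frame, s)
            ]
            if dy:
                cases.append((rec, ent, dy[0]))
    return cases
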