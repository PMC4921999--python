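"""Behavioral analysis: pointing-movement detection and response times.

Reads the sessions written by 01_simulate_campaign.py, repairs occlusions,
detects pointing movements from the finger-LED velocity profile (22% peak
threshold, 5% onset criterion), validates protocol markers against the
kinematics, sweeps the onset threshold 5%..53%, and runs the one-way RT ANOVA
with Tukey HSD across response conditions.  Writes rt_table.csv,
rt_sweep.csv and rt_stats.json under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from mobipipe.core import EventList, read_streamset
from mobipipe.motion import (compute_velocity, detect_movements,
                             interpolate_occlusions, response_time_stats,
                             sweep_onset_threshold, validate_trial_markers)

parser = argparse.ArgumentParser()
parser.add_argument("--sessions", default="results/sessions")
parser.add_argument("--out", default="results")
args = parser.parse_args()

out = Path(args.out)
rt_rows, sweep_rows = [], []
for sess_dir in sorted(Path(args.sessions).iterdir()):
    s = read_streamset(sess_dir)
    sid = s.meta.get("participant", sess_dir.name)
    finger = next(tr for tr in s.mocap if tr.led_id == "finger")
    prof = compute_velocity(interpolate_occlusions(finger))
    events = s.events
    pointing = EventList(events.df[
        (events.df["condition"] == "pointing")
        & events.df["kind"].isin(("standard", "distractor", "target"))
    ].reset_index(drop=True))
    moves = detect_movements(prof, float(np.max(prof.v)), pointing)
    retained, excl = validate_trial_markers(events, moves)
    cc = {int(r["trial_index"]): float(r["onset"])
          for _, r in pointing.color_changes().iterrows()}
    for m in moves:
        if m.trial_index in cc:
            rt_rows.append({"participant": sid, "condition": "pointing",
                            "rt": m.onset - cc[m.trial_index]})
    df = events.df
    resp = df[(df["kind"] == "response") & (df["condition"] == "button")]
    ccb = df[df["kind"].isin(("standard", "distractor", "target"))] \
        .set_index("trial_index")["onset"]
    for _, r in resp.iterrows():
        rt_rows.append({"participant": sid, "condition": "button",
                        "rt": float(r["onset"]) - float(ccb[r["trial_index"]])})
    sw = sweep_onset_threshold(prof, moves, pointing)
    sweep_rows.append(sw.assign(participant=sid))
    print(f"{sid}: {len(moves)} movements, "
          f"{len(excl['excluded_trials'])} trials excluded "
          f"({excl['exclusion_fraction_by_stimulus']})")

rt = pd.DataFrame(rt_rows)
rt.to_csv(out / "rt_table.csv", index=False)
pd.concat(sweep_rows).to_csv(out / "rt_sweep.csv", index=False)

means = rt.groupby(["participant", "condition"], as_index=False)["rt"].mean()
stats = response_time_stats(means)
for cond, g in means.groupby("condition"):
    print(f"mean RT {cond}: {g['rt'].mean() * 1e3:.1f} ms")
print(f"one-way ANOVA: F = {stats['F']:.2f}, p = {stats['p']:.2g}")
with open(out / "rt_stats.json", "w") as f:
    json.dump({"F": stats["F"], "p": stats["p"],
               "hsd": stats["hsd"].to_dict(orient="records")}, f, indent=2,
              default=str)
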