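#!/usr/bin/env python
"""Build the fear-conditioning session timelines and their optogenetic windows.

Constructs the conditioning (day 1: 2-min baseline, five CS-US pairings),
retrieval (day 2: eight CS presentations, ITI 35-60 s) and reconditioning
(day 3, 3-kHz CS2) timelines, reports their structure, and writes the JSON
serializations plus the laser windows covering CS+US (conditioning) and CS
(retrieval) under results/protocol/.
"""

import json
from pathlib import Path

from fearpipe.protocol import ProtocolParams, build_timeline, laser_windows

OUT = Path(__file__).resolve().parents[1] / "results" / "protocol"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    params = ProtocolParams(rng_seed=0)
    summary = {}
    for session in ("fc_day1", "retrieval_day2", "fc_day3"):
        tl = build_timeline(session, params)
        tl.to_json(OUT / f"{session}.json")
        n_cs = len(tl.by_label("cs"))
        n_us = len(tl.by_label("us"))
        n_pips = len(tl.by_label("pip"))
        mode = "cs_us" if n_us else "cs"
        windows = laser_windows(tl, mode)
        summary[session] = {
            "n_cs": n_cs, "n_us": n_us, "pips_per_cs": n_pips // n_cs,
            "duration_s": round(tl.total_duration, 2),
            "laser_mode": mode, "n_laser_windows": len(windows),
        }
        (OUT / f"{session}_laser_windows.json").write_text(
            json.dumps([{"start": s, "end": e} for s, e in windows], indent=2))
        print(f"{session}: {n_cs} CS, {n_us} US, {n_pips // n_cs} pips/CS, "
              f"{tl.total_duration:.1f} s, {len(windows)} laser windows ({mode})")
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    print(f"\nwrote timelines and laser windows to {OUT}")


if __name__ == "__main__":
    main()
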