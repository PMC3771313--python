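#!/usr/bin/env python
"""Calibration sweep for the self-re-ignition (BFC) wiring constants.

The re-ignition chain's wiring numbers — relay fan-in per pool (k_g),
relay fan-out onto the BFC (k_b), the self-clamp group size and the BFC
drive scale — are not derivable from first principles.  This sweep
simulates the autonomous scribbler over a grid of candidate values and
scores each point on:

* switching reliability: fraction of activity lapses (a complete run
  ending with no successor hand-off) that are answered by a complete
  restart of the re-ignition target chain within 1 s (target >= 0.9), and
* spontaneous ignition: fraction of complete runs that start with no
  preceding activity on their predecessor chain, i.e. ignitions outside
  the hand-off and re-ignition windows (target < 0.01).  Predecessor
  activity is tracked with a sensitive volley detector (frac=0.25) so
  weakened but real traversals are not misread as spontaneous events.

Usage:
    python scripts/synfire_sweep.py --seed 0 --duration 10 \
        --k-b 400 700 1000 --bfc-drive 1.0 1.1 --out sweep.json
"""

from __future__ import annotations

import argparse
import itertools
import json
import time

import numpy as np

from scribblekit import synfire


def score_point(k_g: int, k_b: int, self_clamp: int, drive: float,
                duration: float, seed: int) -> dict:
    cfg = synfire.scribbler_config(
        bfc_width=100, bfc_length=10, stim_rate=0.0,
        k_g=k_g, k_b=k_b, bfc_self_clamp=self_clamp, bfc_drive=drive)
    net = synfire.build_network(cfg, seed=seed)
    raster = synfire.simulate(net, duration, seed=seed + 1, stimulate=False)
    runs = synfire.detect_chain_runs(raster, net)
    sensitive = synfire.detect_chain_runs(raster, net, frac=0.25)
    complete = sorted((r for r in runs if r["complete"]),
                      key=lambda r: r["pool_times"][0])
    succ = {i: ch.successors for i, ch in enumerate(cfg.chains)}

    # switching reliability: lapses answered by a chain-0 restart
    lapses = answered = 0
    for r in complete:
        t_end = r["pool_times"][-1]
        follow = [s for s in complete
                  if 0 < s["pool_times"][0] - t_end < 0.05
                  and s["chain"] in succ[r["chain"]]]
        if follow:
            continue
        lapses += 1
        if any(s["chain"] == 0 and 0 < s["pool_times"][0] - t_end < 1.0
               for s in complete):
            answered += 1

    # spontaneous: complete non-restart runs with a silent predecessor
    spontaneous = 0
    for r in complete:
        t0, ch = r["pool_times"][0], r["chain"]
        if ch == 0:
            continue  # chain 0 is the re-ignition target
        pred = [p for p in sensitive if ch in succ[p["chain"]]
                and 0 <= t0 - p["pool_times"][-1] < 0.15]
        if not pred:
            spontaneous += 1

    return {
        "k_g": k_g, "k_b": k_b, "self_clamp": self_clamp, "drive": drive,
        "n_runs": len(runs), "n_complete": len(complete),
        "n_lapses": lapses,
        "switch_reliability": answered / max(lapses, 1),
        "spontaneous_rate": spontaneous / max(len(complete), 1),
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--duration", type=float, default=10.0)
    ap.add_argument("--k-g", type=int, nargs="+", default=[6])
    ap.add_argument("--k-b", type=int, nargs="+", default=[400, 700, 1000])
    ap.add_argument("--self-clamp", type=int, nargs="+", default=[20])
    ap.add_argument("--bfc-drive", type=float, nargs="+", default=[1.0, 1.1])
    ap.add_argument("--out", type=str, default="sweep.json")
    args = ap.parse_args()

    results = []
    for k_g, k_b, sc, drv in itertools.product(
            args.k_g, args.k_b, args.self_clamp, args.bfc_drive):
        t0 = time.time()
        res = score_point(k_g, k_b, sc, drv, args.duration, args.seed)
        res["wall_seconds"] = round(time.time() - t0, 1)
        results.append(res)
        print(f"k_g={k_g} k_b={k_b} clamp={sc} drive={drv}: "
              f"switch={res['switch_reliability']:.2f} "
              f"spont={res['spontaneous_rate']:.3f} "
              f"complete={res['n_complete']}")

    ok = [r for r in results
          if r["switch_reliability"] >= 0.9 and r["spontaneous_rate"] < 0.01]
    with open(args.out, "w") as f:
        json.dump({"results": results,
                   "passing": ok,
                   "criteria": {"switch_reliability": ">= 0.9",
                                "spontaneous_rate": "< 0.01"}}, f, indent=2)
        f.write("\n")
    print(f"{len(ok)}/{len(results)} grid points meet both targets; "
          f"wrote {args.out}")


if __name__ == "__main__":
    main()
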