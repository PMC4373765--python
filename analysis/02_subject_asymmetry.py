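#!/usr/bin/env python
"""Single-subject compartment analysis on a noise-free phantom.

Runs the full chain (classify -> split -> 50-node weighted-core profiles ->
asymmetry -> lesion extent) on one phantom with a partial lesion elevating
RD by 30% inside the lesion and AD by 10% along transected fibers distal to
it, then reports how well the asymmetry profiles recover those numbers.
Writes the profile table and a recovery summary under results/.
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tractcompart import phantom, pipeline
from tractcompart.profile import valid_node_mask


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default="results/subject")
    args = ap.parse_args()

    cfg = phantom.PhantomConfig(seed=args.seed, noise_sigma=0.0)
    sub = phantom.generate_subject(cfg, subject_id=f"phantom-{args.seed}")
    report = pipeline.run_subject(sub.bundle, sub.ad, sub.rd, sub.lesion_mask,
                                  subject_id=sub.subject_id, out_dir=args.out)

    df = report["profiles"]
    valid = valid_node_mask()
    a, b = sub.truth.lesion_extents[0]
    deltas = {}
    for metric in ("RD", "AD"):
        sel = df[(df["compartment"] == "delta") & (df["metric"] == metric)]
        deltas[metric] = sel.sort_values("node")["value"].to_numpy()
    in_lesion = np.zeros(50, dtype=bool)
    in_lesion[a - 1:b] = True
    distal = valid & (np.arange(1, 51) >= b + 3)

    summary = {
        "category": report["category"],
        "n_lesional": report["n_lesional"],
        "n_non_lesional": report["n_non_lesional"],
        "injected_lesion_nodes": [a, b],
        "measured_extent": [[e.start, e.end] for e in report["extents"]],
        "delta_rd_peak": float(np.nanmax(deltas["RD"][in_lesion & valid])),
        "delta_rd_max_outside": float(
            np.nanmax(np.abs(deltas["RD"][valid & ~in_lesion]))),
        "delta_ad_max_proximal": float(
            np.nanmax(np.abs(deltas["AD"][valid & (np.arange(1, 51) < a)]))),
        "delta_ad_min_distal": float(np.nanmin(deltas["AD"][distal])),
    }
    out = Path(args.out)
    with open(out / "recovery_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    print(f"{sub.subject_id}: {report['n_lesional']} lesional / "
          f"{report['n_non_lesional']} non-lesional fibers, "
          f"lesion nodes {a}-{b}")
    print(f"  peak dRD in lesion   {summary['delta_rd_peak']:.3f} "
          f"(injected 0.30)")
    print(f"  |dRD| outside lesion {summary['delta_rd_max_outside']:.4f}")
    print(f"  |dAD| proximal       {summary['delta_ad_max_proximal']:.4f}")
    print(f"  dAD >= 3 nodes distal {summary['delta_ad_min_distal']:.3f} "
          f"(injected 0.10)")


if __name__ == "__main__":
    main()
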