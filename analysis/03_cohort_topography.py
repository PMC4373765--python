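#!/usr/bin/env python
"""Cohort topography: lesion frequency vs RD asymmetry, WD load vs AD.

Regenerates the 20-subject phantom cohort (lesion centers concentrated in
the third quarter of the tract, 5% noise), runs the subject pipeline on
each, and aggregates: lesion-frequency histogram, cumulative
Wallerian-degeneration load, mean asymmetry profiles, and the topographic
correlations between them. Tables land under results/.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tractcompart import phantom, pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--n-subjects", type=int, default=20)
    ap.add_argument("--out", default="results/cohort")
    args = ap.parse_args()

    subjects = phantom.generate_cohort(args.n_subjects, seed=args.seed)
    reports = [pipeline.run_subject(s.bundle, s.ad, s.rd, s.lesion_mask,
                                    subject_id=s.subject_id)
               for s in subjects]
    res = pipeline.run_cohort(reports, out_dir=args.out)

    freq = res["lesion_frequency"].counts
    print(f"{args.n_subjects} subjects, "
          f"{sum(len(r['extents']) for r in reports)} lesions on the "
          f"node template; frequency mode at node {freq.argmax() + 1}")
    for name, corr in res["correlations"].items():
        print(f"  {name}: r2 = {corr['r2']:.3f} (p = {corr['p']:.2g}, "
              f"n = {corr['n']} nodes)")


if __name__ == "__main__":
    main()
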