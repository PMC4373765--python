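#!/usr/bin/env python
"""Generate the phantom cohort used by the downstream analyses.

Writes 20 synthetic subjects (TRK bundle, AD/RD maps, lesion mask,
ground-truth JSON) plus a manifest to a data directory. Volumes are binary
imaging files, so they go under scratch/ by default; the downstream
analyses can also regenerate subjects in memory from the same seed.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tractcompart import phantom


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--n-subjects", type=int, default=20)
    ap.add_argument("--out", default="scratch/cohort_data")
    args = ap.parse_args()

    subjects = phantom.generate_cohort(args.n_subjects, seed=args.seed)
    out = Path(args.out)
    manifest = [phantom.write_subject(s, out) for s in subjects]
    with open(out / "manifest.json", "w") as fh:
        json.dump({"seed": args.seed, "subjects": manifest}, fh, indent=1)

    n_lesional = [int(s.truth.lesional.sum()) for s in subjects]
    extents = [s.truth.lesion_extents for s in subjects]
    print(f"wrote {len(subjects)} subjects to {out}")
    print(f"lesional fibers per subject (of {subjects[0].config.n_fibers}): "
          f"{n_lesional}")
    print(f"lesion node extents: {extents}")


if __name__ == "__main__":
    main()
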