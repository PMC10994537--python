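#!/usr/bin/env python
"""Simulate the study cohort: 24 controls, 6 anoxic and 11 traumatic coma
patients, with implanted anoxic (mesocircuit/posteromedial) and traumatic
(mPFC) binding elevations and CRS-R outcomes tied to pallidal/putaminal/PCC
binding.

Writes subjects.tsv and ground_truth.tsv under results/, and (with
--write-images) the dynamic NIfTI phantoms + schedule sidecars under
scratch/cohort/.
"""

import argparse
from pathlib import Path

from tspopet import simulate_cohort, write_dynamic
from tspopet.core import write_label_map

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--write-images", action="store_true")
    args = ap.parse_args()

    cohort = simulate_cohort(seed=args.seed)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    cohort.subjects_table().to_csv(results / "subjects.tsv", sep="\t", index=False)
    cohort.ground_truth().to_csv(results / "ground_truth.tsv", sep="\t", index=False)

    groups = [s.record.group for s in cohort.subjects]
    print(
        f"simulated {len(groups)} subjects: "
        f"{groups.count('control')} controls, {groups.count('anoxic')} anoxic, "
        f"{groups.count('traumatic')} traumatic (seed {args.seed})"
    )
    pats = cohort.subjects_table().query("group != 'control'")
    print(
        f"patient CRS-R range {pats.crs_r.min()}-{pats.crs_r.max()}; "
        f"{(pats.outcome == 'unfavourable').sum()} unfavourable outcomes"
    )

    if args.write_images:
        out = ROOT / "scratch" / "cohort"
        out.mkdir(parents=True, exist_ok=True)
        write_label_map(cohort.label_map, out / "labels.nii.gz")
        for s in cohort.subjects:
            write_dynamic(s.image, out / f"{s.record.id}.nii.gz")
        print(f"wrote {len(cohort.subjects)} dynamic images to {out}")


if __name__ == "__main__":
    main()
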