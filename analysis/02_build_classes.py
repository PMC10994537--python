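#!/usr/bin/env python
"""Build the SVCA kinetic class sets (blood / specific GM / non-specific GM /
white matter) from the control subjects, separately for high- and
mixed-affinity binders, and write them to results/classes_{HAB,MAB}.json.
"""

import argparse
import json
from pathlib import Path

from tspopet import simulate_cohort
from tspopet.pipeline import build_affinity_class_sets

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    args = ap.parse_args()

    cohort = simulate_cohort(seed=args.seed)
    controls = [
        (s.record, s.image) for s in cohort.subjects if s.record.group == "control"
    ]
    class_sets = build_affinity_class_sets(controls, cohort.label_map)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for affinity, cs in class_sets.items():
        path = results / f"classes_{affinity}.json"
        path.write_text(json.dumps(cs.to_dict(), indent=2))
        print(
            f"{affinity}: class set from {cs.n_controls_used} controls "
            f"-> {path.name}"
        )


if __name__ == "__main__":
    main()
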