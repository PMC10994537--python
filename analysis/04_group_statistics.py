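#!/usr/bin/env python
"""Group statistics on the quantified binding-potential maps and VOI table:
voxel-wise anoxic-vs-control and traumatic-vs-control t maps with BH FDR and
effect-size classes, the group x VOI ANOVA with genotype covariate, Tukey
post hocs per VOI, CRS-R Spearman correlations, and the cohort descriptive
battery. Writes results/group_stats.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from tspopet import (
    descriptive_tests,
    groupwise_tukey_by_voi,
    spearman,
    two_way_anova,
    voxelwise_ttest,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    args = ap.parse_args()

    tab = pd.read_csv(ROOT / "results" / "voi_bp.tsv", sep="\t")
    maps_file = np.load(ROOT / "scratch" / "bp_maps.npz", allow_pickle=False)
    labels = maps_file["labels"]
    brain = labels != 0
    subjects = tab.drop_duplicates("id").set_index("id")
    report = {}

    # voxel-wise parametric mapping per patient group vs controls
    for group in ("anoxic", "traumatic"):
        a = [maps_file[f"bp_{sid}"] for sid in subjects.index
             if subjects.loc[sid, "group"] == group]
        b = [maps_file[f"bp_{sid}"] for sid in subjects.index
             if subjects.loc[sid, "group"] == "control"]
        res = voxelwise_ttest(a, b, brain)
        sig = res.q <= 0.05
        report[f"{group}_vs_control"] = {
            "n_significant_voxels": int(sig[brain].sum()),
            "n_brain_voxels": int(brain.sum()),
            "median_d_in_significant": (
                float(np.median(res.d[sig & brain])) if sig[brain].any() else None
            ),
        }

    aov = two_way_anova(tab)
    report["anova"] = aov.to_dict(orient="records")
    tukey = groupwise_tukey_by_voi(tab)
    sig_pairs = tukey[tukey.p_adj < 0.05]
    report["tukey_significant_pairs"] = sig_pairs[
        ["voi", "level_1", "level_2", "mean_diff", "p_adj"]
    ].to_dict(orient="records")

    pats = tab[tab.group != "control"]
    corr = {}
    for voi in ("globus_pallidus", "putamen", "pcc", "precentral"):
        sub = pats[pats.voi == voi]
        rho, p = spearman(sub.bp.to_numpy(), sub.crs_r.to_numpy(float))
        corr[voi] = {"rho": rho, "p": p, "n": len(sub)}
    report["crsr_spearman"] = corr

    desc = descriptive_tests(
        subjects.reset_index(), numeric_cols=["crs_r"],
        categorical_cols=["genotype"],
    )
    report["descriptives"] = desc.to_dict(orient="records")

    out = ROOT / "results" / "group_stats.json"
    out.write_text(json.dumps(report, indent=2))

    print("voxel-wise q<=0.05 discoveries:",
          {k: v["n_significant_voxels"] for k, v in report.items()
           if k.endswith("_vs_control")})
    main_effects = {r["factor"]: r["p"] for r in report["anova"]}
    print("ANOVA p-values:", {k: f"{v:.3g}" for k, v in main_effects.items()})
    print(f"{len(sig_pairs)} significant Tukey pairs across VOIs")
    for voi, c in corr.items():
        print(f"CRS-R vs {voi}: rho={c['rho']:+.2f} p={c['p']:.3g}")


if __name__ == "__main__":
    main()
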