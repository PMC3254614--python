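"""Main-tumor arm: black pixel counts for labeled macrophages vs free agent.

Simulates two arms of six tumors each — one receiving iron-labeled
macrophages (designed hypointensity ~12% of tumor voxels), one receiving the
free agent solution (~2%, cleared without cell-mediated delivery) — runs the
pre/post black-pixel pipeline on every tumor, and compares the arms.
Writes results/tumor_cohort.csv and results/tumor_stats.json.
"""

import argparse
import json
from pathlib import Path

from fionmri.pipeline import compare_cohort, comparison_to_dict, quantify_cohort
from fionmri.synthetic import TUMOR_GROUPS, simulate_ln_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_ln_cohort(groups=TUMOR_GROUPS, seed=args.seed)
    table = quantify_cohort(cohort, classify=False)
    table.to_csv(args.out / "tumor_cohort.csv", index=False)

    summary = table.groupby("group")[["designed_fraction_pct", "black_pixel_pct"]].agg(
        ["mean", "std"]
    )
    print(summary.round(3).to_string())

    cmp = compare_cohort(table)
    (args.out / "tumor_stats.json").write_text(
        json.dumps(comparison_to_dict(cmp), indent=2)
    )
    print(
        f"\n{cmp.labels[0]} vs {cmp.labels[1]}: "
        f"{cmp.means[0]:.2f}% vs {cmp.means[1]:.2f}% black pixels, "
        f"{cmp.method} p = {cmp.p_value:.4g}."
    )
    print(
        "Cell-mediated delivery concentrates the agent in the tumor; the "
        "free solution arm stays near the baseline false-positive rate."
    )


if __name__ == "__main__":
    main()
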