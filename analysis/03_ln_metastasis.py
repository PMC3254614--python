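"""Lymph-node arm: group differences and the 20% metastasis rule.

Simulates 12 brachial, 12 axillary (both metastatic, heavy macrophage
recruitment) and 12 inguinal (non-metastatic) lymph nodes, quantifies each
node's black pixel count, tests the three-group difference with one-way
ANOVA + Tukey-Kramer, and evaluates the over-20%-black-pixels metastasis
call. Writes results/ln_cohort.csv, results/ln_stats.json and
results/ln_calls.csv.
"""

import argparse
import json
from pathlib import Path

from fionmri.group_stats import anova_tukey
from fionmri.pipeline import comparison_to_dict, quantify_cohort
from fionmri.synthetic import GroupSpec, simulate_ln_cohort

LN_GROUPS_FULL = (
    GroupSpec("brachial", 12, 0.45064, 0.11932),
    GroupSpec("axillary", 12, 0.34242, 0.11456),
    GroupSpec("inguinal", 12, 0.08413, 0.05449),
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_ln_cohort(groups=LN_GROUPS_FULL, seed=args.seed)
    table = quantify_cohort(cohort, classify=True)
    table.to_csv(args.out / "ln_cohort.csv", index=False)

    by_group = table.groupby("group")["black_pixel_pct"]
    print(by_group.agg(["mean", "std", "count"]).round(3).to_string())

    labels = [g.name for g in LN_GROUPS_FULL]
    cmp = anova_tukey([by_group.get_group(l).to_numpy() for l in labels], labels)
    (args.out / "ln_stats.json").write_text(
        json.dumps(comparison_to_dict(cmp), indent=2)
    )
    print(f"\nOne-way ANOVA: F = {cmp.statistic:.2f}, p = {cmp.p_value:.3g}")
    print(cmp.pairwise.round(4).to_string(index=False))

    calls = table[["subject", "group", "black_pixel_pct", "call"]]
    calls.to_csv(args.out / "ln_calls.csv", index=False)
    metastatic = table["group"].isin(["brachial", "axillary"])
    called = table["call"] == "metastatic"
    sens = 100.0 * (metastatic & called).sum() / metastatic.sum()
    spec = 100.0 * (~metastatic & ~called).sum() / (~metastatic).sum()
    print(
        f"\n20%-rule calls: sensitivity {sens:.1f}% over {metastatic.sum()} "
        f"metastatic nodes, specificity {spec:.1f}% over "
        f"{(~metastatic).sum()} non-metastatic nodes."
    )
    print(
        "Misses come from axillary nodes whose drawn hypointense fraction "
        "falls below 20%; the designed group spreads overlap the rule "
        "threshold, so perfect separation is not expected on every draw."
    )


if __name__ == "__main__":
    main()
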