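"""Phantom relaxometry: per-tube T2* and the relaxivity regression.

Simulates the four-echo agar-tube phantom of iron-labeled cell pellets
(noiseless and at SNR 50), fits voxel-wise T2* maps, summarizes each tube,
and regresses R2* on molar iron concentration to recover the agent's
relaxivity. Writes results/phantom_t2star.csv and results/relaxivity.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from fionmri.relaxometry import fit_relaxivity, fit_t2star_map, roi_mean_t2star
from fionmri.synthetic import PhantomSpec, simulate_phantom

ACQ_TES = [4.9, 13.6, 22.3, 57.0]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    relaxivity_points = []
    for label, sigma, method in [("noiseless", 0.0, "loglinear"),
                                 ("snr50", 20.0, "nls")]:
        spec = PhantomSpec(noise_sigma=sigma, seed=args.seed)
        series, rois, truth = simulate_phantom(spec, ACQ_TES)
        t2map = fit_t2star_map(series, method=method)
        for tube in spec.tubes:
            s = roi_mean_t2star(t2map, rois[tube.label])
            true_t2 = float(truth.t2star_ms[rois[tube.label]].mean())
            if label == "noiseless":
                relaxivity_points.append((tube.iron_concentration, s.mean))
            rows.append({
                "condition": label,
                "tube": tube.label,
                "iron_ug_per_ml": tube.iron_concentration,
                "true_t2star_ms": round(true_t2, 3),
                "fitted_t2star_ms": round(s.mean, 3),
                "sd_ms": round(s.sd, 3),
                "n_voxels": s.n,
            })
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "phantom_t2star.csv", index=False)
    print(table.to_string(index=False))

    # relaxivity from the (unrounded) noiseless tube means
    fit = fit_relaxivity(relaxivity_points)
    payload = {
        "r2star_mM_s": round(fit.r2star, 3),
        "intercept_s": round(fit.intercept, 4),
        "r_squared": round(fit.r_squared, 6),
    }
    (args.out / "relaxivity.json").write_text(json.dumps(payload, indent=2))
    print(
        f"\nRelaxivity regression over {len(relaxivity_points)} tubes: "
        f"r2* = {fit.r2star:.1f} mM^-1 s^-1 "
        f"(baseline R2* = {fit.intercept:.1f} s^-1, R^2 = {fit.r_squared:.4f})."
    )
    print(
        "The unlabeled tube sits at the intrinsic 100 ms; tubes above "
        "~25 ug Fe/mL decay faster than the shortest echo can sample, "
        "which is why the in-vitro series saturates at high loading."
    )


if __name__ == "__main__":
    main()
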