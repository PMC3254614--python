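# fionmri

MR quantification of iron-oxide-labeled macrophages for cell-tracking
studies: voxel-wise **T2\*/R2\* relaxometry** of labeled-cell phantoms,
**relaxivity** estimation, and the muscle-normalized **black pixel count**
— a hypointensity-burden statistic for tumors and lymph nodes on
gradient-echo MRI — with the over-20% metastasis rule for lymph nodes.

Macrophages loaded with ferromagnetic iron-oxide nanocubes (FIONs) darken
the tissue they home to on T2\*-weighted images. This package implements the
quantification side of that experiment for radiology/imaging researchers:

* **Relaxometry** — per voxel, `SI(TE) = SI0·exp(−TE/T2*)` is fitted across
  multi-echo magnitude volumes (log-linear OLS by default, a nonlinear
  magnitude fit for low SNR); relaxivity r2\* is the OLS slope of
  R2\* = 1000/T2\* (s⁻¹) against molar iron concentration (mM).
* **Black pixel count** — lesion voxels are normalized to the mean signal of
  a muscle ROI of the same scan (nSI (%) = 100·SI/SI_muscle), the
  pre-injection lesion minimum nSI defines a baseline threshold, and the
  black pixel count is the percentage of post-injection lesion voxels
  strictly below it. A lymph node with over 20% black pixels is called
  metastatic.
* **Synthetic data** — phantoms (four echoes, TE = 4.9/13.6/22.3/57 ms,
  tubes at 0–100 µg Fe/mL, r2\* = 324 mM⁻¹s⁻¹) and single-echo lesion/muscle
  scenes with a designed hypointense voxel fraction and Rician noise, each
  with exact ground truth, so every stage is testable without any download.
* **Group statistics** — t / Mann-Whitney two-group tests and one-way ANOVA
  with Tukey-Kramer post-hoc contrasts over cohort tables.

See `docs/methods.md` for the model, assumptions and limitations.

## Worked example

Simulate a lymph-node cohort, quantify every node, and test the groups:

```python
from fionmri import simulate_ln_cohort, quantify_cohort, compare_cohort

cohort = simulate_ln_cohort(seed=1)            # 3 arms × 6 nodes, pre+post
table = quantify_cohort(cohort)                # black pixel count per node
print(table.groupby("group")[["designed_fraction_pct", "black_pixel_pct"]].mean())
cmp = compare_cohort(table)                    # ANOVA + Tukey-Kramer
print(cmp.pairwise)
```

```
          designed_fraction_pct  black_pixel_pct
group
axillary              30.050094        30.368906
brachial              43.231034        43.544137
inguinal               7.979914         8.432148
     group1    group2  meandiff   p-adj    lower    upper  reject
0  axillary  brachial   13.1752  0.0401   0.5612  25.7893    True
1  axillary  inguinal  -21.9368  0.0011 -34.5508  -9.3227    True
2  brachial  inguinal  -35.1120  0.0000 -47.7260 -22.4979    True
```

The recovered black pixel counts track each node's designed hypointense
fraction to within half a point, and the metastatic arms separate from the
inguinal controls decisively.

The numbered drivers under `analysis/` run the full study workflow and
write tables under `results/`:

```bash
python analysis/01_phantom_relaxometry.py --seed 1   # T2* per tube + r2* fit
python analysis/02_tumor_blackpixel.py   --seed 1   # two tumor arms + t test
python analysis/03_ln_metastasis.py      --seed 1   # 3 LN arms + 20% rule
```

`01` recovers the designed relaxivity exactly on noiseless data
(`r2* = 324.0 mM^-1 s^-1, R^2 = 1.0000`) and shows which tubes remain
measurable at SNR 50; `03` prints the ANOVA (`F = 35.54, p = 5.87e-09` at
seed 1), the Tukey table, and the 20%-rule sensitivity/specificity.

There is also a CLI for file-based workflows (NIfTI-1 volumes, masks with
values {0,1}, YAML configs; echo times in a JSON sidecar):

```bash
fionmri simulate phantom --config configs/phantom.yaml --seed 1 --out sim/
fionmri t2map --echoes sim/phantom_00.nii ... --te 4.9 --te 13.6 --te 22.3 --te 57 --out map/
fionmri blackpixel --pre pre.nii --post post.nii --lesion-pre lp.nii \
    --lesion-post lpp.nii --muscle-pre mp.nii --muscle-post mpp.nii \
    --classify-ln --out out/
fionmri pipeline --config configs/demo_cohort.yaml --seed 7 --out run/
```

Every run writes a `provenance.json` (config + seed + version) next to its
results and is bit-reproducible from it.

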