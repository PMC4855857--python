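# ewa-lge — automatic infarct quantification in LGE cardiac MR

Quantifying myocardial infarction (MI) on late-gadolinium-enhancement (LGE)
cardiovascular MR is routine clinically but has no standard method: simple
n-SD-from-remote or FWHM thresholds give widely varying sizes, differ
between magnitude-IR and PSIR reconstructions, and ignore partial-volume
voxels at the infarct border. This package implements a fully automatic
pipeline for IR, PSIR and high-resolution T1-weighted short-axis stacks,
aimed at imaging scientists and method developers who need a reproducible,
scriptable infarct-size measurement plus the classical comparator
thresholds and agreement statistics — all exercised on synthetic phantoms
with voxel-level ground truth, so no clinical data is required to develop
against it.

## The method

Given a stack `I`, endo/epicardial contours, the culprit coronary artery
and the two RV insertion points, the pipeline runs six steps:

1. **Surface-coil intensity correction** — a second-order polynomial
   surface (terms `1, x, y, x², xy, y²`) is fitted per slice to
   class-normalized blood-pool and remote-myocardium intensities
   (reliability-weighted least squares) and divided out. Remote myocardium
   is defined a priori as the sectors outside the culprit artery's maximal
   perfusion territory on an extended bulls-eye (9 rings × 24 sectors,
   oriented by the RV insertion points).
2. **EM classification** — a constrained two-Gaussian mixture (normal
   myocardium vs MI) is fitted to myocardial intensities by
   Expectation-Maximization. Initialization labels the top 10% of the
   histogram MI; each E-step clamps intensities below the 5th percentile to
   normal and above the 95th to MI. The optimal threshold `t*` solves
   `π_n N(t; μ_n, σ_n) = π_i N(t; μ_i, σ_i)`.
3. **Level-set segmentation** — the core grows from the seed set
   `{I > t*}` under the speed `S = (I − t*)/(I_max − t*)` with a curvature
   penalty (`S − α·κ`), smoothing ragged borders; `α = 0` reproduces plain
   thresholding exactly.
4. **Microvascular obstruction (MVO)** — hypointense regions enclosed by
   infarct, or sealed between infarct and the endocardial border, are
   recovered slice-by-slice by flood fill plus a 3×3-cross morphological
   closing, and counted as 100% infarct.
5. **Post-processing** — infarct voxels outside the culprit territory are
   removed; isolated regions smaller than 1.5 cm³ and ≤ 1 %LVM are dropped
   unless they are the only region.
6. **Weighted summation** — each infarct voxel gets a partial-volume weight
   `w = clamp((I − μ_remote) / (P90_MI − μ_remote), 0, 1)` (MVO voxels
   `w = 1`), and infarct size is `100 · Σw · v_voxel / V_myocardium` in
   percent of LV mass (%LVM).

Comparators (`2sd`/`3sd`/`5sd` from remote, FWHM from minimum or from
remote mean, Otsu, plain EM cut), Dice overlap, Bland–Altman bias and
Pearson R are included for benchmarking.

## Worked example

```sh
python examples/quantify_phantom.py
```

```
true infarct size :  25.45 %LVM
weighted estimate :  21.80 %LVM
binary core + MVO :  25.39 %LVM
EM threshold t*   :  47.16
MVO volume        :   0.00 mL
```

The phantom is a 9-slice magnitude-IR stack with a 90° transmural septal
wedge (a quarter of the annulus, hence ~25 %LVM), blurred borders, a coil
gradient and noise at contrast-to-noise 10. The weighted estimate
down-weights border voxels by their intensity and therefore reads lower
than the binary voxel count at this noise level (see
`docs/methods.md` for the bias analysis); the EM threshold sits between
the fitted normal (~12) and infarct (~95) component means.

The same pipeline is available from the shell:

```sh
ewa phantom --seed 1 --out ph/
ewa run ph/image.nii.gz ph/contours.json --culprit LAD \
    --anterior 24.2 24.2 --inferior 24.2 70.8 --out result
ewa compare ph/image.nii.gz ph/contours.json --culprit LAD \
    --anterior 24.2 24.2 --inferior 24.2 70.8 --out compare.csv
```

`ewa run` writes a NIfTI label map (1 = core, 2 = MVO) and a JSON report
with the weighted and binary sizes, threshold and EM parameters.

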