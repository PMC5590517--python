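# cordisp

**Validating MRI-derived neurite orientation dispersion against histology,
on a synthetic spinal-cord phantom.**

Neurites — axons and dendrites — vary in how strongly their orientations
disperse around a dominant axis, and that variability changes with
pathology: demyelinated multiple-sclerosis lesions show *reduced*
orientation dispersion, and gray matter disperses more than white.
Diffusion MRI can estimate this microstructural property in vivo through
the dispersed-stick (NODDI) model, but the estimate needs histological
validation: does the MRI orientation dispersion index (ODI) track the
dispersion actually measured in stained sections?

`cordisp` implements that validation study as a reusable pipeline for
quantitative-MRI and microscopy researchers:

* **Diffusion modelling** — the ex-vivo Watson-dispersed stick model with
  free-water, isotropically-restricted ("dot"), intra- and extra-neurite
  compartments, fitted voxel-by-voxel on a six-shell protocol
  (b up to 18,720 s/mm², 196 measurements), plus standard DTI
  (FA/AD/RD/MD) in the Gaussian regime b ≤ 4680 s/mm²:

      S(b,g) = s0 [ v_iso e^(−b·d_iso)
                    + (1−v_iso)( v_ir + (1−v_ir)( v_in·A_in + (1−v_in)·A_en ) ) ]

  with `A_in` the Watson-averaged stick signal, `A_en` the
  tortuosity-coupled extra-neurite tensor averaged under the same Watson
  distribution, and `ODI = (2/π)·arctan(1/κ)`.
* **Histology quantification** — k-means segmentation of neurites and
  immunostains, structure-tensor orientation estimation, and patch-wise
  (0.16 × 0.20 mm², the MRI in-plane resolution) circular variance
  `CV = 1 − |Σ w·e^(2iθ)| / Σ w` and staining fractions
  (MSF/NSF/ASF/µGSF for myelin, neurofilaments, astrocytes, microglia).
* **Co-registration** — landmark-guided thin-plate-spline warping of
  histology patch maps onto the MRI slice, quality-controlled by the Dice
  overlap of tissue outlines.
* **Statistics** — ROI-median extraction (two histology sections per MRI
  slice, averaged), within-group Pearson correlations, and five
  standardized multivariable regression models
  `m = β₀ + β₁CV + β₂MSF + β₃NSF + β₄ASF + β₅µGSF` (and nested subsets)
  for each MRI metric m.
* **Synthetic phantom** — a sagittal cord slab (gray/white matter, focal
  lesions) with known per-ROI ground truth driving all three data streams:
  Rician-noisy multi-shell DWI, silver-staining-like fiber images with
  Watson-distributed stroke orientations, and immunostain-like images with
  calibrated stained-area fractions.  48 ROIs (20 control, 28 MS) feed the
  statistics, mirroring the scale of the original post-mortem study.

Since no real specimen data are distributed, the phantom defines the study
conditions; see `docs/methods.md` for the model details, parameter choices
and what the synthetic data do and do not emulate.

## Worked example

Run the full phantom study (about 7 minutes on one CPU):

```python
from cordisp import RunConfig, run_full_analysis

report = run_full_analysis(RunConfig(seed=1), "demo_run")
print(report["pearson_ODI_CV"])
print(report["lesion_contrasts"])
```

which prints (numbers from this exact invocation):

```
{'pearson_r_ODI_CV_control': 0.995800647167083, 'pearson_p_ODI_CV_control': 3.798525055803501e-20,
 'pearson_r_ODI_CV_MS': 0.9789540783989978, 'pearson_p_ODI_CV_MS': 1.7934618752092686e-19}
{'ODI_WM_nonlesional': 0.09800200541925223, 'ODI_WM_lesional': 0.06680625476350385,
 'CV_WM_nonlesional': 0.0658081137801998, 'CV_WM_lesional': 0.05772026946418686,
 'ODI_GM_nonlesional': 0.44645526016834536, 'ODI_GM_lesional': 0.3027306854662811,
 'CV_GM_nonlesional': 0.4148790712178429, 'CV_GM_lesional': 0.3785826070055357}
```

Reading the output: the fitted MRI dispersion (ODI) and its histological
counterpart (CV) correlate strongly across ROIs within each group (r ≈ 1.00
control / 0.98 MS, p ≪ 0.05) — the phantom-scale analogue of the
MRI-histology dispersion agreement the pipeline is designed to test — and
both indices are lower in lesional than in matched nonlesional tissue
(e.g. white-matter ODI 0.067 vs 0.098), the expected signature of reduced
neurite architectural complexity in demyelinated lesions.  `demo_run/`
contains the metric table, the Pearson and regression CSVs, all parameter
maps as NIfTI, the simulated DWI with FSL-style `bval`/`bvec` files, and a
`report.json` whose bytes are identical across reruns with the same seed.

The same stages are scriptable from the shell:

    cordisp simulate --kind ms --seed 0 --out phantom/
    cordisp fit-noddi --dwi phantom/dwi --d-iso 2.0 --out noddi/
    cordisp fit-dti --dwi phantom/dwi --b-max 4680 --out dti/
    cordisp quant-histo --image phantom/palmgren.tif --stain palmgren
    cordisp run-all --seed 1 --out demo_run

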