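# endoquant

Quantitative analysis of the weak protein–protein interactions that couple
activated arrestin2 to the clathrin-mediated endocytosis machinery, and of
the cellular readouts of receptor internalization. The package provides a
tested, reusable implementation of the full analysis chain used in studies
of GPCR (e.g. CCR5) endocytosis:

- **equilibrium** — exact 1:1 mass-action binding under ligand depletion,
  nonlinear K_D fitting of NMR titrations, and a coupled
  activation → adaptor-binding model;
- **nmr_mapping** — per-residue intensity-attenuation (I/I₀) and combined
  ¹H/¹³C chemical-shift-perturbation profiles with one-standard-deviation
  significance rules and contiguous binding-region segmentation;
- **sec_quant** — SEC A280 window integration, Beer–Lambert complex
  quantification by apo-profile subtraction, and mass-balance apparent K_D;
- **proteolysis** — limited-proteolysis gel densitometry: relative
  abundance, interpolated digestion midpoints, protection factors;
- **coloc_imaging** — thresholded Mander's coefficients, puncta
  detection/classification (receptor-only vs receptor+arrestin), puncta
  densities per 100 µm², line profiles;
- **synthetic** — seeded generators that emulate each input with known
  ground truth, so every stage is testable without measurements;
- **io / cli** — CSV/TSV/TIFF/JSON formats and the `endoquant` command-line
  tool (`fit-kd`, `map-binding`, `sec-kd`, `proteolysis`, `coloc`,
  `simulate`).

## The core model

For a labelled protein P titrated with ligand L at comparable (tens of µM)
concentrations, the observed fast-exchange response is

```
Δδ = Δδ_max · ([L] + [P] + K_D − sqrt(([L] + [P] + K_D)² − 4[P][L])) / (2[P])
```

the exact quadratic solution of the 1:1 equilibrium in *total*
concentrations. `fit_kd` estimates (K_D, Δδ_max) by nonlinear least squares.
The same quadratic drives everything downstream: the fraction of arrestin
activated by a phosphopeptide, the apparent adaptor affinity
K_D,app = K_D,intrinsic / f_act under partial activation, and the
mass-balance inversion K_D = (A−c)(B−c)/c used for SEC-measured complex
concentrations.

## Worked example

Simulate a titration with a planted K_D of 104 µM (8 points, 0–600 µM
ligand, 50 µM protein, 0.002 ppm shift noise) and fit it:

```
$ endoquant simulate titration --seed 7 --out-dir demo
wrote demo/titration.csv (K_D truth 104.0 uM)
$ endoquant fit-kd --input demo/titration.csv --out-dir demo
K_D = 121 +/- 21 uM (converged=True) -> demo/fit_kd.json
```

The fitted 121 ± 21 µM covers the planted 104 µM within one standard
error — at 0.002 ppm noise on a 0.05 ppm maximum shift this scatter is
expected, and the reported standard error (from the linearized covariance
at the optimum) quantifies it honestly.

The SEC chain composes the coupled equilibrium with Beer–Lambert optics:

```
$ endoquant simulate sec --seed 7 --out-dir demo
wrote SEC set (complex truth 3.33 uM)
$ endoquant sec-kd --mixture demo/mixture.csv --apo-reference demo/apo_a.csv \
      --epsilon 20000 --a-total-um 10 --b-total-um 10 --out-dir demo
complex = 3.36 uM, apparent K_D = 13.1 uM -> demo/sec_kd.json
```

Here 10 µM arrestin + 10 µM adaptor with 100 µM phosphopeptide (activation
K_D 45 µM) activates 67% of the arrestin, so the intrinsic 9 µM adaptor
affinity appears as 9/0.675 ≈ 13.3 µM; the chromatogram round trip recovers
13.1 µM (≈2% integration error).

In Python, the activation arithmetic is one call:

```python
>>> from endoquant import fraction_bound
>>> fraction_bound(protein_total=50, ligand_total=250, kd=45)
0.82273906891607          # a 5-molar-equivalent peptide activates ~80%
```

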