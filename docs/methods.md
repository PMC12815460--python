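# Methods

This note documents the models implemented in `endoquant`, the defaults
and their rationale, what the synthetic generators do and do not emulate,
and the numerical and design choices made where the underlying experimental
conventions leave room.

## 1:1 binding under ligand depletion (`equilibrium`)

All binding math uses the exact mass-action solution in total
concentrations. For protein total [P], ligand total [L] and dissociation
constant K_D (all µM), the bound fraction of P is

    f = ([L] + [P] + K_D − sqrt(([L] + [P] + K_D)² − 4[P][L])) / (2[P])

The discriminant is mathematically ≥ (K_D + |[L] − [P]|)² > 0; it is
clipped at zero only to guard floating-point rounding, and the result is
clipped into [0, 1]. `fraction_bound` is validated in the test suite
against an independent `brentq` root of (P−c)(L−c) = K_D·c to |Δ| < 1e−9
over 1000 random triples in [0.1, 1000] µM.

**Fitting.** `fit_kd` minimizes unweighted squared residuals between
observed shift responses and Δδ_max·f over (K_D, Δδ_max) with
`scipy.optimize.least_squares` (trust-region reflective; K_D bounded
positive, Δδ_max free in sign; xtol/ftol/gtol 1e−14 so that noiseless
round trips recover parameters to ≤1e−6 relative). Initialization is
scale-aware and data-driven: K_D⁰ = median titrant concentration,
Δδ_max⁰ = 1.2 × the largest observed |response|. No per-point error model
is assumed (shift measurement uncertainties are rarely reported), so the
fit is unweighted. Standard errors are 1-σ values from the Gauss–Newton
covariance s²(JᵀJ)⁻¹ at the optimum; reported "±" values from comparable
experimental fits are treated as 1 SE. A series whose responses are all
equal carries no curvature and is rejected (`FitDegenerateError`) rather
than silently returning a boundary value. Responses are taken as
|δ_apo − δ_bound|; absolute values avoid sign ambiguity across reporters.

**Coupled activation → adaptor binding.** Adaptor recruitment requires
prior activation of arrestin by a receptor phosphopeptide (release of the
C-terminal β20 strand). The package models the two equilibria as
independent: with activated fraction f_act given by the quadratic above
(arrestin total, peptide total, activation K_D), the apparent adaptor
affinity is

    K_D,app = K_D,intrinsic / f_act

This is deliberately the simplest coupling: it is exact in the saturation
limit (f_act → 1) and diverges as peptide is withdrawn, but it ignores
thermodynamic linkage (adaptor binding pulling the activation equilibrium)
and any peptide-dependent conformational differences. Under partially
activating conditions it therefore predicts a smaller apparent-affinity
penalty (~2×) than is sometimes observed experimentally (~4–5×). The
model is exposed as an explicit modelling choice and is not calibrated to
reproduce any particular measured apparent affinity.

## Per-residue interface mapping (`nmr_mapping`)

Two observables localize a binding site on the labelled partner:

- **Intensity attenuation** I/I₀ (complexed over apo). Line broadening at
  an interface in intermediate exchange lowers the ratio. A residue is
  significant when its ratio is *strictly below* mean − 1 SD of all shared
  resonances.
- **Combined CSP** Δδ_HC = sqrt(Δδ_H² + (Δδ_X/3.6)²), with Δδ = apo −
  bound and the 3.6 weight scaling the ¹³C (or ¹⁵N) range onto ¹H.
  Significant when strictly above mean + 1 SD.

Choices the convention leaves open, fixed here: sample (n−1) standard
deviations; statistics computed over all resonances present in both lists
(excluded or missing keys never enter); strict inequalities, so a
zero-variance profile yields no significant residues. Residue numbering is
1-based construct numbering; no renumbering is attempted. Peak integration
is upstream of this package — intensities are consumed as given.

A caveat inherent to the one-SD rule: it is a relative threshold. It works
when the perturbed site is a minority of the observed resonances (the
regime of the profiles it was designed for, where interface residues are
~5–10% of assignments). If the site approaches half of the resonances,
the threshold itself is dragged down to the attenuated level and the rule
loses power. With many observed residues the rule also admits occasional
isolated false positives (the threshold sits only a few noise SDs below
the unperturbed ratios), which appear as single-residue regions alongside
the genuine interval; region reporting keeps them visible rather than
suppressing them.

`segment_regions` merges significant residues into maximal runs with gaps
≤ max_gap (default 0), reproducing the field's "374–381"-style reporting.

## SEC complex quantification (`sec_quant`)

The complex window integral of the mixture trace minus the same integral
of the apo reference isolates the absorbance newly brought into the window
by the partner joining the complex. Dividing by ε·path·V_inj
(Beer–Lambert) converts AU·ml to the complex concentration in the
injected sample:

    c = (I_mix − I_ref) / (ε · path · V_inj)

Defaults: window 2.4–2.8 ml around a 2.6 ml complex peak, 1 cm path,
0.25 ml injection (250 µl loop); all configurable. The subtraction is
exact when (i) the free and bound forms of the reference species
contribute equally inside the window across runs and (ii) the other free
species stays outside — the generator's default geometry satisfies both.
No baseline correction is applied by default (an optional linear baseline
can be configured); overlapping species are handled only through the
subtraction, not by peak deconvolution; the equilibrium is assumed frozen
during elution (no on-column dissociation correction); peptide absorbance
is neglected (no tryptophan). A negative excess is clamped to zero with a
warning rather than an error — it is the experimental signature of "no
detectable complex". Concentrations refer to the injected sample, not the
diluted on-column peak.

With measured complex c and known totals, mass balance for 1:1
stoichiometry gives the apparent K_D = (A−c)(B−c)/c, the exact inverse of
the forward quadratic solver (verified to 1e−9 relative in the tests).

## Proteolysis densitometry (`proteolysis`)

Relative abundance is the two-band normalization 100·top/(top+bottom),
invariant to uniform lane-intensity rescaling. The digestion midpoint is
the first 50% crossing, linearly interpolated between bracketing time
points — linear (not log-time) interpolation matches the coarse bracket
reporting ("20–30 min") these assays use; the bracketing interval is
recoverable from the time course itself. Curves that never reach 50% are
right-censored at the last time; curves starting at or below 50% are
flagged pre-digested. Protection factors are midpoint ratios; a censored
protected course yields a flagged lower bound.

## Colocalization imaging (`coloc_imaging`)

Thresholded Mander's coefficients per ROI:
M1 = Σ receptor intensity on arrestin-positive pixels over Σ receptor
intensity on receptor-positive pixels (M2 symmetrically). The numerator
mask is the partner channel's alone: intersecting it with the own-channel
mask biases the estimate low under noise, because threshold-boundary pixel
flips then only ever remove intensity. Values are clipped into [0, 1].

Puncta are 8-connected components above threshold with a minimum physical
area (pixel noise rejection); a receptor punctum is double-positive when
≥ 30% of its pixels exceed the arrestin threshold (default tolerant of
PSF-induced partial overlap; configurable). Where such counting is done
manually in practice, this package automates it with explicit
threshold/connectivity/min-area rules and records every parameter in its
output. Densities are centroid counts scaled to 100 µm². Auto-thresholds:
Otsu (default) or mean + k·SD (k = 2); both are global image statistics.
Line profiles use bilinear interpolation at evenly spaced points.

## Synthetic generators (`synthetic`)

Each generator is a pure function of its arguments including the seed
(one `numpy.random.default_rng` per call) and returns ground truth
sufficient to score the consuming stage. Default conditions mirror the
experimental designs the stages serve:

- **Titrations**: K_D 104 µM, Δδ_max 0.05 ppm, 50 µM protein, 8 ligand
  points 0–600 µM, additive Gaussian shift noise (0.002 ppm default).
- **Peak-list pairs**: a planted contiguous site with rectangular
  attenuation (depth 0.8) and proton-shift perturbation; Gaussian noise
  on the intensity ratio and shifts.
- **SEC sets**: 10 µM + 10 µM totals, 100 µM peptide, activation K_D
  45 µM, intrinsic adaptor K_D 9 µM; Gaussian peaks (σ 0.04 ml) at
  2.6 ml (complex), 2.7 ml (free/apo arrestin, inside the window) and
  3.1 ml (free adaptor, outside); peak areas are Beer–Lambert integrals
  with nominal ε of 30 000 / 20 000 M⁻¹cm⁻¹.
- **Proteolysis**: first-order decay of the full-length band with
  complementary cleaved band, sampled at 0/5/10/20/30/60/90 min;
  multiplicative density noise (densitometry errors scale with band size).
- **Images**: 40 Gaussian puncta (PSF σ 0.2 µm) on a 192² grid at
  0.1 µm/pixel, unit amplitude, additive background noise with
  SD = amplitude/SNR (SNR 10 default); the arrestin channel reproduces a
  set fraction of receptor puncta at identical positions plus independent
  puncta elsewhere, with a minimum spot separation so chance overlap is
  negligible.

What the generators do **not** emulate — and hence what passing tests do
not demonstrate about real data: exchange-regime-dependent lineshapes and
peak overlap; non-Gaussian or correlated noise; SEC peak tailing, baseline
drift and on-column dissociation; partial trypsinolysis intermediates;
cell morphology, uneven illumination, out-of-focus light and true PSFs.
In particular, the Mander's M1 estimate on *raw* noisy pixels biases low
as SNR approaches ~5 (noise pixels entering the denominator and threshold
truncation of spot tails); imaging pipelines mitigate this by deconvolving
or denoising before quantification, which is outside this package's scope.
The double-positive puncta fraction, being count-based, is robust down to
SNR 5 in the same conditions.

## Problem sizes used in the automated checks

The test suite exercises: 1000 random triples for the oracle equivalence;
100 seeded titrations for estimator consistency (median K_D within 15%,
~2σ coverage ≥ 80%); 100 seeded peak-list pairs at ratio-noise SD 0.05 for
site recovery; three SEC configurations spanning saturating and partial
activation; 50 seeds per colocalization fraction in {0, 0.5, 0.7, 1}.
These sizes make the stochastic claims reproducible in seconds while
keeping Monte-Carlo error well inside the asserted margins.
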