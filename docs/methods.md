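# Methods

## Scope and model

`nirlipid` estimates three per-sample (and per-pixel) quantities from
near-infrared hyperspectral reflectance data of liver tissue: total
lipid content (mg lipid per g tissue), hydrocarbon chain length (HCL)
and degree of saturation (DS) of the accumulated fatty acids. The
chemistry, preprocessing and calibration stages are deterministic given
their inputs; all randomness lives in the synthetic-data generator and
is seed-controlled.

### Functional-group chemistry

Fatty acids are modelled as straight-chain carboxylic acids Cn:d with
one CH₃ terminus, one COOH terminus, 2d CH carbons and n − 2 − 2d CH₂
carbons. Branched, hydroxy and otherwise modified acids are out of
model; the odd-chain internal standard 17:0 is treated as an ordinary
straight chain. Double-bond position and cis/trans geometry are
invisible to CH/CH₂/CH₃ counting and are ignored (the `(n-x)` suffix in
shorthand like `18:2(n-6)` is parsed and discarded).

Tissue-level HCL and DS default to **pooled** ratios — group counts
summed over all molecules with molar-fraction weights, then the ratio
taken — because the per-sample statistic is a ratio over the sample's
molecules. Since every straight chain carries exactly one CH₃, pooled
HCL reduces to the molar-weighted mean carbon number. A `weighted` mode
(molar-weighted mean of per-acid HCL/DS) is kept because the HCL/DS
scatter is naturally read as a linear combination of per-acid vectors;
the two modes agree for HCL and differ slightly for DS (a
mediant-vs-mean effect of order 0.01 for liver-like mixtures). Both are
exposed so the discrepancy is testable.

Printed two-decimal comparisons round half away from zero (0.625 →
0.63), matching how the reference DS values are quoted.

### Preprocessing

Order of operations: reflectance → spike removal → ROI mean (for
calibration) or per-pixel (for mapping) → absorbance → crop → SNV.

- Reflectance R = (I_raw − I_dark)/(I_white − I_dark) per pixel/band.
  Pixels where |I_white − I_dark| falls below 1e−12 of the white-frame
  scale at any band are masked out; masks only ever shrink downstream.
- Absorbance is decadic, A = log₁₀(1/R), the spectroscopy convention;
  pixels with non-positive R are masked.
- The crop keeps the closed interval [1000, 1400] nm ("below 1000 and
  above 1400 removed" forces closedness at the endpoints).
- SNV uses the sample (n−1) standard deviation, the common chemometrics
  choice; switching to population SD is a one-argument change
  (`snv(x, ddof=0)`). SNV is applied to absorbance spectra: that is the
  representation the calibration consumes, and scatter/baseline effects
  are multiplicative/additive there.
- Spike removal is unspecified in the underlying protocol, so it is our
  design: a running median (7 bands) along the **spectral** axis, with a
  band replaced by the local median only when (a) its residual exceeds
  `z = 6` robust SDs (1.4826 × per-pixel median absolute residual,
  floored at 1% of the spectrum's range so noiseless spectra cannot trip
  on numerical curvature) and (b) the deviation is isolated — the
  smaller of its two adjacent differences is itself spike-sized. The
  isolation condition distinguishes single-band sensor artifacts from
  genuine ~10–12 nm absorption bands, which span ~5 grid points at the
  2.2 nm spacing. Spatial-neighborhood filtering was the open
  alternative; spectral filtering was chosen because the artifacts
  modelled (and injected by the generator) are single-band events.

### Calibration and validation

One support vector regression per target (lipid, HCL, DS), features =
per-sample SNV spectra as-is (SNV already standardizes each spectrum),
targets standardized internally and back-transformed. Defaults: RBF
kernel, C = 100, ε = 0.01 (standardized target units), γ from the
median pairwise squared-distance heuristic, libsvm tolerance 1e−4. None
of these are prescribed by the data model; they are recorded in
`RegressionConfig`/`RunConfig` so every run is reproducible. Validation
is leave-one-out cross-validation implemented as an explicit n-fold
refit; the report is tested for exact equality against an independent
brute-force loop. R² is the conventional cross-validated coefficient:
residuals of predictions against measurements, total sum of squares
about the measured mean; when measured variance is zero, R² is reported
as undefined (`None`) instead of dividing by zero.

Calibration uses per-sample ROI-mean spectra; deployment applies the
fitted model per pixel. The mapping stage adds no numerics beyond
masking and color scaling, which is asserted (map == per-spectrum
prediction exactly).

## The synthetic generator

The generator emulates the statistical structure of a diet-controlled
liver study so that recovery — not absolute spectral fidelity — can be
asserted.

**Compositions.** Five diet groups (ND, HFD, HCD, 2% LA, 12% LA) have
mean compositions over a 16-acid liver panel. Rather than inventing
fractions, each template is solved in closed form from the group's
published liver summary statistics (HCL between 17.22 and 17.83, DS
between 0.75 and 0.83, lipid means 65–174 mg/g): the 16:0 fraction
follows from the HCL target, the 18:2/18:3 split from the DS target,
with diet-specific minor acids and oleic fractions fixed at plausible
levels. The solved templates are dominated by 16:0, 18:2 and 18:3 (plus
18:1), reproduce each group's HCL/DS exactly, and preserve the
characteristic orderings (HCL rising 2% LA < 12% LA < HFD < ND < HCD,
DS in the reverse order). Lobe-to-lobe variability is Dirichlet
(concentration 150, giving per-group HCL SDs near the reported ~0.1)
around the template, with total lipid truncated-normal at zero using
the published group means/SDs.

**Spectra.** Beer–Lambert-style absorbance: each functional group
absorbs as a Gaussian band — CH₃ at 1150 nm, CH₂ at 1175 nm, CH at
1190 nm, all ~12 nm wide — scaled by its molar-pooled count per
molecule and by total lipid. Band centers sit at the literature
overtone positions; Gaussian shapes and the relative weights are free
parameters (the CH₃ weight is set 4× weaker than CH₂/CH, reflecting
the single methyl group per chain — this is what makes HCL the hardest
target, as in real data). Water is a rising sigmoid edge above
~1350 nm so the 1000–1400 nm crop is exercised; a per-sample linear
scatter baseline (offset 0.10–0.30, slope ±0.05) is added and must be
removed by SNV. No radiative transfer, PSF or temperature effects.

**Frames.** The instrument grid is 512 bands from 760 nm at 2.2 nm.
White = dark (100 counts) + a smooth lamp profile (~3000 counts); raw =
dark + (white − dark)·10^(−A) so that the reflectance equation inverts
the generator *exactly* — the zero-noise render→preprocess round trip
recovers the generated absorbance to 1e−6 and anchors the whole
pipeline to an analytic oracle. Noise is multiplicative shot-like
(0.3%), additive readout (2 counts) and isolated positive single-band
spikes (rate 2e−4, amplitude 20% of the white level, far above 10σ so
despiking is well-posed). Per-pixel lipid jitter (CV 4%) gives maps
spatial texture. Identical scene + seed ⇒ bit-identical cubes.

**What passing does not show.** The generator's band model is far
cleaner than tissue optics: no overlapping protein/water fine
structure, no scattering anisotropy, no wavelength-correlated noise.
Recovery R² values here (≈0.99 for lipid and DS, ≈0.8 for HCL at the
default noise) therefore demonstrate that the pipeline is correct and
well-conditioned, not that an instrument will reach them; on real
tissue the reported accuracies were R² > 0.9 (lipid, DS) and 0.82
(HCL), and only the qualitative pattern — DS and lipid easy, HCL
hardest — should be expected to transfer.

## Problem sizes

The shipped study size is 100 lobes (20 per diet) at 12×12 pixels per
lobe — above the ~70-sample threshold where calibration error was
reported to stabilize — and a 24×24 tumor scene; at these sizes the
full simulate→calibrate→validate cycle runs in seconds. ROI sizes per
real sample (1500–3000 pixels) are emulated at reduced pixel counts
since the ROI mean concentrates noise away regardless of area.

## Degenerate inputs and tie-breaks

- Compositions must sum to 1 within 1e−6 and be duplicate-free.
- DS is undefined for chains with no interior carbons (rejected at the
  type level: carbons ≥ 4).
- Constant targets: `fit` trains on zeros and predicts the constant;
  `loocv` reports R² as undefined rather than raising mid-report.
- All-identical spectra with varying targets are rejected as degenerate
  rather than silently fitted.
- Nearest-band lookup for pseudo-color channels tolerates at most one
  grid spacing of mismatch; color scaling is per-raster masked min/max
  by default, with optional fixed limits.

## Known limitations

- The 16-acid default panel and the diet templates are solved stand-ins
  constrained by group summary statistics, not measured compositions.
- SVR hyperparameters are sensible defaults, not tuned to any
  instrument; an inner grid search is deliberately not run by default
  to keep LOOCV honest and fast.
- The ENVI-style reader supports the band-sequential float64 layout the
  package writes, not the full zoo of vendor interleaves.
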