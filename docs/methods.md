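# Methods

## Problem and model

Two analytes whose UV absorption spectra overlap completely cannot be
quantified by direct absorbance at any single wavelength. Under the
Beer–Lambert law the mixture spectrum is additive and homogeneous in the
concentrations,

    A(λ) = ε_V(λ)·C_V·l + ε_R(λ)·C_R·l ,

with ε the molar absorptivity (L·mol⁻¹·cm⁻¹), C the molar concentration
and l the pathlength (cm). Mass concentrations in µg/mL convert as
molarity = c·10⁻³/M. Every transform in the package (gap derivative,
moving-average smoothing, division by a *fixed* divisor spectrum) is a
linear operator on the spectrum, so additivity and homogeneity survive the
signal processing — this single fact underwrites all three methods:

- **FDS.** At a wavelength where one analyte's derivative is zero at every
  concentration (a zero-crossing), the mixture derivative equals the other
  analyte's derivative. Linearity of the derivative makes the crossing
  concentration-independent.
- **RAD.** Dividing by a stored spectrum of analyte X at concentration C′
  turns X's contribution into the wavelength-independent constant δ = C/C′
  (the quotient of two proportional curves). Any two-wavelength difference
  of the ratio spectrum therefore cancels δ exactly; the difference is
  implemented as ΔP = P(λ₁) − P(λ₂), which is what the two-reading
  subtraction algebra gives.
- **RFD.** Differentiation annihilates the constant δ at every unmasked
  wavelength, so a single extremum amplitude suffices.

## Operators and numerical choices

- **Gap derivative.** `D(λ) = s·[A(λ+Δλ/2) − A(λ−Δλ/2)]/Δλ`, evaluated
  only where the full window fits (no zero padding — padding fabricates
  sign changes at the scan edges). Δλ must be an even multiple of the grid
  step so the half-offsets land on grid points. The error against the
  analytic derivative of a smooth band is O(Δλ²) (verified: halving Δλ
  shrinks the max error ≈ 4×). The scaling factor s is a display
  convention; it multiplies slope and reading alike and cancels in every
  recovery, r² and %RSD. Defaults Δλ = 4 nm, s = 10.
- **Smoothing.** Centred moving average over the odd point count spanning
  the window (41 points for 4 nm at 0.1 nm); ends shrink symmetrically.
  Smoothing is applied only *after* ratio division, mirroring laboratory
  practice of smoothing stored ratio spectra; raw absorption spectra are
  differentiated unsmoothed.
- **Division guard.** Ratio points where |divisor| < 10⁻³ AU are masked,
  not divided: an unguarded quotient amplifies noise without bound where
  the divisor analyte is transparent. Masks propagate through every
  subsequent transform (a point is valid only if its whole stencil was
  valid), and working-wavelength selection and amplitude lookups refuse
  masked regions.
- **Wavelength lookups** interpolate linearly between grid points;
  working wavelengths are physical nm values, never indices.
- **Zero-crossing acceptance.** A wavelength qualifies when every series
  member's derivative changes sign within one grid step of a common root
  and the interpolated amplitude at the consensus root stays below
  10⁻³ × the series' maximum derivative amplitude. The tolerance makes
  "zero absorption" operational on sampled, finite-precision data.
- **Selection tie-breaks.** Candidates within 1% relative sensitivity are
  ties and resolve toward shorter wavelengths. For RAD the pair is entered
  at the shortest wavelengths within 1% of the extreme per-unit ratio
  responses; on the default system this lands at an interior ratio peak
  and at the onset of the null plateau (~207/229 nm for the VGN-like
  analyte), the same structure the laboratory method uses.
- **Inverse prediction** `(reading − intercept)/slope` is never clamped;
  below/above-range flags communicate span violations. Calibrations with
  |slope| < 10⁻¹² are refused.
- **LOD/LOQ** use the SD-of-intercept convention, 3.3σ/|S| and 10σ/|S|,
  so LOQ/LOD ≡ 10/3.3. r² is the squared Pearson correlation (identical
  to regression R² in simple OLS); regression is unweighted throughout.
- **Rendered tables** round half away from zero to 2 decimals (3 for
  LOD/LOQ and SD cells). Dispersion statistics are always labelled by
  their formula (sample SD, population SD, %RSD) because published assay
  tables are not consistent about which one "SD"/"%RSD" means.

## Synthetic system

The generator exists so that every downstream stage — selection,
calibration, quantification, validation — can be exercised against known
ground truth. Bands are Gaussian in wavelength: the standard desk-scale
surrogate, with analytically known derivatives for oracle tests.

Shipped defaults (molar masses 303.4 and 522.6 g/mol are external
chemistry constants, used only for unit conversion):

| analyte | bands (center nm, σ nm, ε_peak) |
|---|---|
| VGN-like | (209, 7.5, 18100), (222, 4.0, 7240) |
| RGE-like | (226, 11, 32133), (201, 2.2, 15000), (275, 9, 8500) |

Design rationale:

- The VGN-like analyte must absorb appreciably (>5% of its maximum) out to
  230 nm — the complete-overlap premise — yet be below 1% of its peak
  beyond 235 nm. A single Gaussian cannot satisfy both (the 5% constraint
  forces σ ≥ 8.6 nm, the 1% constraint σ ≤ 8.6 nm), so a weak 222 nm
  shoulder steepens the cutoff while the 209 nm band stays dominant.
- The RGE-like 275 nm band provides first-derivative signal in the long-
  wavelength region where the VGN-like analyte is numerically zero.
- The RGE-like 201 nm band gives both analytes' *ratio* spectra interior
  peaks and valleys; with smooth single-humped models the ratio of two
  Gaussians is monotone and the RAD/RFD selections would degenerate to
  scan edges. Real spectra have such short-wavelength structure.
- Peak absorptivities sit at the magnitudes measured for the real drugs
  (18100 at 209 nm, 32133 at 226 nm).

Noise is additive, homoscedastic, Gaussian on absorbance — the simplest
model consistent with a double-beam instrument — with default SD 0.002 AU
for validation simulations. All draws are reproducible from explicit
seeds; identical specs give bit-identical spectra.

What the generator does **not** emulate: the true band shapes and hence
the exact literature working wavelengths (213.7, 230.6, 237.2, 287.7 nm …)
— the synthetic system has zero-crossings and ratio features with the same
*roles* at nearby but different wavelengths, and all synthetic studies use
wavelengths discovered by the selector, not literature values; stray
light, baseline drift, heteroscedastic or correlated noise; instrument
bandpass convolution. Passing synthetic validation therefore demonstrates
the correctness of the algebra and the statistics under ideal additive
noise, not instrument-grade performance on real extracts. For real
exported spectra the literature working parameters can be supplied
verbatim through the config/CLI.

## Study designs (defaults)

- Calibration: seven points, 2–60 µg/mL (VGN-like) and 5–90 µg/mL
  (RGE-like), selection and calibration on noiseless series (laboratory
  divisors are stored, smoothed scans; noise belongs to the samples being
  assayed).
- Accuracy/precision: levels 15/30/50 and 25/55/85 µg/mL (low/mid/high
  across each span), 3 replicates, 3 days for interday precision. Each
  accuracy determination is the mean of its triplicate scans, the
  convention assay tables report.
- Specificity: five mixtures — (RGE, VGN) = (10, 50), (40, 50), (40, 5),
  (70, 5), (70, 25) µg/mL — assayed once each by all six (analyte,
  method) models; across-mixture mean and population SD summarize each
  column.
- Standard addition: base 40 + 20 µg/mL (the 2:1 formulation diluted into
  range), spikes of +10/+20/+30 (RGE-like) paired with +5/+10/+15
  (VGN-like); base and spiked solutions measured as triplicate-scan means.
- Acceptance envelopes: r² ≥ 0.999, recoveries within 98–102%,
  %RSD < 2 — the conventional acceptance windows for this assay class.
- Problem sizes: 1001-point grids (200–300 nm at 0.1 nm, the acquisition
  resolution of a 0.1 nm slit), ≤ a few hundred simulated spectra per full
  validation run; the entire suite executes in seconds on one CPU.

## Known limitations

- Binary mixtures only; no multivariate calibration (CLS/PLS) and no
  automated divisor-concentration optimization beyond supplying candidates.
- First-order derivatives only; no Savitzky–Golay or Fourier smoothing.
- Homoscedastic noise only; weighted regression is out of scope.
- JCAMP-DX import covers plain-text AFFN encodings, read-only; compressed
  (SQZ/DIF/DUP) instrument exports must be converted upstream.
- The FDS method is intrinsically the noisiest of the three (a two-point
  difference of unsmoothed absorbance); its LOD/LOQ and %RSD are
  correspondingly the largest, as the validation report shows.
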