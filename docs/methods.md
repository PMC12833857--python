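# Methods

## Problem setting

Harmonic normal-mode calculations systematically overestimate observed
vibrational fundamentals because the quadratic force field neglects
anharmonicity. Two consequences drive this package's design:

1. calculated frequencies need empirical *scaling factors* before they
   can be compared with measured band positions, and
2. even after scaling, deciding *which* candidate conformer produced a
   measured spectrum requires a quantitative similarity score, because
   conformers of flexible molecules (aromatic ring + ethyl
   alcohol/amine side chain, and their hydrates) differ by only a few
   cm⁻¹ across most of the spectrum.

The measured spectra this targets are peak lists: Q-branch maxima of
jet-cooled ionization-detected stimulated Raman spectra, with loss- and
gain-channel tags, signal-to-noise ratios and line widths. Band maxima
are used directly as fundamental frequency estimates; only distinct
features with SNR > 2.5 and fwhm > 4 cm⁻¹ are admitted (strict
inequalities; peaks lacking the metadata pass but are tallied, since
curated peak lists often omit the quality columns).

## Scaling factors

For pairs (νᵢ, ωᵢ) of experimental fundamental and calculated harmonic
frequency, the scaling factor is the least-squares minimizer of
Σ(λωᵢ − νᵢ)²:

    λ = Σ νᵢωᵢ / Σ ωᵢ²

the standard estimator of the scaling-factor literature. Three schemes
partition the data:

* **global** — one factor for everything;
* **range-dependent** — high (>2000 cm⁻¹), mid (1000–2000 cm⁻¹,
  boundaries inclusive, since the neighbouring windows are quoted as
  strict), low (<1000 cm⁻¹);
* **mode-dependent** — the high range split into O–H, N–H, aromatic
  C–H and ethyl C–H stretches (well-isolated modes for which a
  per-type factor is meaningful), with mid/low as in the range scheme.

Classification uses the experimental frequency for database pairs and
the harmonic frequency when scaling a purely calculated spectrum (where
no experimental ν exists). Stretch labels must be supplied by the data
above 2000 cm⁻¹ under the mode scheme; a missing label is an error, not
a guess.

The uncertainty Δλ is, by default, the sample standard deviation
(n−1 denominator) of the per-pair ratios νᵢ/ωᵢ. This reproduces the
magnitude of published global uncertainties (≈0.01), is scheme-agnostic,
and dominated by genuine mode-to-mode scatter rather than by the fit's
standard error. An RMS-residual alternative,
√(Σ(ν−λω)²/Σω²), is exposed as a configuration switch for sensitivity
checks; the choice between the two was genuinely open and the ratio
form was adopted as the default because it is the more conservative
(larger) of the two on heterogeneous data.

### Error statistics and protocols

Signed errors e = λ_class·ω − ν feed a fixed battery: RMS, mean
absolute deviation, standard deviation σ (ddof 1), MAPE
(100·mean(|e|/ν)), quartiles Q1/Q2/Q3 of |e| (linear interpolation),
and the signed extremes. Quartiles are computed on absolute errors so
that Q2 reads as "typical discrepancy in cm⁻¹".

Stability protocols:

* **Resampling** — 100 iterations of random 70%/30% training/test
  splits, stratified per class so every class is fittable each
  iteration (stratification is a design choice; unstratified splits
  would occasionally lose a small class entirely). One integer seed
  drives a single generator for the whole run; iterations that still
  fail to fit are redrawn (up to 1000 attempts) and counted.
* **Top-intensity refit** — factors recomputed on the top 20% of pairs
  by experimental intensity (selected globally, not per class) must
  stay within the full-fit Δλ for the derivation to count as
  composition-independent.

## Spectral matching

Preprocessing normalizes each peak list to maximum intensity 1 and, for
whole-spectrum methods, convolves sticks with unit-peak-height
Lorentzians, L(x) = I·γ²/((x−ν)²+γ²), γ = fwhm/2, fwhm 4 cm⁻¹ by
default, on a 300–3800 cm⁻¹ grid at 1 cm⁻¹ (the grid step is
configurable; 1 cm⁻¹ resolves the default line width comfortably).
Unit *height* rather than unit area keeps an isolated convolved maximum
equal to its stick intensity, matching how stick and broadened spectra
are overlaid in practice.

Four similarity methods score a measured spectrum against each scaled
candidate:

1. **Cross-correlation**: both convolved spectra are zero-meaned and
   unit-normed; the score is the maximum correlation over integer-step
   displacements within ±20 cm⁻¹ (positive lag = calculated spectrum
   moved to higher wavenumber). Bounded in [−1, 1]. Because shifted-in
   samples are zero-padded, even a perfect translation scores slightly
   below 1 (≈1 − 10⁻⁴ on typical grids); this is inherent to the
   bounded-window form.
2. **Average Euclidean barcode distance**: a cost matrix over feature
   pairs, c = √(Δν² + w²ΔI²), is minimized by the Kuhn–Munkres
   assignment; the score is total cost / number of matched measured
   peaks. Surplus calculated peaks (the usual case — measured spectra
   are subsets, due to beam population and line overlap) stay unmatched
   at zero penalty. Dividing by the measured count keeps scores
   comparable across species with different feature counts.
3. **Average Manhattan barcode distance**: as above with
   c = |Δν| + w|ΔI|.
4. **Optimal transport**: intensities normalized to unit total mass on
   each side; the Wasserstein-1 distance (∫|F₁−F₂| dν over the
   cumulative mass functions) is the minimal work to move intensity
   along the frequency axis. Computed on stick spectra, not convolved
   ones — transport is between discrete features.

The intensity weight **w = 10 cm⁻¹ per unit normalized intensity** sets
how much an intensity mismatch costs relative to a frequency offset: a
full-scale intensity error equals a 10 cm⁻¹ shift, placing typical
intensity noise on the same cost scale as typical median frequency
errors of globally scaled data. No published value exists for this
weight; it is declared, configurable, and all reported benchmarks use
the default.

Ranking is per method (cross-correlation descending, distances
ascending); ties are broken by candidate input order and logged.
A candidate that cannot be scaled (unclassifiable feature) is marked
failed and excluded from ranks rather than aborting the comparison.

### Distance uncertainties

Average-distance uncertainties assume independent Gaussian errors
(σ_ν per peak position, σ_I per normalized intensity, on both sides)
and propagate them to first order through each assigned pair's cost,
treating the assignment as fixed:

* 1-D: Var(c) = 2σ_ν²
* Euclidean 2-D: Var(c) = 2(Δν/c)²σ_ν² + 2(w²ΔI/c)²σ_I²
* Manhattan: Var(c) = 2σ_ν² + 2w²σ_I²

with the Manhattan form used as the bound for a coincident (c = 0)
pair, where the Euclidean gradient is undefined. This is this package's
own formulation of standard first-order propagation; it agrees with
Monte-Carlo perturbation to within ~10% on well-separated assignments
but degrades when |Δν| approaches σ_ν (the |·| kink) or when a
perturbation would flip the assignment.

## Synthetic data generator

The generator emulates the statistical structure of the motivating
measurements so the whole pipeline is testable without proprietary
data:

* **Composition**: 824 database rows per theory level with class counts
  O–H 35, N–H 56, C–H(ring) 118, C–H(ethyl) 112, mid 321, low 182 —
  the published per-class proportions rescaled to the published total.
* **Ground truth**: per-class λ* defaults to benchmark mode-dependent
  values at each of the eight supported functional/basis combinations,
  so fitted factors have a known target.
* **Harmonic windows** (pre-scaling): O–H 3650–3900, N–H 3450–3600,
  aromatic C–H 3150–3250, ethyl C–H 3050–3150, mid 1080–1970, low
  420–980 cm⁻¹ — standard ranges, with margins so that scaled
  frequencies plus jitter and conformer offsets never cross the
  1000/2000 cm⁻¹ class cutoffs.
* **Noise model** (defaults): frequency jitter σ = 5 cm⁻¹ between
  scaled harmonic and fundamental positions; log-normal intensity
  noise with 20% coefficient of variation; 30% peak dropout; 0.5
  interloper gain-channel peaks per 1000 cm⁻¹ whose SNR (1–8) and fwhm
  (2–9 cm⁻¹) straddle the inclusion thresholds, so the fundamentals
  filter removes some and leaves the rest as realistic contamination.
* **Conformer structure**: candidates share one base mode set and
  differ by per-class frequency offsets of 2–15 cm⁻¹ (random sign,
  plus 2 cm⁻¹ per-mode scatter) and log-normal intensity
  redistribution — similar spectra, as real conformers have.

What the generator does **not** emulate: normal-mode coupling and Fermi
resonances (which shift apparent frequencies non-multiplicatively and
are the known failure mode of per-class scaling for ethyl C–H),
correlated theory-level errors beyond the per-class factor,
instrument baselines, and overlapping unresolved features. Passing
tests therefore demonstrate the statistical machinery and the relative
behaviour of the similarity methods under realistic noise — not the
accuracy of any electronic-structure method on real molecules.

## Numerical choices and degenerate inputs

* Assignment uses `scipy.optimize.linear_sum_assignment`; transport
  uses `scipy.stats.wasserstein_distance`. Both are cross-checked in
  the test suite against independent oracles (exhaustive enumeration
  over all row-into-column injections; a linear-program transport
  solver).
* λ fits require ≥ 2 pairs; classes below that are reported absent
  with a warning rather than crashing a whole scheme.
* Frequencies are written to 0.1 cm⁻¹ (below experimental resolution),
  making file round-trips exact.
* Duplicate frequencies within one record are rejected; records are
  re-sorted on every construction.
* Boundary frequencies 1000 and 2000 cm⁻¹ classify as mid.
* The commas in basis-set names are replaced by periods in database
  column headers to keep the CSV dialect quoting-free.

## Problem sizes used by the checks

The shipped acceptance script and test suite run the full protocol at
the study's native sizes — 824 database rows per theory level, 100
resampling iterations, 200 identification scenarios of 8 candidates
(~50 modes each) — which completes in a few seconds; nothing is
scaled down.

## Known limitations

* The identification benchmark's ≥95% success rates for the barcode
  distances hold under the generator's default noise; heavier dropout
  or jitter comparable to the conformer offsets degrades all methods.
* Cross-correlation is sensitive to the convolution width and lag
  window; it is reported and ranked but is not the headline criterion.
* Optimal transport is deliberately included as a negative control: it
  redistributes intensity freely across adjacent features and is
  demonstrably fooled by intensity-shuffled impostors (see the
  adversarial test), so it should not be used alone for structural
  identification.
* Raman intensity scaling (harmonic activities vs observed gains) is
  out of scope; intensities are treated as per-record arbitrary units
  and normalized.
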