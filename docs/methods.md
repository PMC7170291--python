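# Methods

## The problem

Gamma cameras are checked every morning with a flood-field acquisition: a
spatially uniform source (a Co-57 sheet, or a Tc-99m point/sheet) imaged
before patient studies.  A healthy detector returns an image whose only
variation is Poisson counting noise; a failing one adds *structure* —
localized sensitivity dips from weak photomultiplier tubes (PMTs),
gradients from electronic drift, periodic interference, edge faults.
Classical pixel-value metrics such as the integral uniformity (IU) compare
smoothed extreme pixel values and are driven as much by counting noise as
by structure, so subtle but clinically relevant patterns pass unnoticed.
`floodqc` implements a frequency-domain alternative, the structured noise
index (SNI), and the automation around it: sorting incoming DICOMs,
scoring, alerting at two thresholds, archiving, and fleet statistics.

## The structured noise index

For an image patch I(x_i, y_j) with pixel spacing Δx, Δy, the 2D noise
power spectrum is the single-realization periodogram

    NPS(u, v) = (Δx·Δy)/(N_x·N_y) · |DFT(I − Ī)|²,

with Ī the patch mean, so the DC bin is exactly zero.  No windowing or
ensemble averaging is applied; each ROI is one realization.  An optional
least-squares plane detrend is available (`sni_for_patch(..., detrend=True)`)
and off by default.

Pure Poisson noise has variance equal to its mean, so its NPS is flat at
the *quantum level* L = Ī·Δx·Δy.  The structured spectrum is the residual
NPS − L over the non-DC bins.  Both the input and the structured spectrum
are weighted by a band-pass visual response

    V(r) = r^1.3 · exp(−c·r²),

where r is radial frequency in cycles/degree and c = 1.3/(2·r*²) places
the peak at r* = 4 cycles/degree (c = 0.040625 deg²·cyc⁻²).  Frequencies
are converted to visual angle by assuming the full image width is displayed
at 6.5 cm and viewed from 150 cm (small-angle mapping, error < 0.1%); ROIs
inherit the full-image mapping, so a 64-pixel window occupies 64/W of the
display.  The SNI is the ratio of the visually weighted integrals,

    SNI = Σ w·(NPS − L) / Σ w·NPS,   clamped to [0, 1],

with w = V(r)^p.  The default weighting exponent is p = 2 (a power
spectrum is weighted by the *squared* transfer function of a filter);
p = 1 is selectable via `ViewingGeometry(filter_exponent=1)`.  Absolute
SNI values, and therefore the placement of the alert thresholds, depend on
this choice.

### Why the quantum subtraction is not clamped per bin

Each non-DC periodogram bin of a structure-free flood is approximately
exponentially distributed with mean L.  Zeroing the negative residuals bin
by bin before integrating would add E[max(X − L, 0)] = L/e per bin to the
numerator — about 37% of the total quantum power — and pin the
structure-free SNI near 0.37 *per patch*; after taking the maximum over
~170 ROIs the image score of a perfectly clean flood would exceed the 0.50
alert threshold almost always.  The numerator therefore uses the signed
residual (negative and positive quantum fluctuations cancel in the sum)
and only the final ratio is clamped to [0, 1].  `structured_nps` still
offers clamped output (`clamp=True`, the default) because a non-negative
spectrum is the right thing to *display*.  With signed subtraction the
simulated structure-free image SNI is ≈ 0.33 ± 0.05 — comfortably below
the 0.50 threshold, while leaving the headroom that real floods (which
always carry some genuine residual structure) are known to consume.

The quantum mean defaults to the *ROI* mean (a local floor); the global
image mean can be passed via `quantum_mean=` instead.

## ROI scheme

Two large, equal, overlapping squares span the central 90% of the field:
side = round(0.9·min(rows, cols)), anchored at the top-left and
bottom-right corners of the centered 0.9·rows × 0.9·cols region (on a
square matrix they coincide and one is kept).  A roving 64×64 window then
sweeps the entire image in 16-pixel steps, with a final edge-clamped
position per axis when the span is not step-aligned — 169 positions on a
256×256 matrix.  The image SNI is the maximum over all ROI scores; ties go
to the earliest ROI (large ROIs first, then raster order), so the sweep is
deterministic.  Rounding is half-up throughout, and centered regions place
odd margins one pixel toward the top/left; the same conventions are used
for the UFOV/CFOV masks.

## Artifact image

Under the counting-noise null the mean-subtracted flood is approximately
iid with per-pixel variance Ī, so each non-DC coefficient of the
unnormalized DFT has Rayleigh-distributed magnitude with scale
√(N_x·N_y·Ī/2).  Coefficients at or below the 1 − 1/N_bins quantile of
that law (≈ one expected false coefficient per image) are zeroed, the DC
term is always removed, and the real part of the inverse transform is the
artifact image.  Thresholding acts on magnitudes, so Hermitian pairs
survive or die together and the inverse transform is real to rounding
error.  Retained coefficients keep full magnitude and phase; the threshold
is per-bin (no radial pooling) and the map is computed on the full field
for the diagnostic figure.

## Integral uniformity baseline

IU = 100·(max − min)/(max + min) of the smoothed counts inside a field of
view: UFOV = centered round(0.9·dim) per axis (230 on 256), CFOV =
centered round(0.75·UFOV) per axis (173 on 256).  Smoothing is the
standard 9-point kernel [[1,2,1],[2,4,2],[1,2,1]]/16 with edge taps
renormalized over in-bounds support.  The metric operates on the native
matrix — no rebinning to a coarser analysis grid is applied.  A
consequence worth knowing: at daily-flood count densities (≈ 76 counts per
native 256² pixel for 5×10⁶ totals) the smoothed Poisson extremes alone
give UFOV IU ≈ 17%, far above the conventional 5% action level, so on
simulated floods IU alerts on essentially every image.  Its detection
"sensitivity" is then trivially high and its weakness appears as false
positives — vendor programs avoid this by analyzing on coarser pixels with
thousands of counts each, a protocol this package deliberately does not
guess at.

## Simulator

A flood is modelled as independent per-pixel Poisson draws with mean
total_counts · S / ΣS, where S is a multiplicative sensitivity map of unit
mean built from parameterized defects (Gaussian PMT dropout, linear
gradient, sinusoid, edge band — see `floodqc.synthetic`).  Defaults mirror
a typical daily QC acquisition: 256×256 matrix, 5×10⁶ total counts,
2.2 mm pixels, Co-57.  Unit-mean renormalization after applying defects
keeps the count target independent of defect amplitude.  Campaign
simulations derive per-image seeds from (seed, day, CRC32(station)), so
results are reproducible and independent of iteration order; images whose
defects reach amplitude 0.10 are labelled "service-worthy" (a 10% local
sensitivity loss is plainly actionable; the threshold is a simulator
configuration, not a measured quantity).

What the simulator does *not* reproduce: collimator scatter, energy
windows, dead time, isotope-specific uniformity-correction maps, intrinsic
PMT mosaic patterns, or drifts correlated across days.  Passing tests on
simulated floods therefore demonstrate the estimator's statistical
behavior under the stated noise model, not clinical performance on any
particular camera fleet.

## Pipeline conventions

* Sorting is a pure function of header fields (station allow-list,
  substring tokens against the series/study description, pixel-sum count
  minimum, matrix-size list); which DICOM attributes encode "study type"
  varies by vendor, so token matching is configurable.
* Alert thresholds default to 0.50 (lower: physics recipients) and 0.60
  (upper: physics + clinical + engineering); "exceeds" is strict
  inequality, configurable to ≥.
* Every ingested file yields exactly one record — analyzed, skipped with
  the first failing sort criterion, or errored with the failing stage.
* The record store is an append-only CSV keyed by (station, acquired_at,
  analysis_version); duplicates are rejected, and re-analysis under a new
  version coexists with history.  Archives never overwrite (collision
  suffix).
* Notification is a pluggable interface; the default writes one JSON
  message per alert to an outbox directory.  SMTP delivery is deployment
  plumbing outside this package.
* Multiple floods from one station on one day are each processed and each
  alert independently.

## Validation statistics

Detection is scored at *instance* granularity against a service log: an
image-quality event (station, start, end) is a true positive if any record
for that station within the window exceeds the threshold; false positives
are maximal runs of consecutive alerting days overlapping no event, each
run counting once (a multi-day repair produces several poor floods for one
issue).  Sensitivity = TP/(TP+FN), reported as undefined — never zero —
when there are no eligible events.  The coefficient of variation uses the
sample (n−1) standard deviation; the fleet CV is the mean per-station SD
divided by the mean per-station mean.  Both pooled and per-period
computations are available through the `period` argument.

## Problem sizes

Simulation-based checks use 256×256 floods at 5×10⁶ counts (the typical
clinical acquisition), with 100 seeds for null-distribution statements,
100 paired seeds per amplitude for monotonicity, and 20 six-day two-camera
campaigns for the SNI-vs-IU comparison; oracle-equivalence checks use
8×8–16×16 patches where the brute-force double-sum transform is exact and
cheap.

## Known limitations

* The SNI scale depends on the filter exponent and on anchoring the
  display size to the full image width; scores are comparable within one
  configuration, not across configurations.
* M = 1 periodograms make individual bin estimates noisy by construction;
  the visual weighting concentrates mass in a modest annulus of bins, so
  patch scores carry sampling scatter of a few hundredths.
* The IU baseline is self-consistent but not vendor-identical (no rebinning
  protocol, no vendor smoothing variants).
* Poisson draws are independent across pixels; correlated detector noise is
  out of scope.
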