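# Methods

## Signal model

D-FFOCT contrast is modelled phenomenologically. Each voxel's raw
interferometric amplitude is

    x(t) = A(c) + Σ_b σ_b(c) · u_b(t) + ε(t),

where `c` is the voxel's compartment, `A(c)` its static backscatter
amplitude, `u_b(t)` independent unit-variance Gaussian processes strictly
band-limited to the three analysis bands, `σ_b²(c) = V(c) · w_b(c)` the
compartment's total AC variance split by band weights (Σ w_b = 1), and
`ε(t)` white detector noise. The bands are the instrument presets —
(0, 0.6], (0.6, 5.4], (5.4, 25] Hz — and band-limited noise is synthesised
by drawing Fourier coefficients only on the rFFT bins whose centre
frequency falls in the band, using the same bin-assignment rule as the
analysis estimator. Consequences worth knowing:

* band weights are exactly controllable and analytically checkable
  (a flat-spectrum voxel yields band powers proportional to bandwidths
  0.6 : 4.8 : 19.6);
* no optics are simulated — no coherence gating, PSF or speckle
  statistics. The phantom validates the *analysis*, not the instrument;
* the 4-frame block average attenuates in-band power slightly near the
  25 Hz edge (|H(f)|² ≈ 0.70 at 25 Hz). This cancels in every T1:T0 ratio
  and does not move power between bands, so no correction is applied.

## Spectral estimator

The production estimator is a mean-removed, rectangular-window one-sided
periodogram; band integration assigns each bin to the band containing its
centre frequency, the DC bin belongs to no band, and (for even n) the
Nyquist bin is not doubled. Normalisation is Parseval-exact: the sum over
all bins k ≥ 1 equals the biased sample variance. This is the simplest
estimator with an exact brute-force oracle (explicit DFT summation), which
the test suite checks to 1e-9 relative. Welch averaging is available
(`estimator="welch"`) for lower variance at coarser resolution; channels
are integrated *power* by default with an amplitude (square-root) option,
since the instrument's convention is not public. Quantification always
reads the raw float channels; the 8-bit RGB export is display-only.

## Acquisition defaults

1000 frames at 300 Hz, non-overlapping 4-frame average (250 frames at
75 Hz effective, Nyquist 37.5 Hz > 25 Hz top band edge), 1 µm/px isotropic
sampling. The frequency grid is 0.3 Hz in both the generated (1000 @ 300)
and analysed (250 @ 75) domains, so generation and analysis agree on band
membership bin by bin.

## Phantom geometry and populations

The default field is 256 × 256 µm (the instrument's 1.25 × 1.25 mm field
is supported; the small default keeps a full simulate–analyse cycle at a
few seconds). Two muscle "layers" appear as complementary regions with
orthogonal fiber textures; ganglia are random ellipses (semi-major
30–46 µm) joined by 8 µm tracts; the plexus renders dark, muscle bright,
and the plexus rim very bright in static contrast. Nuclei are ellipses
with axis ratio uniform in [1, 2], areas drawn per class from the measured
Gaussians — neurons N(89.9, 17.9²) µm², glia N(49.9, 15.8²) µm² (draws
below 5 µm² are rejected) — placed by rejection sampling wholly inside
ganglia with ≥1.5 px clearance (relaxed to 0.5 px before failing; rasters
always stay disjoint). Detection dropout is Bernoulli per class (neuron
0.04, glia 0.22, from the reported 163/170 and 71/91 detection counts);
dropout nuclei keep DAPI visibility but inherit the cytoplasm fluctuation
model.

Per-compartment fluctuation defaults are directional, not calibrated — no
quantitative extra-ganglionic spectrum is published. They are chosen so
that (i) every band is stronger inside ganglia than outside, (ii) nuclei
are medium/high dominant with neurons stronger than glia, (iii) the medium
band dominates extra-ganglionic spectra with low ≥ high:

| compartment          | total variance | weights (L, M, H) |
|----------------------|---------------|--------------------|
| neuron nucleus       | 12.0          | 0.15, 0.45, 0.40   |
| glia nucleus         | 6.0           | 0.20, 0.50, 0.30   |
| ganglion cytoplasm   | 2.0           | 0.30, 0.50, 0.20   |
| extra-ganglionic     | 0.40          | 0.30, 0.55, 0.15   |
| muscle               | 0.30          | 0.35, 0.50, 0.15   |

Detector noise SD is 0.3 (static amplitudes are O(1)).

## Treatments

A treatment is a triple of per-band *amplitude* gains applied to the three
ganglionic compartments only (band variances scale by gain²; weights are
renormalised). Whole-ganglion band-power ratios therefore equal 100·g²
in expectation, which the response tests verify across a gain grid.
Defaults (magnitudes are free parameters; only directions are anchored):

* veratridine 75 µM: gains (0.8, 1.5, 1.5); additionally clears dropout
  flags with probability 0.5, reproducing the appearance of previously
  silent nuclei. Dropout flags live in the scene, so the rescue is a
  scene-level operator (`rescue_dropouts`), separate from the spec-level
  variance rescale;
* TTX 1 µM: gains (0.85, 1, 1) — a small low-band suppression only, since
  no nuclear-level effect was reported and basal activity is low;
* mannitol: gain_b = 1 / (1 + k_b·dose) with k = (0.0030, 0.0025, 0.0020)
  per mM — strictly monotone in dose, identity at dose 0;
* vehicle / washout: exact identities (washout re-simulates from the
  baseline spec).

## Segmentation and measurement

Ganglia: static-dark (Otsu) ∧ dynamically-bright (Otsu on log total
power — the log scale separates tissue from background rather than nuclei
from everything else), closing (r=3), hole filling, opening (r=5) to cut
tracts, area filter ≥ 400 µm². A user-supplied mask bypasses all of this.

Nuclei: medium+high channels, Gaussian smoothing (σ = 0.8 px), global
isodata threshold on the log power inside ganglion masks (detects both
classes), hole filling, watershed on the smoothed distance transform
seeded at h-maxima (h = 1; foreground components that receive no marker
are rescued as single labels), then a per-blob boundary refinement that
re-thresholds each nucleus at the midpoint of its own foreground and
local-background means. The midpoint rule is the reason the measured areas
are unbiased: a Gaussian-smoothed step edge crosses the mean of its two
plateau levels exactly at the step. Isodata (iterated class-mean midpoint)
was preferred over Otsu for the same reason; Otsu remains available.
Area filter 20–300 µm²; areas are pixel counts × pixel_size²; band means
are taken on raw channels. On default phantoms the measured-minus-true
area error is +0.1 ± 0.4 µm² (neurons) and +0.2 ± 1.0 µm² (glia).

Classification: area ≥ 65 µm² → neuron, < 65 µm² → glia, boundary
configurable (neuron by default). Matching to ground truth is greedy
nearest-centroid, one-to-one, 5 µm radius.

Known biases: glia below the 20 µm² filter (≈3% of the class Gaussian)
are lost, raising the measured glial mean by ≈ +1 µm²; rasterisation at
1 µm/px contributes ≈ ±0.3 µm². Both are inside the 3-SE tolerances used
throughout.

## Response quantification

Per-nucleus ratios use the T0 labels at every time point; the ganglion
mean of its member nuclei is the statistical unit (nucleus-level tables
are exposed but pseudo-replicated). Emergent nuclei (present at T1, absent
at T0) have no denominator and are counted separately. Zero T0 means yield
missing ratios with a warning. Two-group comparisons use scipy's
Mann-Whitney U (exact null for small untied samples); dose-response uses
Kruskal-Wallis plus a hand-rolled Dunn's post-hoc versus control (rank
sums with tie correction) with Holm adjustment by default (Bonferroni or
none selectable) — no post-hoc library ships the test in this
environment's stack.

## Problem sizes in tests and drivers

The test suite and drivers use scaled-down but structurally identical
problems, chosen as the package's own defaults: 128–288 µm fields, 2–4
ganglia, full 1000-frame acquisitions. The morphometry experiments split
the study populations (219 neurons, 125 glia) over eight 288 µm phantoms.
Treatment experiments use two replicates of a 128 µm two-ganglion phantom
per arm (four ganglion units per group). Type-I-error checks run the
statistical routines on 200–500 null draws directly; the compartment
comparison uses 8 regions per side because the exact 5-vs-5 Mann-Whitney
null is too discrete to reach α = 0.05.

## What passing tests do and do not show

The phantom shares the data's geometry, its printed population parameters
and its acquisition protocol, but its fluctuations are exactly band-limited
Gaussian processes and its compartments are exactly homogeneous. Passing
tests therefore demonstrate that the pipeline recovers known inputs under
the stated noise — not that the biological magnitudes in the source
figures are reproduced (those are figure-only and are deliberately not
asserted anywhere).

## Limitations

* Single-plane 2D+time by default; the thin z-stack mode of the source
  acquisitions (60 × 0.5 µm planes) is not rendered.
* No mucosa/submucosa; no deformable registration (fixation-induced
  deformation is deliberately neglected, as in the source procedure).
* The fluorescence channels are idealised blobs, not microscopy PSFs.
* Landmark tables contain all nuclei; scenes with fewer than 10 nuclei
  yield correspondingly fewer landmarks.
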