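# Methods

## Scope and model

`aisquant` quantifies proximal-axon pathology in cultured motor neurons
from multichannel immunofluorescence, together with the matching
patch-clamp read-outs. The measurement model follows standard practice in
axon-initial-segment (AIS) morphometry:

* All imaging measurements operate on the **maximum-intensity projection**
  (MIP) of a Z-stack. The per-cell compartments are the **soma** (delimited
  on the somatodendritic MAP2 channel), the **GAP** (the axon-hillock
  stretch between the soma contour and the proximal AIS end, visible as
  weak MAP2 / strong β3-tubulin staining), and the **AIS** (the
  ankyrin-G-positive segment).
* **Integrated density** of a region is area (µm²) × mean gray value —
  algebraically the pixel-value sum × pixel_size². Per-channel GAP and AIS
  densities are summed into a proximal total; this additivity is exact by
  construction and asserted, not toleranced.
* **Mean axonal caliber** is region area divided by region length, a width
  proxy robust to irregular outlines.
* Only cells with a **single soma-derived AIS** enter quantitative
  analysis; cells whose AIS abuts the soma have no GAP and are excluded
  from GAP-dependent comparisons (ratio fields carry a reason code instead
  of a value).

## Segmentation and geometry

**Thresholds** are calibrated on control cells as a percentile of the
pooled control pixel distribution (order statistic, method recorded in the
model). The library default is the 99th percentile; the pipeline helper
uses channel-specific percentiles chosen against the pooled abundance of
the structure each threshold must isolate: AnkG 98 (the AIS covers ~1% of
a control field, so the threshold must sit below that rank), β3-tubulin 92
(stained structures cover ~10%), NF-L 99, and pNF-M/H 99.99 — normal axons
carry moderate phospho-neurofilament staining, and only accumulations
should exceed the brightest staining control cells ever show. Threshold
comparisons are strict (`>`): a pixel exactly at threshold is negative.
Calibration images must come from pathology-free control cells
(`synthgen.calibration_params()` in synthetic studies): with a
near-ceiling percentile, a single accumulation-bearing cell in a small
calibration set would raise the pNF-M/H threshold to accumulation
intensity and blind the detector — exactly as selecting a visibly
pathological "control" image would in a real experiment.

**Soma delimitation** floods the supra-threshold MAP2 component from an
annotated seed and severs each annotated neurite entry with a thin
circular-arc cut (radius ≈ 2× the process width, lateral reach ≈ 1.5×)
concave around the leaving process. A thin cut line reproduces the concave
hand-drawn contour while removing almost no area; removing a filled disc
instead was found to bias GAP area (and hence caliber) by tens of percent
on short GAPs. Pass-through mode rasterises an explicit soma polygon when
the annotation provides one.

**AIS detection** labels supra-threshold AnkG components outside the soma
(8-connectivity, one closing of radius 1 px so touching fragments count
once), discards components shorter than 5 µm (configurable despeckling
guard), and tightens each survivor to its half-maximum contour — for a
step edge blurred by a symmetric PSF the half-maximum contour sits on the
true boundary, whereas the threshold-level component is dilated by the
PSF flank.

**GAP delineation** is geodesic. Within the thresholded axon corridor the
GAP is the set of pixels lying on near-shortest paths between soma and
AIS: `d_soma(p) + d_AIS(p) ≤ d_entry + slack` with slack 0.5 µm (about one
axon caliber), where `d_entry` is the soma→AIS geodesic distance. This
excludes both the distal axon and pixels alongside the AIS flank. A
measured GAP shorter than 0.5 µm means the AIS abuts the soma: the cell
is recorded as GAP-less.

**Lengths** are 8-connected geodesic path lengths (√2 diagonal steps)
whose traceback coordinates are moving-average smoothed (window 7 px)
before summing segment norms; raw 8-connected chains overestimate
Euclidean length by up to ~8% (staircase bias), which smoothing removes.
AIS length is the geodesic eccentricity from the proximal entry pixel.
On 100 synthetic cells at default noise this recovers GAP and AIS lengths
with regression slope 1.00–1.01 and RMSE ≈ 0.3 µm, and calibers with mean
error ≈ 0.1 µm (the test suite asserts slope 1 ± 0.05, RMSE ≤ 1 µm,
caliber error ≤ 0.2 µm).

**Accumulation detection** labels supra-threshold pNF-M/H components of at
least 1 µm² overlapping the GAP or AIS by at least 0.5 µm². Overlap is
tested against region interiors eroded by 2 px so PSF bleed across the
GAP/AIS boundary cannot claim the neighbouring compartment; a region too
thin to erode is used as-is. The extent label is `gap_only` or
`gap_and_ais`; an (unexpected) AIS-only overlap maps to `gap_and_ais`
because the extent vocabulary has no separate member for it.

## Electrophysiology

Quality control excludes recordings with series resistance > 10 MΩ, Rs
drift > 20%, or a junction-corrected resting membrane potential (RMP) not
more hyperpolarised than −35 mV; each failure is reason-coded, and missing
metadata fails closed. The liquid junction potential (15 mV, K-gluconate
internal) is subtracted from measured potentials. RMP is the mean over a
≥ 30 s quiescent recording.

Spikes are peaks crossing 0 mV whose preceding 2 ms contain a dV/dt of at
least 10 mV/ms (phase-plane criterion; the refractory period is 2 ms). AP
features come from the first AP of the first spiking sweep: rheobase =
that sweep's command current; threshold = voltage at the last sub-criterion
sample before the steepest point of the upstroke; amplitude = peak −
threshold; half-width at threshold + amplitude/2 with sub-sample
interpolated crossings; delay from step onset to the threshold crossing.
Maximum firing frequency is the largest per-sweep spike count divided by
the 1-s step duration (the max-count sweep, not the rheobase sweep — the
measure is explicitly a maximum).

Firing patterns partition every cell into exactly one of four classes:
**none** (no spikes), **one spike** (≤ 1 per sweep), and on the max-count
sweep **repetitive** (last spike at ≥ 80% of the step and last/first ISI
ratio < 2) versus **adaptive** (everything else). The 80%/2 split is an
operationalisation of the visually defined classes; both knobs are
function parameters.

Voltage-clamp analysis takes the Na current as the most negative value in
the first 10 ms after step onset and the K current as the mean over the
final 10% of the step ("low" potassium read as the steady-state late
current), both at the sweep maximising |Na| and scaled by membrane
capacitance; the Na/K ratio uses magnitudes.

## Statistics

Group comparisons use Kruskal–Wallis (tie-corrected mid-ranks) followed by
Dunn's pairwise z tests on pooled mid-ranks with the standard tie term;
pairwise p values are Holm-adjusted by default (configurable). Frequency
tables (firing-pattern distributions) are compared with two-sided Fisher's
exact tests, Bonferroni-adjusted over the family.

Integrated-density measures additionally pass a **fold-difference gate**:
the ratio of group medians (mutant/control) must reach 3 before a Dunn
call is declared significant. Medians (not means) define the fold to stay
inside the nonparametric framework. The gate is a conjunction — it can
only shrink the significant set. Whether the gate should read "fold ≥ 3"
or "fold ≤ 3" is genuinely ambiguous in the source convention; the default
is ≥ 3 (a stringency requirement), the opposite reading is available via
`direction="le"`, and the report records gate status per row rather than
silently folding it into the p value.

The null calibration of this layer is checked by simulation: over 5,000
null three-group studies (n = 25/group) the rejection rate at α = 0.05
falls within [0.04, 0.06].

## Synthetic data: what it emulates and what it does not

The generator produces the study conditions, not arbitrary fixtures. A
cell is a convex soma (radius 5–8.5 µm), a tubular axon leaving it (GAP
caliber then AIS caliber, constant per segment), 2–4 dendrites, and a
random straight-line neurite network filling a target area fraction of
the field. Channel amplitudes per region emulate the staining pattern:
AnkG confined to the AIS, MAP2 strong in soma/dendrites and weak in the
GAP, panNav concentrated in the AIS with configurable leakage into the
GAP, pNF-M/H moderate along the axon with optional accumulation at 0.65
(≥ 3× the control proximal level of ~0.16), NF-L soma puncta covering an
exact pixel fraction. Per-cell amplitude jitter is ±8%.

Default imaging conditions (chosen once; none are stated in the source
conventions): pixel size 0.2 µm/px (63× regime), Gaussian PSF σ 0.2 µm,
Gaussian read noise 2% of dynamic range per slice (optional Poisson shot
noise off by default), 280×440 px fields, thin Z-stacks whose axial
weights peak at exactly 1 mid-stack so a noiseless MIP equals the 2-D
scene; analysis cohorts use 3 slices (the allowed range is 3–7; the MIP
is the analysis substrate, so slice count only scales noise realisations).
16-bit quantisation applies on write only; the in-memory pipeline is
floating point.

The *control* condition draws GAP length 1–6 µm, GAP caliber 0.9–1.5 µm,
AIS length 15–45 µm, AIS caliber 0.8–1.4 µm, accumulation prevalence 5%.
The *mutant* condition has GAP 5–14 µm, GAP caliber 1.5–2.3 µm, AIS
caliber 1.1–1.8 µm, panNav GAP amplitude 0.3–0.5 (vs 0.08), accumulation
prevalence 50%, NF-L soma fraction 0.15–0.4.

Electrophysiology sweeps are a template-insertion model, not a
conductance model: a subthreshold exponential membrane response (R_in
0.3 GΩ, τ_m 20 ms) plus a closed-form AP waveform
`A·(1−e^(−t/0.3 ms))²·e^(−t/1.5 ms)` (A = 95 mV, peak-normalised) whose
peak lands exactly on each ground-truth spike time. The sigmoidal onset
gives an analytically solvable dV/dt-criterion threshold and half-width
(root-finding on the exact derivative), which the feature tests use as an
independent oracle. Regimes: one spike near 0.15 s; adaptive with
geometrically growing ISIs (ratio 1.25, firing ceasing before 60% of the
step); repetitive with regular ISIs spanning 5–97% of the step. Recording
noise is low-pass-smoothed white noise rescaled to 0.3 mV (2 kHz-filtered
acquisition regime); voltage-clamp families use a fast biexponential
inward transient and a saturating outward current.

**What passing tests do not show about real data:** tubes have constant
caliber and no varicosities except as caliber contrast; backgrounds are
flat (no illumination gradients, debris, or overlapping cells);
annotation seeds are always correct; spike waveforms are stereotyped with
no depolarisation block, bursting, or channel noise. Accuracy numbers
from the synthetic benchmark are therefore upper bounds for real
microscopy, and the pipeline's robustness to annotation error is
untested by design.

## Numerical choices and degenerate inputs

* Pixel coordinates are 0-based, row-major, pixel-centred; areas are
  pixel counts × pixel_size².
* Percentile thresholds use the inverted-CDF (order-statistic) method, so
  a calibrated threshold is always an observed pixel value.
* Background subtraction defaults to the median of pixels outside all
  registered ROIs and clips at zero; an estimate exceeding the image
  maximum logs a warning and yields a zero image.
* Zero-length regions yield reason-coded undefined calibers, never a
  division error; a zero GAP Nav density yields a reason-coded undefined
  ratio.
* Two AIS candidates that touch are merged by a single radius-1 closing
  before counting.
* All randomness flows through `numpy.random.Generator` seeded from
  explicit integers; cohort seeds derive from a `SeedSequence`, and
  identical seeds give bit-identical images, masks, sweeps, and CSVs
  (fixed float formatting on write).

## Known limitations

* Geodesic lengths on strongly curved axons are slightly corner-cut by
  the smoothing window; with the default 6° per 4 µm wiggle the effect is
  ≪ 0.3 µm.
* The percentile-calibration heuristic assumes control fields with
  roughly the structure abundances above; very sparse or very dense
  cultures would need adjusted percentiles.
* `build_report` treats groups independently per measure and does not
  model per-experiment nesting; the per-experiment aggregation helper in
  `nfquant` should be applied first where the design is dot-per-experiment.
* The four-class firing classifier inspects only the max-count sweep;
  mixed regimes across sweeps are resolved in favour of that sweep.
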