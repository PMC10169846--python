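# Methods

## Transport models

The open-pore conductance treats the nanotube as a barrier-free cylinder
of electrolyte: G = 6.02×10²⁶ (μ_K + μ_Cl) c_KCl e π D²/(4L), with D and
L converted to metres internally and the result reported in nS. The
prefactor 6.02×10²⁶ converts a molar concentration to an ion pair density
per m³. Default mobilities are the bulk literature values at 25 °C,
μ_K = 7.62×10⁻⁸ and μ_Cl = 7.91×10⁻⁸ m² V⁻¹ s⁻¹; every default is
overridable through `ElectrolyteState`. The model deliberately omits
access resistance and any free-energy barrier; for a 1.2 nm × 10 nm tube
in 1 M KCl it predicts ≈1.69 nS, above the ≈1.0 nS center measured for
real separated tubes. Both numbers are surfaced (the model value by
`tube_conductance`, the measured operating points in
`analysis/03_transport_physics.py`); the package does not attempt to
reconcile them.

The translocation conductance drop is the volume-exclusion expression
ΔG = 6.02×10²⁶ L⁻¹ [(π/4) d² (μ_K+μ_Cl) c e − μ_K* q*]. The counterion
term defaults to absent — for analytes comparable in width to the pore the
exclusion term dominates — and the function returns the *drop* as a
positive number (a negative return would mean the counterion term
overcompensates). `delta_g_from_blockade` converts a measured fractional
blockade and operating point (I₀, V) to the same quantity, and
`infer_mobility_factor` forms (ΔG_test L_test)/(ΔG_ref L_ref), the
mobility ratio implied by ΔG ∝ (μ_K+μ_Cl)/L; an interval test length
propagates to an interval of factors.

Selectivity follows the Nernst/GHK chain: ΔE = (RT/F) ln(a_cis/a_trans),
V_R = (2T_K − 1)ΔE, SR = T_K/(1 − T_K). Activities use a built-in KCl
mean-activity-coefficient table (0.770 at 0.1 M, 0.604 at 1.0 M, 25 °C)
with log-linear interpolation inside the table and a Davies-equation
fallback outside it. A reversal potential beyond the Nernst limit clips
T_K into (0, 1) with a warning; T_K exactly 0 or 1 is a selectivity
boundary (exclusively anion/cation conducting) and `selectivity_ratio`
raises rather than fabricating an infinite ratio. Temperature defaults to
298.15 K.

The PEG diameter estimate exploits size exclusion: PEG smaller than the
pore threads and blocks strongly, larger PEG is excluded. The estimator
returns the hydrodynamic-diameter bracket of the adjacent calibration
pair with the largest (or first super-threshold) blockade step; a flat
table warns and returns the widest bracket. A helper maps PEG molecular
weight to hydrodynamic diameter via the empirical power law
d_H = 0.0444·MW^0.55 nm (a literature convention, ≈1.2 nm at 400 Da and
≈1.5 nm at 600 Da), provided for building calibration tables only.

## Synthetic recordings

`simulate_trace` generates the study conditions used throughout: open
pore 70 pA (at +80 mV), Poisson arrivals at 150 events/min, rectangular
blockades of depth 0.442, exponential dwells of mean 1 ms, Gaussian noise
of 2 pA RMS, 100 kHz sampling and a 4-pole 5 kHz Bessel corner. Events
are ideal rectangles; the finite rise time in the output comes only from
the filter. Overlapping arrivals are merged in the ground truth, since no
detector can split them; at the default rate×dwell product the overlap
probability is ≈0.25%. The dwell law defaults to exponential (memoryless
escape); a lognormal option parameterized by its arithmetic mean and
log-sd is available. No recording-noise amplitude is stated by the
source recordings; 2 pA RMS at 5 kHz bandwidth is a typical
planar-bilayer figure and is configurable. A single integer seed drives
all draws; identical configurations are bit-identical.

What the generator does *not* emulate: 1/f and capacitive noise, baseline
drift, multi-level or structured events, bilayer rupture. Passing
recovery tests on these traces therefore demonstrates correctness of the
detection chain under stationary Gaussian noise with rectangular events,
not robustness to every artifact of real recordings.

## Event detection and rate correction

Filtering uses a causal Bessel low-pass (`scipy.signal`, magnitude-
normalized so the stated corner is the −3 dB point) initialized in DC
steady state at the first sample, so a constant trace is a fixed point
and synthetic traces have no startup transient.

The baseline estimator starts at the trace median and iterates a
one-sided 3σ clip that discards samples *below* the current level, with
σ the scaled median absolute deviation; blockades therefore cannot drag
I₀ down as long as the open level holds a majority of samples. Traces
that appear dominated by the blocked level trigger an "unreliable"
warning. For traces beyond 2×10⁶ samples the estimator uses a stride
subsample (~10⁶ samples), which leaves the robust statistics unchanged
to well below the reported precision.

Detection opens an event when the current crosses I₀ − kσ (k = 5 by
default) and closes it on recrossing I₀ − (k/2)σ; the half-threshold
hysteresis prevents chatter, standard single-channel practice. Events
shorter than min_dwell (default 0.4 ms, two filter periods at 5 kHz —
the shortest events whose amplitude survives the filter) are discarded.
Per-event blocked current excludes ~80 µs of settling at each edge
(events too short keep their central third), and the blockade fraction
(I₀ − I_b)/I₀ is clipped to [0, 1]. Note the convention: larger
fraction = deeper blockade; scatter axes elsewhere labelled "I/I₀"
correspond to this fractional *blockage*. Positive (conductance-
increase) excursions are ignored.

Two systematic effects of this detector are modeled explicitly rather
than ignored:

1. **Dwell lengthening.** The entry threshold is crossed early on the
   falling edge and the exit threshold late on the rising edge, so the
   measured dwell exceeds the true dwell by a constant computable from
   the filter step response (`hysteresis_dwell_bias`; ≈0.08 ms at the
   default settings).
2. **Left-censoring of the rate.** A min-dwell cutoff on an exponential
   dwell law silently removes the fraction 1 − exp(−t_cut/τ) of events,
   where t_cut is the cutoff expressed in *true* dwell (min_dwell minus
   the dwell bias). `truncation_corrected_rate` estimates τ as the
   detected mean dwell minus min_dwell (exact for a shifted
   exponential) and divides the raw rate by the detected fraction. At
   the study conditions roughly a third of events fall below the 0.4 ms
   cutoff, so the raw detected rate is ≈105/min while the corrected
   rate recovers the true ≈150/min. The correction assumes the
   memoryless dwell law; for other laws the raw rate is the honest
   quantity.

## Discrimination

`fit_two_populations` fits a two-component full-covariance Gaussian
mixture by EM (scikit-learn, k-means++ initialization, 10 seeded
restarts, best likelihood kept) on blockade fraction, optionally with
log-dwell as a second dimension; components are reported ordered by
blockade mean. `separation_report` pools two labelled populations, fits
blind, maps components to populations by the lower-error assignment and
reports the misclassification rate, a histogram overlap coefficient
(square-root binning rule, clamped to 10–50 bins, to keep counting noise
from deflating the overlap of identical samples) and the blockade-mean
separation in pooled-sd units. For equal Gaussians Δ apart the expected
misclassification is the Bayes error Φ(−Δ/2σ), which the tests use as a
closed-form oracle. The component count is fixed at two: the analyte
experiments are pairwise by design.

## Imaging

Spots are local maxima of the temporal-maximum projection exceeding the
robust background (median + k·MAD-σ of all voxels, k = 5), refined by
intensity-weighted centroids in a fixed window; coordinates are 0-based
(row, col) with pixel centers at integers. Per-frame spot intensity is
the background-subtracted window sum (no sub-pixel PSF fitting — the
downstream statistics are coarse intensity/size scatter, not
localization). pixel_size counts above-threshold pixels at the brightest
frame with the same background threshold as detection. Blinking analysis
feeds the intensity series, one sample per frame (20 ms frames in the
emulated movies), through the same hysteresis detector, so dark dwells
are quantized to whole frames and sub-frame events are undetectable by
contract; the baseline logic requires the bright phase to dominate the
duty cycle. Confidence ellipses scale the sample covariance eigenvectors
by √(χ²₂(level)); a singular covariance is flagged degenerate.

## Problem sizes and numerical choices

The recovery analyses use a 300 s recording at 100 kHz (3×10⁷ samples,
~750 events), enough to put Poisson counting error (~3.7%) well inside
the 10% rate band and depth sampling error far inside the 2-point band;
distribution-level checks use 10³–10⁴ draws. Detection cost scales with
the number of threshold crossings, not trace length, via index-array
segmentation. Ties and degenerate inputs: empty event lists summarize to
zeros (not errors), zero-noise traces treat any dip below baseline as an
event, mixture fits reject fewer than 20 events, and equal cis/trans
activities are rejected as non-identifiable everywhere they appear.

## Known limitations

Single static baseline per trace (drift-free by construction of the
generator; a segmented baseline is not implemented). The censoring
correction is exact only for exponential dwells. The cylinder conductance
model overpredicts measured tube conductances (no access resistance).
The imaging stage stops at intensity statistics: the mapping from ion
flux to fluorescence is taken as proportional, with no photophysics
model.
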