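# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `cordflow`.

## Problem setting

After a contusion spinal cord injury (SCI), blood flow around the lesion
organizes into three zones: an **umbra** (epicenter, minimal or abolished
flow), flanking **penumbras** (in this analysis, peaks of *elevated* flow on
each side), and **distal** tissue whose flow is unchanged. `cordflow`
quantifies this organization from two kinds of mid-sagittal ultrasound
recordings of the exposed (post-laminectomy) cord:

* **Non-contrast (SMI-type Doppler)** recordings, reduced to a per-pixel
  *velocity index* (arbitrary units). The index is monotonically related to
  flow velocity but is not calibrated in mm/s; the package deliberately makes
  no absolute-velocity claims.
* **Contrast-harmonic** recordings of a microbubble bolus, reduced to a
  per-pixel first-order washout **decay constant** k (1/s): the faster the
  microbubble signal clears after its peak, the greater the perfusion.

Both maps are reduced to the same one-dimensional object — the spatial
distribution of flow versus signed distance from the injury — on which zone
labeling, temporal tracking and cross-modality comparison operate.

## Contrast arm

Each pixel's time–intensity curve is smoothed with a centered 32-sample
simple moving average (shrinking windows at the edges, so output length
equals input length) and the post-peak segment is fit to

    y(t) = A · exp(−k · (t − t_peak)),

with k ≥ 0 the flow surrogate. Pixels that never received contrast are
assigned k = 0 explicitly: a pixel is unperfused when its smoothed peak
never reaches **0.015 AU** or when the peak arrives at or after **75 s**
into the recording (the boundary is inclusive: peak_time ≥ 75 s
disqualifies). These rules are exhaustive — every pixel is either fit or
explicitly zeroed, and maps contain no NaNs.

Numerical choices for the fit:

* **Log-linear least squares** on log y of the post-peak segment. On a clean
  exponential this is exact; an optional nonlinear refinement
  (`refine=True`) polishes the estimate in the linear domain but is off by
  default.
* The exponential has **no additive offset** — a pure first-order decay.
* Samples at or below a **relative floor** (2 % of the peak) are excluded:
  the log is undefined at 0 and noise dominates there.
* Samples within one filter length (32 samples) of the peak and of the
  series end are excluded: the moving average mixes rise and decay near the
  peak and becomes asymmetric near the end. On an interior segment the
  boxcar multiplies a clean exponential by a constant, so the log-slope is
  unchanged and the fit stays exact. If the guard leaves fewer than 10
  usable samples it is dropped; if still fewer, the fit is marked failed.

Decay maps can be cleaned with a **grayscale opening by a non-flat
structuring element** — a disk of radius 5 px carrying heights
b(s) = h·sqrt(1 − |s|²/r²) with h = 0.05 1/s. Erosion then dilation with
this element is anti-extensive and idempotent and removes isolated
microbubble-aggregate speckle narrower than the disk. Image borders are
reflect-padded. The opening is destructive to genuine structures narrower
than the disk, so the library applies it only on request (the `decaymap`
CLI command defaults it on, matching the intended use on speckled
recordings).

## Non-contrast arm

RGB color-Doppler frames are decoded to the velocity index by
nearest-neighbor lookup against a colormap LUT (Euclidean distance in RGB;
pixels farther than `max_color_distance` from every entry decode to 0). The
scanner's exact colormap is proprietary, so the LUT is an input; a linear
hot-scale default is provided. Grayscale stacks are assumed index-valued and
bypass the decode. Each 5 s recording (195 frames at 39 fps) is reduced to
one map by per-pixel time averaging, which cancels cardiac pulsatility over
whole cycles.

## Spatial distribution

Every ROI pixel gets the minimum Euclidean distance to the user-drawn
two-point injury segment, scaled to mm; the sign is negative on the rostral
side (by convention the left of the image; a flag flips it). The ROI is the
band strictly between the two user-drawn cord-border polylines, excluding
the anterior/posterior spinal arteries.

Pixels are binned into half-open 0.1 mm distance bins **anchored so one bin
edge falls at 0 mm** (required for "closest peak on either side of 0" to be
well defined). Each bin is summarized by the area-adjusted index

    I = v · (A_px / A_ROI),

where v is the mean of "colored" pixels (value strictly above a threshold,
default 0) and A_px/A_ROI the colored fraction of the bin. With threshold 0
this is algebraically the bin mean including zeros, which makes the binned
profile linear in the pixel values and conserves total ROI flow
(Σ I·count = Σ values). Bins with no ROI pixels are flagged missing (NaN),
never silently zero.

The binned curve is smoothed with a centered moving average **1 mm wide**.
1 mm / 0.1 mm = 10 bins is even; the filter uses the nearest odd count,
**11 bins**, so it stays symmetric (config-overridable). Missing bins are
excluded from each local mean; edges use shrinking windows; smoothing never
fills a bin farther than half a window from observed data.

## Zone labeling

On the smoothed post-injury profile:

1. Local maxima with **topographic prominence ≥ 0.03 AU** are detected
   (standard prominence semantics — height above the lowest contour
   isolating the peak; the implementation is oracle-tested against an
   exhaustive computation). The closest qualifying peak on each side of
   0 mm is the rostral/caudal penumbra; a side with none fails labeling.
2. The **umbra** is the argmin strictly between the two penumbras. A run of
   consecutive tied bins resolves to the run center; non-consecutive tied
   runs resolve toward 0 mm (a package decision — the tie is measure-zero on
   real data); a minimum at the search-interval edge is returned but
   flagged.
3. **Prominence** = penumbra flow − umbra flow, per side.
4. **Injury extent** is the distance between the two half-maximum crossings:
   walking from the umbra toward each penumbra, the location where flow
   equals the mean of that penumbra's and the umbra's flow, found by linear
   interpolation between the bracketing bins (sub-bin resolution). No
   crossing (flat profile) fails labeling.
5. **Distal flow** is the mean over bins strictly outside each penumbra; an
   empty side is missing, not zero.

Pre-injury parameters are read from the pre-injury profile at the
post-injury locations; the injury extent has no pre-injury analog and is
left NaN. There is no algorithmic equivalent of the human visual
verification step; a QC plot per recording is emitted instead.

Single points are used for the umbra and penumbras (region-based variants
can be built from the same primitives but are not the default).

## Temporal tracking

Continuous recordings are analyzed frame by frame with the identical
geometry and binning; zones are re-detected on every smoothed frame profile.
Because mislabeled peaks produce physically impossible jump discontinuities,
the location traces are median filtered with a **40-frame** window before
flows are sampled at the filtered locations. A centered even-length median
is ambiguous (the mean of the two middle order statistics lets a glitch
occupying exactly half the window leak through), so even sizes are rounded
up to the next odd count — the same convention as the spatial filter; a
40-frame request uses 41 frames, and any glitch of up to 20 consecutive
frames is removed exactly on a constant-location recording. Distal means
are recomputed per frame by default (`freeze_distal` pins them to the first
labeled frame's penumbra locations).

## Cross-modality comparison

Per subject, Spearman's rank correlation is computed over shared distance
bins (missing bins dropped pairwise, average ranks for ties, two-sided p).
No linearity between velocity index and decay constant is assumed — only
monotonicity. Across subjects the correlations are averaged in Fisher
z-space: tanh(mean(atanh ρ)); |ρ| = 1 is rejected (callers clip with a
warning). A pooled-bins correlation is exposed as an alternative but is not
the default. For the per-bin discrepancy curve the two profiles are first
rescaled to [0, 1] by their own maxima — a package convention, since the
units differ (AU vs 1/s); discrepancies are comparable only under this
normalization. The p-value reported for the averaged correlation is a
one-sample t test on the z-transformed per-subject values, labeled as such
in the CLI output.

## Synthetic phantoms

No recordings ship with the package; every stage is exercised on phantoms
with analytic ground truth.

**Truth profile.** flow(d) = baseline − depth·G(d; 0, σ_u) +
Σ height·G(d; offset, σ_p), Gaussians of unit peak. Defaults: baseline
0.30 AU, umbra depth 0.25 AU and σ_u = 0.5 mm, penumbra offsets ∓1.5 mm,
heights 0.15 AU, σ_p = 0.4 mm — a moderate-to-severe injury shape with
umbra flow ≈ 0.05 AU and distinct penumbra peaks. Because the dip and bumps
overlap, the true extrema sit slightly off the nominal centers;
`zone_locations` finds them on a 1 µm grid. The 1 mm averaging filter is
part of the labeling procedure, and its width is comparable to σ_p, so the
procedure's estimand is the extremum of the *filtered* distribution, which
sits ≈ 0.06 mm outside the raw one under the defaults; recoverability is
therefore measured against `zone_locations(smoothing_mm=1.1)` (11 bins ×
0.1 mm).

**Scene.** A 96 × 256 px field at 0.05 mm/px (12.8 mm span), horizontal cord
borders, a 7-row axial artery band, perpendicular sulcal-like branches every
0.4 mm with 0.1 mm jitter, and a 25 %-dense capillary-like scatter. Every
column carries the same number of non-axial vessel pixels (branch columns
arrange them contiguously, scatter columns randomly), so the area-adjustment
term is spatially uniform by construction and noiseless recordings recover
the truth to within a bin. Real recordings do not have this property —
variable per-bin vessel area is exactly what the area-adjusted index and the
1 mm filter exist to absorb — so passing recovery tests bound discretization
and noise behavior, not anatomic variability. The injury line is vertical at
the image center.

**Non-contrast rendering.** Per-frame pixel value = true flow × raised
cardiac sinusoid (1 + a·sin 2πft, mean exactly 1; a = 0.2, f = 5 Hz,
rat-like) + additive Gaussian noise (σ = 0.03 AU on vessel pixels, clipped
at 0) with Bernoulli dropout (p = 0.1) emulating transient Doppler loss.
Off-vessel pixels are exactly zero. No dropout statistics are published for
SMI-type recordings; these defaults are stated, not calibrated.

**Contrast rendering.** Each vessel pixel follows a bolus: zero before
arrival (5 s), linear ramp to a 0.5 AU peak over 10 s (the rise shape is
inert to the post-peak fit), then exponential washout with
k = 0.02 (1/s)/AU × local flow. The proportionality constant is a modeling
choice — the two modalities are only claimed to be monotonically related —
and puts k in the low 10⁻² 1/s range over a 150 s recording. Perfused-pixel
noise is Gaussian (σ = 0.01 AU, clipped at 0); non-perfused pixels carry
uniform background strictly below the 0.015 AU threshold. Optional speckle
injects ≤ 2 px-radius blobs with artificially high k to exercise the
opening stage. No acoustic wave propagation, speckle physics or beam
modeling is attempted.

**Tube phantom.** A straight tube (diameter 408 or 506 µm at 0.05 mm/px)
rendered at known velocities with index i(v) = v/(v + 20 mm/s) — a
saturating, strictly monotone map, so a noiseless measurement gives
Spearman ρ = 1 by construction and the noisy Monte-Carlo property is a
statement about the noise model, not about real Doppler physics. The
diameter enters only through geometry.

All generators are bitwise deterministic for a fixed seed.

## Problem sizes used in the checks

The automated checks run: washout recovery on 500 pixels (150 s at 39 fps);
zone recovery on 50 seeded scenes (96 × 256 px, 195-frame renders), clean
and at default noise; morphology oracle equivalence on 50 random 32 × 32
images; the area-adjustment identity on 1000 random bins; cross-modality
agreement on 5 subjects (64 × 192 px scenes, full 150 s contrast renders);
and the tube phantom at 8 velocities. Decay maps are fit in pixel chunks
(default 2048) to bound memory on long recordings.

## Known limitations

* The velocity index is relative; nothing here yields mm/s.
* The color decode depends on a user-supplied LUT; wrong LUTs silently
  produce wrong (though often still monotone) indices.
* The exponential washout model ignores recirculation and any additive
  baseline; late secondary boluses would bias k.
* The prominence threshold (0.03 AU) is an operating point chosen for
  velocity-index profiles; decay-constant profiles have different scales
  and may need a different threshold (`--min-prominence`).
* Axial-plane (transverse) profiles are out of scope.
* Group-level statistics (repeated-measures ANOVA and post-hoc comparisons
  across injury severities) are not implemented; the zone tables are tidy
  exports meant for external statistical tools.
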