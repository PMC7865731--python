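# Methods

This note records the models, parameter choices and numerical decisions
behind punctakit, and what the synthetic-scene tests do and do not show
about real data.

## Image model and conventions

All images are float64 arrays indexed `(channel, frame, row, col)`,
0-based, origin top-left, pixel centers at integer coordinates. Spatial
calibration is a pixel pitch in nm (default scenes use 160 nm/px, typical
of EMCCD TIRF at 100×); time-lapses carry a frame interval in seconds.
Explicit calibration arguments always override file metadata.

Two-channel alignment is a pure translation estimated from the peak of the
circular cross-correlation of mean-subtracted images, refined to subpixel
by a separable three-point quadratic fit. Rotation and scale are out of
scope. The reported shift is the displacement of the moving channel
relative to the reference; the correction applied is its negation, with
bilinear interpolation. Featureless (constant) channels make the problem
undetermined and raise an error rather than returning a default.

## Spot detection (find maxima)

The detector is the algorithmic core. Pixels are processed in descending
intensity order and merged with a union-find structure, which is exactly
descending flood-fill region growing: each region remembers its peak, and
when two regions meet, the weaker peak dies at that saddle level. Its
prominence is peak height minus saddle level (the global maximum is
referenced to the image minimum), and a punctum is reported when its
prominence strictly exceeds the noise tolerance. Because prominences are
computed once and tolerance is only a filter, raising the tolerance can
never increase the detection count. Plateaus (exactly equal neighbours)
merge silently and are reported at their centroid; isolated peaks are
refined by a separable 3×3 quadratic fit clamped to ±0.5 px. Maxima within
3 px of the border are dropped, and a region mask can restrict detections
to the cell.

The tolerance has no universally correct value; the scale-free default is
5× the robust background sd (median absolute deviation × 1.4826), computed
on an off-cell region when one is supplied. An optional background
subtraction before detection is deliberately not applied by default.

Measured on synthetic scenes (σ = 1.2 px spots, amplitude 200 over
background 50, Poisson + read noise), the subpixel localization error is
≈ 0.2 px median, and the noiseless quadratic-fit bias is < 0.04 px.

## ΔF/S and co-localization

Pixel membership for the circle (r ≤ 1.5 px) and annulus (1.5 < r ≤ 2.5 px)
is decided by the pixel-center distance from the possibly-subpixel site
center; the annulus inner diameter equals the circle diameter (contiguous
annulus), the standard circle–annulus design. ΔF = c − a and S = a − bg
hold exactly by construction; the score ΔF/S is only defined for S > 0 —
undefined sites are excluded and counted, never imputed. The per-cell
score requires at least seven valid sites (overridable). The score is
invariant to affine intensity rescaling applied to the whole frame.

Co-localization automates an observer call: a reference punctum counts as
co-localized when a query punctum center lies within 1 px (0.16 µm) of its
center, searched within an 11 µm² square cutout (21×21 px at 160 nm/px).
For independent channels at density d this converges to the Poisson chance
rate 100·(1 − exp(−d·π·r²)), ~3.2 % at d = 0.4 µm⁻².

## Dynamics

Whole-cell traces are mean cell-mask intensity minus mean off-cell
background per frame, normalized to the mean over all pre-stimulation
frames (≥ 5 required), time axis shifted so stimulation is t = 0.
Normalization is flagged undefined (not raised) when the baseline is ≤ 0.
Bleach correction is off by default; a linear pre-stimulation detrend can
be added upstream if needed.

Endocytosis events are rapid losses of site ΔF: the event frame is the
first frame at or below (1 − threshold) × trailing 5-frame median, with
the fall from baseline taking at most 2 frames, persisting at least 3
frames (rejects blinking), and the baseline median retaining at least 20 %
of the trace's 95th-percentile amplitude. The last gate exists because a
purely relative drop rule otherwise fires on the faint tail of any slow
monotone decline, where a 50 % change is meaningless; with it, the
false-positive rate on event-free noisy movies is ≤ 0.02 per trace while
programmed step losses are recovered with recall and precision ≥ 0.9 and
±1 frame timing. The 50 % default matches the scale of stimulus responses
in membrane-trafficking data (whole-cell fluorescence roughly halving);
both threshold and persistence are configurable.

Density before/after stimulation averages per-frame cluster densities over
the last 5 frames before the stimulation and the last 5 frames of the
movie, so the loss transition belongs to neither window.

## Tracking

Linking is mutual-nearest-neighbour greedy: all candidate pairs within the
5 px cutoff (the tracking-plugin "pixel size cut off" read as a gating
radius — the only reading consistent with units) are accepted in ascending
distance order, each detection at most once. No gap closing. Tracks
shorter than 3 points are discarded to suppress spurious one-frame links.
Displacement histograms pool per-step lengths; per-track total path length
is also emitted because published histograms are ambiguous between the
two, and the count of minimum-displacement tracks reports the lowest bin
of the per-track histogram.

For Brownian motion with diffusion coefficient D and interval Δt, per-axis
steps are N(0, 2DΔt), so step lengths are Rayleigh with mean √(πDΔt)
(0.056 µm at D = 0.01 µm²/s, Δt = 0.1 s) and pooled speed √(πDΔt)/Δt.
These laws are verified by linking the generator's own per-frame positions:
that isolates the linker and the statistics, which is the point of the
check. Positions localized from images instead add an error variance of
roughly 2σ_loc² per axis per step, inflating the measured step scale
(≈ 8 % in pooled speed at high SNR) and strictly breaking the Rayleigh
law at large n — an inherent property of localization, not of the linker.

## PLA counting

The chain is projection → autofluorescence subtraction (clipped at 0) →
white top-hat → cell definition → thresholded counting. The top-hat disc
has *diameter* 10 px (an exact even-diameter disc footprint, not the usual
odd radius-5 disc), so 10 px objects are the removal boundary; "over 10
pixels" could alternatively mean area in px², which is noted but not
implemented. Nuclei are segmented by Otsu threshold, hole filling,
8-connected labelling and a 50 px² minimum area (the source pipelines give
no segmentation detail); cell regions are every pixel within 65 px
Euclidean distance of a nucleus, assigned to the nearest nucleus, and
signals whose centroid falls outside every region are removed. Counting
takes 8-connected components of pixels above 0.08 on a min–max-normalized
[0, 1] image; auto-normalization is opt-in because silently rescaling an
already-calibrated image would change the threshold's meaning.

## Synthetic scenes

The generators produce every input the pipeline consumes, with ground
truth, and their defaults define the conditions under which the package's
claims are tested:

- **Punctate fields**: isotropic Gaussian PSF, σ = 1.2 px (≈ 190 nm at
  160 nm/px — diffraction-limited); amplitude 200 on membrane background
  40 inside an elliptical cell, 8 off-cell; Poisson shot noise plus
  Gaussian read noise sd 2 (peak SNR ≈ 12). Spot density is defined over
  the cell mask (0.4 µm⁻² default, the scale of cluster densities in
  membrane-trafficking data); the spot count is Poisson(density × cell
  area). A `coloc_fraction` subset of channel-1 spots is duplicated into
  channel 2 at identical centers and channel 2 is topped up to the same
  density with independent spots; an exclusion radius instead produces
  anti-localized scenes. Equal seeds give bit-identical scenes.
- **Time-lapses**: Brownian steps are independent per-axis Gaussians with
  variance 2DΔt (no motion blur); steps that would leave the cell are
  re-drawn (a reflecting boundary in effect). Internalization removes a
  round(fraction × n) subset's amplitude linearly over 1 or 2 frames,
  starting 1–8 frames after the stimulation frame; photobleaching is not
  modelled.
- **PLA scenes**: non-overlapping nuclei discs on a jittered grid; each
  cell receives Poisson(mean) dots (σ = 0.8 px, amplitude 200) within
  65 px of its nucleus, dart-thrown with a 5 px minimum mutual separation.
  The separation makes every programmed dot a resolvable connected
  component, because the fixed counting rule cannot split coalesced dots;
  the ground truth is therefore the number of countable amplified signals,
  as in real PLA where merged signals are counted once.
- **Cq tables**: treated target Cq shifted by −log₂(fold), reference genes
  unshifted, Gaussian replicate noise (default sd 0.2 cycles, triplicates).

What passing these tests shows is that each quantification stage recovers
what the model scene encodes at realistic SNR. What they do not show:
robustness to structured backgrounds, uneven illumination, photobleaching,
3-D PSFs, cell-shape irregularity, or segmentation of touching cells —
real data needs the usual visual sanity checks.

## Problem sizes

The shipped tests use fields of 80–240 px, 30–100-frame movies, 20 seeds
for sign/recovery statistics, 4 × 30-cell PLA scenes per mean, ~12 000
linked Brownian steps, and 500 simulated tables per qPCR fold; these sizes
keep each statistical check's sampling error several times smaller than
the tolerance it is tested against.

## Known limitations

- Detection merges sub-diffraction spot pairs (≲ 3 px apart) into single
  maxima, so densities read ~10–15 % low at 0.4 µm⁻²; match statistics use
  a neighbourhood criterion (any detection within the radius) so that this
  physical ambiguity is not charged to the detector.
- Alignment handles translation only.
- ΔF vs S saturation (one-site binding) is observed in real data but no
  curve is fitted here; the score is only meaningful at small S.
- The minimum-referenced qPCR variant interprets "minimum" per gene (not
  per plate); the alternative reading would change normalization constants
  but not treated/untreated folds.
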