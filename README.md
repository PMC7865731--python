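# punctakit

Quantification of punctate membrane fluorescence for trafficking studies:
the toolchain a lab would use to ask whether a membrane transporter sits in
caveolin-coated clusters and disappears from the plasma membrane when its
substrate arrives.

It is aimed at microscopists analysing TIRF (total internal reflection
fluorescence) movies of labelled membrane proteins, PLA (proximity ligation
assay) micrographs, and the qPCR tables that accompany such experiments.
All image inputs are calibrated TIFF stacks (e.g. 160 nm/pixel); every
quantification stage can also be exercised end-to-end on synthetic scenes
with known ground truth, generated by the package itself.

## What it computes

**Spot detection and cluster density.** Diffraction-limited puncta are
detected with find-maxima semantics: a local maximum is kept when its
height above the highest saddle connecting it to any stronger maximum
exceeds a noise tolerance (descending flood-fill region growing), with
plateau merging and 3×3 quadratic subpixel refinement. Cluster density is
puncta per µm² of cell-mask area.

**ΔF/S binding score.** At each punctum site, with mean fluorescence *c*
in a central circle (3 px ≈ 0.5 µm diameter), *a* in a surrounding annulus
(5 px ≈ 0.8 µm outer diameter) and *bg* in an off-cell region:

    ΔF = c − a        (site-specific fluorescence)
    S  = a − bg       (local unbound fluorescence)

ΔF/S measures binding at the site independently of expression level —
positive means enrichment, negative means exclusion. A per-cell score
averages at least seven well-separated sites. Co-localization between two
channels is the percentage of reference puncta whose nearest query punctum
lies within one pixel.

**Dynamics.** Whole-cell traces (background-corrected, normalized to the
pre-stimulation baseline, stimulation at t = 0), endocytosis events
(rapid ≥50 % loss of site ΔF within one or two frames that persists), and
cluster-density ratios before/after stimulation.

**Tracking.** Frame-to-frame linking gated at a 5 px step cutoff with
greedy ascending-distance assignment; per-step displacement histograms and
per-track speeds (µm/s), pooled mean ± SEM.

**PLA counting.** Maximum-intensity projection, autofluorescence
subtraction, white top-hat (10 px disc) cleaning, DAPI nuclei expanded by
65 px into cell regions, connected components above intensity 0.08 (on
[0, 1]-normalized images) counted per cell; signals per cell = total ÷
number of cells.

**qPCR relative quantification.** With A/B the mean target-gene Cq
(untreated/treated) and F/G the same for the reference gene:
2^−ΔΔCt = 2^((A−B)−(F−G)); efficiency-corrected (Pfaffl) fold
E_t^(A−B) / E_r^(F−G) with default efficiencies 1.85 (target) and 1.97
(reference); and a minimum-referenced variant expressing each gene
relative to its lowest-mean-Cq reaction.

## Worked example

```python
import punctakit as pk

params = pk.SceneParams(field_size_px=(128, 128), density_per_um2=0.4,
                        coloc_fraction=0.5, seed=42)
stack, masks, truth = pk.gen_two_channel_frame(params)

green = pk.find_maxima(stack.frame(0, 0), noise_tolerance=30, within=masks["cell"])
red = pk.find_maxima(stack.frame(1, 0), noise_tolerance=30, within=masks["cell"])
print(f"detected {len(green)} green and {len(red)} red puncta "
      f"({len(truth.spot_positions)} simulated)")

density = pk.cluster_density(green, masks["cell"], stack.pixel_size_nm)
print(f"cluster density: {density:.3f} per um^2 (true 0.400)")

pct = pk.colocalization_percent(green, red)
print(f"co-localization: {pct:.1f}% (true 50%)")

score = pk.cell_binding_score(stack.frame(1, 0), truth.positions_array(0),
                              masks["background"])
print(f"mean dF/S at spot sites: {score.mean_score:.3f} "
      f"({score.n_sites - score.n_undefined} sites)")
```

prints

```
detected 102 green and 95 red puncta (121 simulated)
cluster density: 0.364 per um^2 (true 0.400)
co-localization: 45.1% (true 50%)
mean dF/S at spot sites: 0.433 (121 sites)
```

The detected density sits below the simulated 0.4 µm⁻² because sub-
diffraction spot pairs merge into single maxima; the co-localization
estimate recovers the programmed 50 % fraction minus the few detections
displaced by noise, and the positive ΔF/S reflects that half the sites
carry a channel-2 spot. The same API is exposed as a CLI
(`punctakit simulate|detect|dfs|coloc|trace|events|track|pla|qpcr`).

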