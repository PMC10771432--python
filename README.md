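# cordflow

Spatial and temporal analysis of spinal cord blood flow from contrast and
non-contrast ultrasound.

After a contusion spinal cord injury, blood flow reorganizes into an
**umbra** (epicenter with minimal flow), two flanking **penumbras** (peaks of
elevated flow) and unchanged **distal** tissue. `cordflow` turns ultrasound
recordings of the exposed cord into quantitative descriptions of this
organization. It is written for researchers processing mid-sagittal
recordings of rodent (or, eventually, intraoperative human) spinal cords:

* **Contrast-harmonic recordings** — each pixel's time–intensity curve is
  smoothed (32-sample moving average) and its post-peak segment fit to a
  first-order exponential washout `y(t) = A·exp(−k·(t − t_peak))`; the decay
  constant k (1/s) is the perfusion surrogate. Pixels that never reach
  0.015 AU, or peak at or after 75 s, are assigned 0 1/s. Maps can be cleaned
  of microbubble-aggregate speckle with a grayscale opening by a non-flat
  offset-disk structuring element (radius 5 px, height 0.05 1/s).
* **Non-contrast (SMI-type Doppler) recordings** — RGB color-Doppler frames
  are decoded to a velocity index (AU) against a colormap LUT and
  time-averaged over each 5 s clip.
* Both map types are reduced to the **spatial distribution of flow versus
  signed distance from the injury line**: each ROI pixel's minimum Euclidean
  distance to the injury segment (rostral negative), binned at 0.1 mm, each
  bin summarized by the area-adjusted index `I = v · A_px / A_ROI`, and the
  curve smoothed with a 1 mm moving average.
* **Zone labeling** — penumbras are the closest peaks on either side of 0 mm
  with topographic prominence ≥ 0.03 AU; the umbra is the minimum between
  them (plateau ties resolve to the run center); penumbra prominence is
  penumbra minus umbra flow; the injury extent is the distance between the
  half-maximum crossings flanking the umbra; distal flow is the mean outside
  the penumbras.
* **Temporal tracking** — continuous recordings are labeled frame by frame,
  and zone locations are median filtered (40-frame window) before flows are
  sampled.
* **Cross-modality comparison** — per-subject Spearman rank correlation over
  distance bins, averaged across subjects via Fisher's z transform.

Because such recordings are not freely distributable, the package includes a
**synthetic phantom generator** (`cordflow.synthetic`) that renders both
modalities from an analytic ground-truth flow profile — a Gaussian umbra dip
with Gaussian penumbra bumps on a flat baseline — plus a benchtop flow-tube
phantom. Every pipeline stage is tested against these phantoms.

## Worked example

```python
import cordflow as cf
from cordflow.synthetic import make_scene, render_noncontrast, render_contrast

scene = make_scene(seed=1)                      # 12.8 mm phantom cord, known truth
stack = render_noncontrast(scene, seed=1)       # 5 s SMI-like recording, 39 fps
flow, profile = cf.noncontrast_profile(stack, scene.geometry)
labels = cf.label_zones(profile)

print(f"umbra:    {labels.umbra_location:+.2f} mm  flow {labels.umbra_flow:.3f} AU")
print(f"penumbra: {labels.rostral_penumbra_location:+.2f} / "
      f"{labels.caudal_penumbra_location:+.2f} mm  "
      f"prominence {labels.rostral_prominence:.3f} / {labels.caudal_prominence:.3f} AU")
print(f"distal:   {labels.rostral_distal_flow:.3f} / {labels.caudal_distal_flow:.3f} AU")
print(f"extent:   {labels.injury_extent:.2f} mm")

contrast = render_contrast(scene, seed=2)       # 150 s microbubble bolus
kmap, kprofile = cf.contrast_profile(contrast, scene.geometry)
rho = cf.spearman_profiles(profile, kprofile)
print(f"modality agreement: Spearman rho = {rho.rho:.2f} over {rho.n_bins} bins")
```

prints

```
umbra:    +0.05 mm  flow 0.029 AU
penumbra: -1.55 / +1.65 mm  prominence 0.097 / 0.097 AU
distal:   0.097 / 0.097 AU
extent:   1.54 mm
modality agreement: Spearman rho = 0.87 over 128 bins
```

The phantom's injury sits at 0 mm with penumbra peaks near ±1.6 mm (after
the 1 mm profile filter): the labeled umbra lands within one 0.1 mm bin of
it, the penumbras at the filtered profile's true peaks, and flow in the
umbra (0.029 AU) is far below the distal baseline (0.097 AU). The two
independently rendered modalities — velocity index and washout decay
constant — rank-correlate at ρ = 0.87 across distance bins at the default
noise level.

The same steps are available from a shell:

```sh
cordflow simulate --seed 1 --out sim/
cordflow velmap   --stack sim/noncontrast.tif --out sim/velmap.tif
cordflow decaymap --stack sim/contrast.tif    --out sim/decay.tif
cordflow profile  --map sim/velmap.tif --geometry sim/geometry.json --out sim/profile.csv
cordflow zones    --profile sim/profile.csv --out sim/zones.json --qc-plot sim/zones.png
cordflow track    --stack sim/noncontrast.tif --geometry sim/geometry.json --out sim/track.csv
cordflow compare  --a sim/profile.csv --b sim/profile_contrast.csv --out sim/compare.json
```

## Layout

| module | contents |
| --- | --- |
| `cordflow.synthetic` | phantom scenes, bolus kinetics, tube phantom |
| `cordflow.noncontrast` | LUT color decode, time averaging |
| `cordflow.contrast` | TIC smoothing, washout fit, decay maps, opening |
| `cordflow.profile` | signed distances, ROI, area-adjusted binning, smoothing |
| `cordflow.zones` | peak/prominence detection, umbra, extent, distal means |
| `cordflow.temporal` | frame-by-frame tracking, median location filter |
| `cordflow.compare` | Spearman per subject, Fisher-z averaging, discrepancy |
| `cordflow.io` / `cordflow.cli` | TIFF/JSON/CSV formats and the `cordflow` CLI |

See `docs/methods.md` for the models, parameter defaults and numerical
choices, and for what the synthetic phantoms do and do not establish about
real recordings.
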