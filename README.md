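# axoshed

Quantitative live-imaging analysis of axonal mitochondria transport, the
shedding of mitochondria and mitophagy machinery out of axons, and
axolemmal protrusion (exopher/evulsion) dynamics in the optic nerve —
with a ground-truthed synthetic scene generator for validating every step.

## Who this is for

Labs imaging retinal ganglion cell (RGC) axons in the optic nerve (or any
nerve with roughly parallel axons) who need reproducible, scriptable
versions of four common measurements:

1. **Kymograph transport analysis.** A time series (1 min at 1 Hz, single
   plane) is registered for drift, the nerve contour is traced and divided
   into 0.9–1.8 µm parallel swaths, and a kymograph is extracted per swath.
   Objects (mitochondria, OPTN or LC3b puncta) are detected per time row,
   linked into traces, and classified by their net velocity
   v = (s_last − s_first)/(t_last − t_first): an object is **moving** when
   |v| ≥ 0.1 µm/s (boundary inclusive), anterograde when v > 0 (eye→brain),
   retrograde when v < 0, otherwise stationary. In healthy axons roughly
   half of mitochondria are stationary and a quarter move in each
   direction, at mean speeds near 0.63 (anterograde) and 0.78 µm/s
   (retrograde).
2. **Trace co-localization.** Traces from two channels (e.g. mitochondria
   and the mitophagy receptor OPTN) are matched one-to-one when they stay
   within 0.5 µm for at least half of the reference trace's frames; the
   co-localized/solo split is stratified by movement class.
3. **Outside-axon volumetry.** In z-stacks (1 µm steps) the diffuse
   cytoplasmic EGFP-LC3b signal provides an axon mask; for each signal
   channel the percent of supra-threshold volume outside the mask is
   computed, and the extra-axonal part is split between a shell at the
   nerve surface and the parenchyma, with an OLS trend across animals.
4. **Protrusion morphodynamics.** Asymmetric axolemmal protrusions are
   detected along sparse axons (linear density per 100 µm, mitochondria
   content), 3-D objects are scored by Wadell sphericity
   Ψ = π^(1/3)(6V)^(2/3)/A, and single dystrophies are tracked over
   repetitive z-scans: minimum bud–axon boundary distance,
   baseline-normalized loading curves, event kind (swelling / loading /
   pinching-off / detached), pinch-off time, and a conservative persistence
   bound (survivors × span / tracked).

Every measurement is validated against a synthetic generator
(`axoshed.synthetic`) that emulates the imaging: Gaussian PSF,
Poisson + Gaussian noise (SNR ≈ 5 at spot peaks), frame-to-frame drift,
state-dependent channel coupling, controlled extra-axonal volume
fractions, and scripted protrusion events — all with exhaustive ground
truth.

## Worked example

Run the full simulated study (2 synthetic animals by default):

```python
from axoshed.pipeline import run_pipeline
report = run_pipeline({"seed": 5})
print(report["transport"]["pct_stationary"])
print(report["coloc"]["stationary"])
print(report["volumetry"]["pct_outside_mito_mean"])
print(report["dystrophy"])
```

prints (abridged):

```
{'mean': 47.653904, 'sem': 3.734985, 'n_animals': 2}
{'frac_coloc': 0.647482, 'n_coloc': 90, 'n_total': 139}
15.981081
{'planted': 5, 'detected': 5, 'density_per_100um': 0.5,
 'mito_fraction_pct': 60.0, 'event_kind': 'pinching_off',
 'event_pinch_time_s': 180.0, 'true_pinch_time_s': 180.0}
```

Reading this: the pipeline measured 47.7 ± 3.7 % stationary mitochondria
(generative truth 50 %), 65 % of stationary mitochondria carrying OPTN
(truth 60 %), 16.0 % of mitochondrial signal outside the axon mask (truth
≈ 15 %), and it found all five planted protrusions (0.5 per 100 µm, 60 %
mito-positive) and called the pinch-off event at the correct 30-s
interval. Percentages are computed per animal first and averaged across
animals (N = animals), as is standard for nested imaging data.

The same stages are scriptable from the shell:

```bash
axoshed simulate --out scene/
axoshed kymo --stack scene/timelapse.ome.tif --out kymos/
axoshed transport --kymo-dir kymos/ --out traces.csv
axoshed volume --stack scene/zstack.ome.tif --out volume.json
axoshed dystrophy --out event.json
axoshed report --out report/
```

## Layout

- `axoshed.config` — `SceneConfig`, YAML I/O, validation
- `axoshed.stacks` — calibrated `FrameStack`/`VolumeStack`, OME-TIFF I/O
- `axoshed.synthetic` — scene generator with ground truth
- `axoshed.kymo` — registration, contour, swaths, kymograph extraction
- `axoshed.transport` — detection, linking, classification, co-localization
- `axoshed.volumetry` — axon mask, % outside, surface/parenchyma split
- `axoshed.dystrophy` — segmentation, sphericity, protrusions, event tracking
- `axoshed.stats` — per-animal aggregation, t-test / ANOVA + Tukey
- `axoshed.pipeline` / `axoshed.cli` — orchestration and CLI

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
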