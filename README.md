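# stedview

Quantification of nanoscale synaptic protein localization from two-color
STED / confocal imaging, and of inhibitory synaptic transmission from
whole-cell recordings — with a ground-truthed synthetic-data generator so
the entire measurement chain can be validated end to end.

## The problem

Synapses align presynaptic release machinery with postsynaptic receptor
scaffolds across a ~20 nm cleft. With STED microscopy (~50 nm lateral
resolution) this trans-synaptic architecture can be measured directly at
*side-view synapses*: synapses imaged edge-on, where the postsynaptic
scaffold (PSD-95 at excitatory, Gephyrin at inhibitory synapses) appears
as a bar at the edge of the presynaptic vesicle cloud (Synaptophysin,
confocal). The typical readouts are:

- **Peak-to-peak distance** `d`: for each side-view synapse, a 1 µm × 250 nm
  intensity profile is sampled perpendicular to the scaffold bar through
  its center. After a 5-pixel rolling average, the scaffold peak position
  `x_s` is the profile maximum of the scaffold channel, and the
  protein-of-interest peak `x_p` is the profile maximum within ±100 nm of
  `x_s`. The signed distance `d = x_p − x_s` is reported with + toward the
  presynapse.
- **Average profiles**: per-synapse profiles aligned to the scaffold peak
  and averaged (mean ± SEM vs position), compared across genotypes by
  two-way ANOVA (genotype × position) on a 200 nm window about the peak.
- **Knockout-referenced positivity**: a synapse is positive for the
  protein when its peak intensity exceeds
  `mean(KO) + 3·SD(KO)` of knockout-reference synapses, assessed per
  culture (under a Gaussian null this fires at `P(Z > 3) ≈ 0.135 %`).
- **Puncta statistics**: synapse density, intensity and size from
  automatic 2D segmentation of the vesicle marker with an inclusive
  0.4–2 µm² size filter.
- **IPSC metrics**: evoked-current amplitude (baseline-to-peak), 20–80 %
  rise time, 100–33 % decay time, and paired-pulse ratios
  `PPR = A₂/A₁` across interstimulus intervals, with the tail of the
  first response removed by exponential extrapolation at short intervals.

Raw data of this kind are rarely deposited, so `stedview` ships a
first-class synthetic generator: vesicle clouds, scaffold bars and
cleft-offset protein bands with per-channel PSF blur and Poisson+Gaussian
noise, plus double-exponential IPSC traces — all with known ground truth.
Validation is parameter *recovery*: simulate with known offsets, measure
blindly through the full pipeline, compare.

## Worked example

```python
import stedview as sv

# simulate one high-SNR side-view synapse with a 40 nm trans-synaptic offset
spec = sv.grid_scene_spec([40.0], seed=8, noise="poisson+gaussian")
scene = sv.render_scene(spec)

rois = sv.detect_sideview_candidates(
    scene.channel("scaffold"), scene.channel("vesicle"), spec.pixel_size
)
profile = sv.smooth_profile(sv.extract_profile(scene.images, rois[0], spec.pixel_size), 5)
m = sv.measure_apposition(profile, "scaffold", "protein")

calls = sv.classify_positive([m.protein_peak_intensity], ["culture1"],
                             {"culture1": [210.0, 190.0, 205.0, 188.0, 207.0]})

tr = sv.generate_trace(sv.IPSCParams(amplitude=1500.0, stimulus_times=(50.0, 100.0),
                                     ppr_true=0.85, noise_sigma=10.0), seed=8)
met = sv.measure_ipsc(tr)
```

prints (via the obvious `print` statements):

```
true offset      : 40 nm
measured distance: 40 nm (scaffold peak at 0 nm)
protein peak     : 616 counts, truncated=False
positivity threshold: 230.7 counts -> positive=True
IPSC amplitude 1507 pA, rise 20-80% 0.94 ms, decay 100-33% 11.47 ms
paired-pulse ratio (50 ms): 0.858
```

The automatic detector found the one side-view synapse, the profile
measurement recovered the simulated 40 nm offset exactly (20 nm pixels),
the synapse's protein peak cleared the knockout-referenced 3-SD threshold,
and the trace metrics recovered the simulated amplitude, kinetics and
paired-pulse ratio.

## Command line

`stedview` exposes the pipeline stages as subcommands over a YAML config
with one master seed:

```bash
stedview simulate --seed 1 --out-dir run    # scenes (OME-TIFF + truth CSV) and traces
stedview segment  --out-dir run             # puncta density / intensity / size
stedview profile  --out-dir run             # side-view distances + average profiles
stedview classify --out-dir run             # KO-referenced positivity
stedview stats    --out-dir run             # gated tests + profile ANOVA
stedview ephys    --out-dir run             # IPSC metrics and PPR
stedview all --seed 1 --out-dir run         # everything, with a run manifest
```

All outputs are CSV/JSON; a `manifest.json` records the full config,
seed and versions, and re-running with the same seed reproduces every
CSV byte for byte.

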