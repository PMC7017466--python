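# earset

X-ray computed tomography turns grain-set phenotyping of cereal ears —
counting and weighing every seed, including the shrivelled, hollow ones a
threshing machine loses — into an image-analysis problem. `earset`
implements that pipeline end to end for wheat-like ears:

- **phantoms** — synthetic reconstructed ear volumes (rachis, seeds with
  crease cavities / germ notches / shrivel, awns, noise) with voxel-exact
  ground truth, so every downstream stage is testable without scan data;
- **recon** — a simplified parallel-beam CT stage: Beer–Lambert forward
  projection and filtered back projection with per-projection detection
  of the unattenuated intensity I₀, which makes the reconstructed
  absorption invariant to primary-beam drift, and a linear 16-bit grey
  mapping whose scale travels in a JSON sidecar;
- **segment** — automated ear separation, grain/chaff separation by a
  three-class intensity split with an absolute grain-absorption floor,
  and marker-watershed splitting of touching seeds;
- **traits** — the per-grain record: voxel count, volume, virtual weight,
  absorption-weighted centre of mass, mean attenuation, 3D aspect
  (spherical) ratio `r_eq / r_mcs` (equal-volume-sphere radius over
  minimum-covering-sphere radius; 1 = sphere, → 0 = thin rod),
  surface-voxel count, surface/volume, and the minimal directional width
  feeding the **virtual 2 mm sieve**;
- **earprofile** — seed ordering along the ear axis (bottom = 0,
  top = 1), seed-weight-versus-position profiles, per-ear totals, and
  r² evaluation against hand-threshed reference weights and counts.

The virtual weight is `k · Σ(absorption) · voxel volume` per seed, with
the single factor `k` fitted through the origin on a ~10% subset of ears
with reference weights.

## Worked example

Generate a two-ear phantom, write it as TIFF + sidecar, and run the full
pipeline against the generator's own reference table:

```python
import pandas as pd
from earset import (PhantomSpec, generate_ear_volume, write_volume,
                    PipelineConfig, run_pipeline)

spec = PhantomSpec(n_ears=2, seeds_per_ear=(25, 35), touch_fraction=0.1,
                   rng_seed=11)
volume, truth = generate_ear_volume(spec)
write_volume(volume, "scan.tif")
pd.DataFrame({
    "ear_id": [f"ear{e.ear_index}" for e in truth.ears],
    "actual_weight_g": [e.total_true_weight_g for e in truth.ears],
}).to_csv("actual.csv", index=False)

cfg = PipelineConfig(input_volume="scan.tif", expected_ears=2,
                     actual_table="actual.csv", out_dir="out", rng_seed=1)
cfg.calibration.subset_fraction = 1.0   # tiny demo: calibrate on both ears
result = run_pipeline(cfg)
print(pd.read_csv(result.ears_csv).to_string(index=False))
```

prints

```
ear_id  n_seeds  n_seeds_sieved  n_seeds_small  total_virtual_weight_g  total_weight_sieved_g  ear_length_seed_span_mm
  ear0       26              20              6                0.474525               0.438221                38.478838
  ear1       29              23              6                0.575979               0.547229                44.983993
```

Both phantom ears carried exactly 26 and 29 seeds with true total weights
0.4745 g and 0.5760 g — seed counts are recovered exactly, the six small
(< 2 mm) seeds per ear are flagged by the virtual sieve, and the fitted
calibration factor (1.6012e-3 g per mm³·absorption, written to
`out/manifest.json`) matches the generator's true density factor of
1.6e-3. `out/traits.csv` holds one row per seed (volume, virtual weight,
aspect ratio, surface, minimal width, sieve flag, normalized ear
position); `out/profile.csv` the weight-position profile;
`out/evaluation.json` the virtual-vs-actual r².

The same stages are available on the command line:
`earset phantom | recon | segment | traits | evaluate | run`.

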