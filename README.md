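# octfoci

Quantification of the axial (inner–outer) distribution of intraretinal
hyperreflective foci (IHRF) in OCT macular volumes, with a synthetic phantom
generator and longitudinal cohort statistics.

## The problem

IHRF are small, bright, well-circumscribed lesions inside the neurosensory
retina on OCT, and one of the strongest imaging risk factors for progression
of intermediate age-related macular degeneration (iAMD). Their *depth* matters:
most appear near the retinal pigment epithelium (RPE) and accrue outward-in,
so tracking how many foci sit at each retinal depth — and how those counts
change between visits — is a candidate progression biomarker.

`octfoci` implements the standard en-face slab protocol for this measurement:

1. **Depth normalization.** Each A-scan's depth axis is mapped to a normalized
   depth `d = (z − z_ILM) / (z_RPE − z_ILM)`, with `d = 0` at the internal
   limiting membrane (ILM) and `d = 1` at the inner border of the RPE, so all
   positions are comparable regardless of local retinal thickness.
2. **Slab extraction.** The retina is divided into K = 5 equidistant slabs,
   each spanning 20 % of the local ILM–RPE thickness and following both
   surface contours. Slab `j` covers `d ∈ [1 − j/K, 1 − (j−1)/K)`; **slab 1 is
   the outermost** (RPE-adjacent) slab, slab 5 the innermost. Each slab is
   collapsed to an en-face image (max-intensity projection by default).
3. **Detection.** Each slab image is thresholded and binarized; vessel,
   drusen-related and user-supplied artifact regions are excluded; connected
   components of at least 3 pixels are counted as foci.
4. **Longitudinal statistics.** Per-eye changes between baseline and month 24
   are categorized (increase / decrease / no change, per slab and in total),
   cohort summaries are computed (mean ± sample SD, range, median, slab
   distribution percentages), and changes are tested with paired t-tests
   (`t = mean(d) / (SD(d)/√n)`, two-sided p from the t distribution with
   n − 1 degrees of freedom).

Patient volumes are not required anywhere: a phantom module generates layered
retinas with curved surfaces, drusen, vessels, multiplicative speckle and
implanted foci at controlled normalized depths, together with a ground-truth
ledger, so every stage can be verified by parameter recovery.

## Worked example

```python
import numpy as np
from octfoci import (PhantomConfig, DetectionConfig, generate_volume,
                     detect_eye, truth_slab_counts)

cfg = PhantomConfig(foci_per_slab={1: 3, 2: 4, 3: 2},
                    speckle_sigma=0.0, n_drusen=0, n_vessels=0, seed=7)
vol, surf, ledger = generate_volume(cfg)
det = DetectionConfig(auto_vessel_mask=False, auto_drusen_mask=False)
counts, lesions, stack, artifacts = detect_eye(vol, surf, det)
print("truth   ", truth_slab_counts(ledger, 5))
print("detected", counts.counts)
```

prints

```
truth    [3 4 2 0 0]
detected [3 4 2 0 0]
```

i.e. on a noise-free phantom the detector recovers the implanted per-slab
counts exactly: 3 foci in the outermost slab, 4 in slab 2, 2 in slab 3, none
further in. The `lesions` table lists each detected focus with its slab,
en-face centroid, pixel area and source intensities.

The statistics stage works on plain per-slab counts. For example, a cohort in
which 40 of 52 eyes increased, 8 decreased and 4 were stable reports 76.9 %,
15.4 % and 7.7 % (percentages rounded half-up to one decimal):

```python
from octfoci import percent
percent(40, 52), percent(8, 52), percent(4, 52)   # (76.9, 15.4, 7.7)
```

## Command line

The same stages are available as a shell tool:

```bash
octfoci simulate --out eye1 --seed 4
octfoci simulate-followup --baseline eye1 --out eye1_m24
octfoci slabs  --volume eye1/volume.tif --surfaces eye1/surfaces.csv --out slabs/
octfoci detect --volume eye1/volume.tif --surfaces eye1/surfaces.csv --out det/
octfoci longitudinal --baseline base_counts.csv --followup m24_counts.csv --out report/
octfoci run-all --out run/ --seed 3          # whole synthetic cohort end-to-end
```

Volumes are multi-page 16-bit TIFFs (one page per B-scan), surfaces and all
tables are CSV, configs are YAML; `run-all` writes a reproducibility manifest
with per-file SHA-256 hashes.

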