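# rppkit

Quantitative bone histomorphometry for developmental inference: **radial
porosity profiles (RPPs)** of limb-bone mid-shaft cross-sections, from raster
measurement to trajectory clustering and membership statistics.

## The problem

Growing tetrapod limb bones deposit highly vascularized (porous) primary
cortex that compacts as growth slows. A section through the mid-shaft
therefore carries a radial record of growth: the innermost posthatching
cortex is the oldest, the periosteal surface the youngest. Quantifying how
primary porosity changes from the inner to the outer cortex — the radial
porosity profile — turns that record into a four-point trajectory that can be
compared across skeletal elements, individuals and taxa, and used to infer
ontogenetic stage and developmental strategy (altricial wing vs precocial leg
modules in birds, and by extension in extinct paravians).

## What the package does

**Measurement.** A cross-section arrives as a class-labelled raster
(background, primary bone, vascular space, medullary cavity, remodelled bone,
outer circumferential layer (OCL), endosteal lamellar layer (EL)).
Measurement sectors spanning the posthatching cortex are split into four
radial quadrants Q_a..Q_d by dividing each radial side into four arcs of
equal length and joining the division points with circumference-following
curves. Porosity per quadrant is

```
P_x = 100 · area(V_x) / (area(Q_x) − area(excluded_x))
```

with secondarily remodelled bone, OCL and EL subtracted from the sampled
area; quadrants whose primary record is mostly obliterated become missing
(NA). The mean RPP of a bone averages matching quadrants over the S = 3
sectors; profiles with at least two of four points remain analysable.

**Grouping.** Four engines sort mean RPPs into trajectory groups:

- `kmeans_cluster` — Lloyd K-means with 100 random restarts (complete RPPs);
- `fit_gbtm` / `gbtm_select` — group-based trajectory modelling: a
  k-component mixture of polynomial mean curves over the quadrant index with
  shared-variance Gaussian residuals, fitted by EM from many starts and
  selected by AIC, BIC and leave-one-out cross-validation error (CVE);
- `distance_matrix` + `hclust_complete` + `cut_tree` — DTW, edit-distance and
  LCSS trajectory similarity (tolerant of incomplete RPPs) followed by
  complete-linkage hierarchical clustering.

**Membership statistics.** `congruence_report` aligns labels across methods
(optimal assignment on the contingency table) and reports pairwise, overall
and consensus-tier congruence; `dissociation` encodes skeletal dissociation
per specimen (`"0"`, `"1-3"`, `"1-2-3"`, ...); `multinom_fit` /
`stepwise_select` regress memberships on age, bone and developmental strategy
with backward AIC elimination, AICc and the predicted-membership match rate
(PM%).

**Synthetic ground truth.** `generate_section` renders sections with known
radially varying pore fractions (hard-core disk packing, analytic targets);
`generate_rpp_dataset` draws RPP tables from known polynomial group
trajectories with sector noise and inner-quadrant missingness. Every stage is
testable without any external data.

## Worked example

```python
import numpy as np
from rppkit import (SectionBlueprint, generate_section, place_sectors_auto,
                    measure_section, mean_rpp)

bp = SectionBlueprint(radial_porosity_function=lambda d: 0.4 - 0.3 * np.asarray(d),
                      seed=1)
image, truth = generate_section(bp)          # labelled raster + analytic truth
sectors = place_sectors_auto(image, 3)       # three 60-degree sectors
profiles, layers = measure_section(image, sectors)
print(np.round(mean_rpp(profiles).as_array(), 2))
print(np.round(truth.quadrant_target_percent, 2))
```

prints

```
[36.12 28.5  20.96 13.68]
[36.03 28.59 21.13 13.65]
```

— the measured mean RPP (porosity % in quadrants a..d, declining outward as
the cortex compacts) agrees with the generator's analytic quadrant targets to
well under one porosity point per quadrant.

Clustering the default four-group synthetic dataset and selecting the model:

```python
from rppkit import four_group_design, generate_rpp_dataset, \
    trajectories_from_frame, gbtm_select

table, truth = generate_rpp_dataset(four_group_design(seed=202))
complete = [t for t in trajectories_from_frame(table).trajectories if t.is_complete]
report, best, summary = gbtm_select(complete, k_max=5, degrees=(1, 2, 3), seed=41)
print(summary["best_k"], summary["best_degree"])   # -> 4 2
```

## Command line

```
rpp simulate  --seed 1 --out sim                 # synthetic fixtures
rpp measure   --image section.tif --out meas     # raster -> tidy RPP table
rpp cluster   --table sim/rpp.csv --methods kmeans,gbtm,dtw,ed --k 4 --out clus
rpp congruence --labels clus/labels.csv --out rep
rpp dissociate --labels clus/labels.csv --table sim/rpp.csv --out rep
rpp regress    --labels clus/labels.csv --table sim/rpp.csv --out rep
```

Every artifact carries a YAML manifest with the package version, seed and a
hash of the effective configuration.

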