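# bonenet

Network analysis of skeletal glucose metabolism from total-body dynamic
PET, with a fully synthetic FDG-kinetics cohort generator for testing and
method development.

## The problem

Static ¹⁸F-FDG PET summarises each tissue by a single standardized uptake
value (SUV), which hides how tissues' uptake *dynamics* relate to one
another. With total-body dynamic PET every bone's full time-activity
curve (TAC) is recorded simultaneously, so the skeleton can be treated as
a system: bones whose uptake profiles rise and fall together are
metabolically coupled, and bones whose profiles are unrelated stand
apart. `bonenet` implements this analysis for a murine skeletal study
design — five mice, seven bone volumes of interest (tibia, femur,
humerus, forearm, spine, sternum, skull), a 60-min dynamic acquisition
binned into 6×30 s, 3×60 s, 2×120 s and 10×300 s frames — and a
synthetic cohort generator that reproduces that design so every stage is
testable without scan data.

## The method

1. **Segmentation** (volumetric inputs): bone voxels are selected by a CT
   Hounsfield-unit window (closed interval, default [332, 50000]);
   per-bone VOIs are the intersection of an integer label map with that
   mask; TACs and mean HU are read out per VOI.
2. **Quantification**: SUV = C_tissue · w / D with tissue concentration
   C (kBq/mL), body weight w (g) and injected dose D (kBq) — the
   body-weight convention with density 1 g/mL. Equilibrium uptake is the
   unweighted mean of the frames lying entirely inside 45–60 min (exactly
   the three final 300-s frames on the default schedule). The
   density-metabolism quotient expresses each bone's SUV and HU as a
   percentage of the totals over all bones.
3. **Network**: profiles (one row per bone, frame-wise mean across
   animals, on the non-decay-corrected signal) → all-vs-all Pearson
   correlation R → keep edges with R > 0.7 that rank in the top-3
   correlations of at least one endpoint (kNN pruning, k = 3). All bones
   stay in the graph as nodes, so weak coupling shows up as isolation.
4. **Statistics**: Shapiro–Wilk normality per bone (recorded, not
   branched on), one-way ANOVA with Tukey-HSD all-pairs comparisons
   across bones, and per-bone simple linear regression of equilibrium SUV
   on mean HU across animals, reported as r².

The simulator drives a two-tissue irreversible FDG compartment model
(dC₁/dt = K₁·C_p − (k₂+k₃)·C₁, dC₂/dt = k₃·C₁) with a tri-exponential
plasma bolus, applies ¹⁸F physical decay (T½ = 109.77 min), bins to the
frame schedule and adds count-like Gaussian noise. Six "coupled" bones
share a per-animal kinetic shape; one "spine-like" bone redraws its
kinetics independently per animal and carries a near-deterministic
HU↔SUV coupling — the structure the network and regression stages are
designed to detect.

## Worked example

```python
import bonenet as bn
from bonenet.network import (assemble_profiles, pearson_matrix,
                             knn_threshold_graph, graph_summary)

schedule = bn.mouse_60min_schedule()
cohort = bn.generate_cohort(bn.CohortSpec(seed=1), schedule)
profiles = assemble_profiles(cohort.tacs)          # 7 bones x 21 frames
r = pearson_matrix(profiles)
g = knn_threshold_graph(r, r_min=0.7, k=3)
summary = graph_summary(g)
print("degrees:", summary.degrees)
print("components:", [sorted(c) for c in summary.components])
print(f"mean edge weight: {summary.mean_edge_weight:.3f}")
```

prints

```
degrees: {'tibia': 3, 'femur': 4, 'humerus': 4, 'forearm': 3, 'spine': 0, 'sternum': 3, 'skull': 5}
components: [['femur', 'forearm', 'humerus', 'skull', 'sternum', 'tibia'], ['spine']]
mean edge weight: 0.972
```

The six driver-coupled bones form one tightly connected component (all
retained correlations above 0.94) while the decoupled spine-like bone is
isolated — its uptake dynamics share no structure with the rest of the
skeleton. Running the full pipeline (`bonenet run --seed 1 --out-dir
outputs`) additionally writes per-bone HU–SUV regressions; on this seed
the spine attains r² = 0.996 while every other bone stays below 0.69,
mirroring the intended design: the one bone that is metabolically
decoupled from the skeleton is also the one whose density tracks its
glucose uptake.

The same stages are available as CLI subcommands (`simulate`, `segment`,
`quantify`, `network`, `stats`, `run`); see `bonenet --help`.

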