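# Methods

## Kinetic forward model

Plasma input uses the standard tri-exponential bolus form

    Cp(t) = (a1·t − a2 − a3)·e^{−l1 t} + a2·e^{−l2 t} + a3·e^{−l3 t},

which is zero at injection, peaks sharply and relaxes through a fast
redistribution phase into a slow tail. Defaults (a1 = 800 kBq mL⁻¹ min⁻¹,
a2 = 180, a3 = 70 kBq/mL, l1 = 4.0, l2 = 0.5, l3 = 0.012 min⁻¹) were
chosen to give a realistic mouse bolus for a ~15 MBq injection: peak near
0.4 min (well inside 2 min), late plasma around 35–50 kBq/mL, and
non-negativity over the whole 0–75 min horizon (asserted by a test).

Tissue follows the two-tissue irreversible FDG model — free pool C₁
(plasma→tissue K₁, efflux k₂), trapped pool C₂ (phosphorylation k₃),
measured signal C_T = (1−vB)(C₁+C₂) + vB·Cp. Two independent solution
paths are implemented: a closed-form convolution of Cp with the impulse
response K₁·(k₂·e^{−(k₂+k₃)t} + k₃)/(k₂+k₃) (exact term-by-term
convolution of ramp- and exponential terms, written with `expm1` to
avoid cancellation when rate constants nearly coincide, with an explicit
branch at |Δ| < 1e−12 and a pure-integral branch for k₂+k₃ = 0), and an
LSODA integration of the ODEs at rtol 1e−9. The analytic path is the
production route; the ODE path exists to cross-check it, and the two
agree to ~1e−8 relative over the tested parameter ranges (K₁ ∈ [0.01,
1.5], k₂ ∈ [0.001, 1], k₃ ∈ [0, 0.3], vB ∈ [0, 0.3]).

Kinetic curves are computed in decay-corrected (tracer-mass) units;
physical decay (¹⁸F half-life fixed at 109.77 min, one constant for the
whole package) is applied multiplicatively afterwards, so both signal
conventions can be emitted.

## Synthetic cohort

The generator emulates the study design end to end: n = 5 animals, seven
bone VOIs, 60-min acquisition binned 6×30/3×60/2×120/10×300 s, injected
dose ~ Normal(15.08, 5.87) MBq (truncated at 1 MBq), body weight ~
Normal(27, 2) g (a 13-week male C57BL/6 scale), injection-to-scan delay
~ Uniform(2, 15) s. Frames are binned on the scanner clock (shifted by
the delay relative to injection), which is exactly what the time-delay
correction in the quantification stage undoes.

Correlation structure is explicit rather than emergent. Coupled bones'
log k₂/k₃ are interpolated toward a common cohort shape (the geometric
mean over coupled bones) with weight `shared_driver_strength` s; one
latent factor per animal multiplies K₁ and k₃ for all coupled bones
alike (σ = 0.25 lognormal); idiosyncratic shape jitter (σ = 0.35) is
scaled by (1−s) so that at s = 1 all coupled bones within an animal
share one curve shape up to amplitude — making their pairwise Pearson
correlation exactly 1 at zero noise, an invariant the tests rely on.
The decoupled (spine-like) bone redraws all three rate constants
independently per animal (lognormal σ = 0.5) around a low-trapping
baseline (k₃ = 0.012 min⁻¹ vs ~0.08 for coupled bones), so its
non-decay-corrected curve peaks early and falls while coupled curves
keep accumulating — the shape contrast that drives its low network
connectivity. Default s = 0.8 and per-bone K₁ baselines (axial sternum
and skull higher than the appendicular bones) give equilibrium SUVs of
roughly 0.2–1.4, a realistic murine bone range.

Acquisition noise is zero-mean Gaussian per frame with SD =
`noise_scale`·sqrt(max(value,0)/duration_min) — count-like variance
shrinking with frame duration; the default scale 2.0 yields ~2–10%
relative noise on late 300-s frames and visibly noisy early 30-s frames.
Negative noisy values are retained, as in reconstructed PET. No other
reconstruction physics (scatter, randoms, attenuation, partial volume)
is modelled, so passing tests demonstrate the pipeline's statistical
behaviour under the assumed noise model, not robustness to real
reconstruction artefacts.

The HU table maps each bone's equilibrium SUV (computed from the emitted
frames) through a configurable affine coupling HU = intercept +
slope·SUV + Normal(0, σ). The spine-like bone defaults to a strong
coupling (slope 600 HU/SUV, σ = 5 HU) and all others to slope 0 with σ =
60 HU around anatomically ordered baselines (appendicular ≈ 1200–1400
HU, axial ≈ 620–1000 HU), so the spine is designed to carry the only
near-deterministic density–metabolism relationship.

Reproducibility: each animal's random stream is seeded by (cohort seed,
animal index) via `SeedSequence`, so output is bitwise stable under a
fixed seed and growing the cohort never reshuffles earlier animals.

## Segmentation

The HU window is treated as a closed interval [332, 50000] — boundary
voxels are bone — a determinism choice tested explicitly. VOI voxel sets
are label ∩ mask; aggregation is the arithmetic mean (median available
as an option); empty VOIs produce NaN rows plus warnings, never silent
zeros. PET and CT must share the voxel grid; no resampling is attempted
(phantoms always share it, real data must be pre-resampled).

## Quantification

SUV uses the body-weight convention with density 1 g/mL; the injected
dose is taken as calibrated at injection time (no decay correction of
the dose). Equilibrium averaging admits only frames lying entirely
inside the window — no fractional weighting — which on the default
schedule and 45–60 min window selects exactly the three last 300-s
frames. Window selection uses the nominal scan-clock schedule: the
injection-to-scan delays are seconds against 300-s frames, and applying
them to frame selection would spuriously drop the final frame. Frame
midpoints are the time axis for any time-indexed computation on framed
data (e.g. decay correction of a TAC table). SUV tables are
decay-corrected by default; the network stage consumes the raw
non-decay-corrected signal by default — both conventions are exposed
per stage, and the correlation matrix's invariance to per-row positive
affine maps makes many such variants coincide exactly.

## Network

Edges require R > r_min strictly (default 0.7). kNN pruning (default
k = 3) uses the union rule: an edge survives if it ranks in the top-k
threshold-surviving correlations of *either* endpoint. The mutual rule
(both endpoints) is exposed as an option but not default, since it can
isolate nodes that genuinely share strong correlations. Ranking ties
break by higher R, then lexicographic bone name, so the edge set is
deterministic. Nodes are never dropped, whatever the pruning. Default
profile mode is the frame-wise mouse average (7 rows); per-animal
profiles (bone × animal rows) are available.

## Statistics

Shapiro–Wilk is recorded per bone but the pipeline does not branch on it
(the ANOVA runs regardless); multiple comparisons use Tukey HSD, chosen
as the standard all-pairs familywise correction, with the unadjusted
pooled-variance pairwise p reported alongside. "Regression" means
per-bone simple linear regression of equilibrium SUV on mean HU across
animals with r² = squared Pearson r; no multivariable model is fitted.
r² consistency with the network stage's correlation matrix is tested
across modules.

## Problem sizes and determinism

The default test and acceptance runs use the paper-scale design (5
animals × 7 bones × 21 frames), 100-draw dual-route sweeps for the
kinetics and graph oracles, and 20-seed Monte-Carlo for structure
recovery; a full pipeline run takes ~1 s on one CPU. All stochastic
stages flow from a single seed, and the run manifest records SHA-256
checksums per output so that identical config + seed implies identical
checksums.

## Known limitations

- No image reconstruction, attenuation/scatter/randoms modelling, or
  partial-volume effects; phantom geometry is boxes/spheres, not
  anatomy.
- The synthetic HU↔SUV coupling is an affine stand-in for whatever
  biology links density and uptake; it is a test harness for the
  regression stage, not a biological claim.
- The Gaussian noise model approximates reconstruction noise; real
  iterative reconstructions have correlated, non-Gaussian residuals.
- Inter-animal kinetic variability magnitudes are design choices (no
  field consensus values exist for this design); all are exposed in
  `CohortSpec`.
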