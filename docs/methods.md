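# Methods

This note documents the models and procedures implemented in `coinvade`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Data model

All rasters are single-band grids on one planar metric CRS, co-registered
by coordinates rather than by array index. Cell (0, 0) sits at the grid's
top-left corner; a point belongs to the cell whose half-open interval
[x₀, x₀ + cs) contains it, with the top edge inclusive. Grid families
(1/5/10/20/30/60 m) nest inside a common extent divisible by 60 m, so a
coarse cell boundary always coincides with 1-m cell boundaries and value
extraction at a cell centre round-trips exactly. Nodata is NaN in memory
and −9999 in the on-disk ESRI ASCII grid format; ASCII grids were chosen
over binary GeoTIFF so every artifact of a run is plain text and
diff-able.

## Synthetic landscape generator

The generator emulates the measurement chain of a field + remote-sensing
campaign over a post-mining mosaic. It is the package's test bed: all of
its outputs are pure functions of a `SceneConfig`, including the RNG seed
(stage-level streams are spawned from the one seed in fixed order, so any
stage can be regenerated bit-identically).

**Latent gradients.** Five spatially autocorrelated fields on the 1-m
master grid: temperature (°C-like, mean 35, sd 5 — summer-maximum surface
temperatures of dark spoil substrates), moisture, disturbance and
succession (unitless z-scores), and vegetation height (m), a deterministic
monotone logistic transform of succession saturating at 28 m. Each field
is Gaussian white noise convolved with a Gaussian kernel (default sigma
25 m, the scale of within-heap habitat patches) and re-standardised;
kernel width 0 degenerates to white noise, which the autocorrelation tests
exploit.

**Sensor layers.** Bands are noisy monotone transforms of the latents: a
1-m canopy height model (additive noise, clipped at 0); per-date 30-m
Red/NIR/thermal stacks in which a random subset of dates carries cloud
blobs that push reflectance *up* and brightness temperature *down*, so the
min-composite (reflectance) and max-composite (thermal) remove them —
one date is always left clean, and one thermal date always attains the
yearly extreme; 10/20/60-m reflectance bands in [0, 1]; a 10-m disturbance
index increasing in the disturbance gradient; a 10-m leaf-area proxy
increasing in green biomass; and a 10-m land-cover raster assigned by
deterministic thresholds on height, greenness, moisture and disturbance
into the 9-code source scheme (water, trees, grass, flooded vegetation,
crops, shrub, built, bare, snow/ice — the generator emits seven of them).
Green biomass is a logistic blend of succession and moisture; the moisture
weight is a config knob (`greenness_moisture_weight`, default 0.8) because
setting it to 0 confines the moisture signal to the short-wave infrared
band, which is how the tests realise a gradient that the survey sees but
the imagery barely does. The thermal stack is stored in sensor DN with the
producer constants 0.00341802 / 149.0 (K = scale·DN + offset), both
overridable.

**Occupancy truth.** Each genus has a logistic niche on the z-scored
gradients. Defaults: genus E — temperature +1.1, disturbance +0.7, height
−1.0, succession −0.6 (hot, open, disturbed, early-successional); genus
S — moisture +1.1, disturbance +0.5, succession² −0.4, height² −0.3
(moist, moderately disturbed, intermediate succession and height). The
intercept is calibrated by bisection on [−40, 40] (tolerance 10⁻⁴) so the
spatial mean of each probability surface hits the target prevalence
(default 0.40) to within 0.02; an unreachable target raises. Occupancy is
a single Bernoulli draw per pixel, and the two genera are drawn
independently given the latents, so joint prevalence (~18% under the
defaults) emerges from niche overlap rather than explicit coupling.

**Survey.** 358 circular plots of 28.3 m² by default, placed without
replacement on 1-m cells, uniformly at random (a stratified-by-succession
option exists; the placement strategy of real campaigns varies and both
are defensible). Plot species richness is 2 + Poisson rising with
succession; communities are assembled from an 80-species pool by trait
matching — species log-height matched to local canopy height, species
moisture preference matched to local moisture — so CWM height tracks the
height gradient and composition turns over along moisture and succession.
Species moisture preference is correlated (r ≈ 0.7) with log-SLA,
reflecting the canonical association between mesic habitats and thin,
high-SLA leaves; this is what lets the cover-weighted leaf economics of a
plot carry moisture information that the imagery may lack. Genus labels
are read off the occupancy truth at the plot centre.

**What the generator does not emulate:** radiative transfer, atmospheric
effects, phenology, spatial error in plot geolocation, detection error in
the survey, interactions between the two genera, and any dependence of
occupancy on the realised community (labels come from the latent niches
only). Passing tests therefore show that the pipeline recovers known
niche structure from data with realistic resolution, noise and nesting —
not that it would perform identically on real imagery.

## Field features

CWM traits are Σ coverᵢ·traitᵢ / Σ coverᵢ over the plot's species (cover
> 0), natives-only variants filter on the nativity flag, and species with
a missing trait are dropped from that trait's weighting; an empty
eligible set yields a missing value, never an exception. FRic is the
convex-hull volume of the plot's species in trait space standardised over
the *full species pool* (not per plot), which makes hull volumes
comparable across plots and invariant to trait units. When a plot has no
more species than trait axes, the cloud is rotated onto its npts − 1
leading principal axes (a 1-D reduction degenerates to the range); a
degenerate hull in full-rank space (collinear species) is missing.
Missing FRic values are imputed by a 500-tree random-forest regression on
the remaining field variables plus the CWM of leaf dry matter content (an
auxiliary trait carried for imputation only); the out-of-bag R² is
reported, and tree ensembles cannot extrapolate beyond the observed FRic
range, which the tests assert.

The succession score is axis 1 of a 2-D nonmetric MDS of the plots'
presence–absence composition under Bray–Curtis distance (equal to
Sørensen dissimilarity for 0/1 data), best of 20 random restarts (a
config knob), 300 iterations, normalised stress. The embedding is rotated
onto its principal axes so "axis 1" is the major axis, and its
indeterminate sign is fixed by positive correlation with CWM height, so
larger scores mean later succession.

## Classification protocol

The 75/25 split is stratified with ⌈0.75·n_class⌉ rows per class in
training — 358 observations yield exactly 270/88. Tuning uses a
stratified 10-fold CV repeated 10 times; fold assignments are shared
across the hyperparameter grid, and a fold that would leave one class
empty is regenerated under a fresh sub-seed. The selection criterion is
mean held-out AUC (rank-based Mann–Whitney with tie correction); the
winning point is refit on all training rows, and the held-out class
probabilities of every resample are retained for threshold selection.
AUC ± SD is the mean and sample SD (n − 1) over the 100 resample AUCs.

Default grids (the literature rarely prints them, so they follow the
conventions of the standard training frameworks and are all
config-overridable): GBM — trees 50…500 step 50 × interaction depth
{1, 2, 3}, with shrinkage 0.1, minimum node size 20 and bag fraction 0.5
held fixed; the whole tree axis is scored from one staged fit per depth
and resample, so the 30-point grid costs 3 fits. RF — 500 trees, mtry over
≤5 values spread across 1…p. SVM — C ∈ {0.25, 0.5, 1, 2, 4} × sigma from
the median heuristic (0.9/0.5/0.1 quantiles of pairwise squared distances
between scaled rows, kernlab-style). Predictors are centred/scaled for
the SVM only (the scaler is part of the model bundle); SVM probabilities
come from Platt-type calibration on internal folds.

Test-set confusion matrices are formed at probability 0.5; the
sensitivity/specificity-balanced thresholds belong to the mapping stage
only. A metric with a zero denominator is *undefined* (NaN), deliberately
distinct from 0. Variable importance is the learner's native measure
(GBM relative influence, RF impurity importance) min–max scaled to a
maximum of 100; the SVM gets a model-free filter (per-variable standalone
AUC folded around 0.5) since the kernel machine has no native per-feature
decomposition. Partial dependence forces one feature to each grid value
over copies of the training rows and averages predicted probabilities.

## Ordination

RDA fits centred Y (the two predicted probabilities) on column-
standardised X by least squares and eigen-decomposes the fitted values
(SVD; eigenvalues s²/(n − 1)). Standardising X is a choice — field and
remote-sensing predictors differ by orders of magnitude in scale, and VIF
is scale-free so nothing downstream depends on it. Type-2 scaling is
underdetermined by name alone; here response scores are the fitted-value
principal axes scaled by √eigenvalue, and explanatory arrows are
correlations of each standardised X column with the constrained site
scores, scaled the same way. A rank-deficient X is fitted through the
pseudoinverse and flagged rather than refused. VIFⱼ = 1/(1 − R²ⱼ) with
exact collinearity reported as infinity; the redundancy screen is
VIF > 10.

## Mapping

Threshold selection evaluates exactly 100 candidates 0.01, 0.02, …, 1.00
per CV resample (classification positive at p ≥ t), takes the candidate
minimising |Se − Sp| with ties broken toward the *smallest* qualifying
threshold (conservative toward sensitivity), skips single-class resamples
with a warning, and averages over resamples. Landmark pixels are the 5-m
cell centres; every coarser layer is queried at its containing cell, with
no interpolation. Rows with any missing predictor become nodata in all
outputs. Masks are p ≥ threshold; the co-invasion layer is their
elementwise AND, so its area can never exceed either genus's.

Coverage converts 5-m pixel counts at 0.0025 ha each and reports percent
against both the supplied site area and the map's own valid-pixel area
(the two differ when site boundaries cut pixels; both accountings are
emitted). Land cover is collapsed to four broad classes — trees → high
vegetation; grass, crops, shrub and flooded vegetation → low vegetation;
bare → bare ground; built → built area — with water retained as its own
class and snow/ice excluded; unknown codes raise with the offending code
listed. Group contrasts use the Welch two-sided t-test
(Satterthwaite df) and Cohen's d with the pooled n−1 SD; positive d means
the first group's mean is larger, and zero pooled variance makes d and p
undefined rather than an error. Report tables round only at presentation.

## Numerical and testing choices

Focal statistics use truncated edge windows (NaN padding, statistics over
valid cells only) and the n − 1 sd denominator. Rao's Q uses equal weights
1/N and absolute-difference distances, N² normalisation including the
zero i = j terms, computed through the sorted-values pair-sum identity to
avoid materialising N² pairs; it is invariant to adding a constant and
linear in positive scaling, and both properties are tested against an
O(N²) loop oracle. The 1-m→5-m canopy aggregation is exact block
statistics (equivalent to the 5×5 focal evaluated at 5-m centres; a
focal-then-resample route differs only at nodata edges). Compositing
happens before index computation — min-composited Red and NIR feed NDVI,
the max-composited thermal band feeds the Celsius conversion — because
the two orders differ and the acquisition-chain order is the meaningful
one.

Unit and property tests run on small grids (≤40×40) with 50-seed oracle
sweeps; the end-to-end test and the acceptance script use the default
1200-m scene (1.44 M 1-m cells, 57,600 landmark pixels, 358 plots) with
the full 10×10 CV, sizes chosen so the whole suite completes in roughly a
quarter hour on one CPU while still exercising every stage at full
protocol fidelity.

## Known limitations

Importance scaling differs across learners, so ranks — not magnitudes —
are comparable between models. The NMDS axis is only identified up to
sign and depends on restart luck for high-stress configurations. The
threshold procedure assumes the CV held-out probabilities are exchangeable
with map-time predictions; covariate shift between plots and landscape
pixels is not corrected. Spatial autocorrelation is ignored by the
resampling (no spatial blocking), so CV AUC is optimistic to the degree
that folds share landscape patches; spatial cross-validation is a noted
extension. RDA significance is not permutation-tested.
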