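# Methods

## Sampling model

The analysis unit is the *transect*: a timed horizontal tow of a video
camera at a fixed target depth, at a named station, during day or night.
Each annotated organism is one event keyed to its transect; organisms seen
while the camera moved between transects are excluded at read time.
Observations are keyed to the transect's *target* depth, not the
instantaneous camera depth: towed systems wobble (typically ≤ 5 m, more on
deep tows in heavy seas), and the target depth is the coordinate on which
the survey design is balanced.

A transect of duration *t* minutes samples a volume *V = F·t*, where *F*
(m³ min⁻¹) is the volume the camera effectively images per minute of
towing. *F* is not derivable from optics alone; it is estimated by counting
a reference taxon that both the camera and a co-deployed quantitative
particle profiler (UVP-type) resolve well — slow-swimming pelagic worms are
ideal because they neither avoid the camera nor move between instruments'
fields. With reference counts *nᵢ*, durations *tᵢ* and matched profiler
concentrations *cᵢ* (ind m⁻³):

    F̂ = Σᵢ nᵢ / Σᵢ (tᵢ · cᵢ).

This pooled-ratio form equals "(total count per total minute) divided by
the duration-weighted mean concentration". It was chosen over the mean of
per-transect ratios because it is defined when individual transects have
zero counts and is exactly invariant to cutting a tow into sub-transects.
Profiler bins are matched to a transect by averaging concentration within
± 25 m of the target depth (`calibration.depth_match_halfwidth_m`),
covering realistic depth wobble. Counts then convert as
concentration = count / (F·t) × 1000 (ind / 1000 m³).

Assumptions worth keeping in mind: one global *F* for all taxa and depths
(larger organisms are visible farther away, so *F* is taxon-size dependent
in reality; a per-taxon factor table can be supplied but the default is
global), and perfect detection within the imaged volume.

## Habitat strata

Mean hydrographic profiles pool all CTD samples into half-open depth bins
[k·w, (k+1)·w), default w = 5 m, reported at bin midpoints; SD uses the
n−1 denominator and empty bins are absent rather than zero. Four strata
partition the column:

* **UL** (upper layer), [0, z1]. z1 defaults to a configured constant
  (92 m) because in practice this boundary is set from mean hydrographic
  conditions by expert judgement; a `max-gradient` alternative takes the
  depth of maximum |dT/dz| in the upper 200 m and raises a "no
  thermocline" error on isothermal input.
* **UOC** (upper oxycline), (z1, z2].
* **OMZ**, (z2, z3]: the contiguous depth band where mean oxygen falls
  below `strata.threshold_umol_kg` (default 60 µmol kg⁻¹). When several
  disjoint sub-threshold layers exist — e.g. a secondary shallow minimum
  near 100 m — the band containing the *global* minimum is the OMZ; the
  shallow dip is deliberately not treated as OMZ. z2/z3 are the linear
  interpolation crossings of the threshold between adjacent grid points,
  which an exact piecewise-linear oracle reproduces to machine precision.
  If oxygen never crosses the threshold, there is no OMZ and stratum-based
  stages cannot run.
* **LOC** (lower oxycline), (z3, z_max], z_max default 1000 m.

Membership is upper-inclusive: a depth exactly on a boundary belongs to the
shallower stratum (z2 is still UOC, z3 still OMZ). Any fixed convention
would do; this one is documented and tested.

## Weighted mean depth and migration testing

WMD = Σ aᵢzᵢ / Σ aᵢ over a taxon's transect depths, computed per station
and period; it is undefined (NaN, never zero) where the taxon is absent.
WMD is invariant to rescaling abundances and equivariant under depth
translation — both property-tested.

Diel vertical migration is tested per taxon with a two-sided paired t-test
on (day − night) station WMDs. The pairing unit is the station: survey
designs of this kind repeat day and night deployments at the same
stations, and station pairing is the only replication structure available
(one pooled WMD per period would leave n = 1). Stations lacking a defined
WMD in either period drop out; fewer than `dvm.min_pairs` (default 3)
pairs yields "insufficient pairs" and never a migration flag — low sample
sizes (e.g. rarely seen pyrosomes or salps) must not produce migration
calls. Degenerate inputs are handled explicitly: all-zero differences give
t = 0, p = 1; a constant nonzero shift gives |t| = ∞, p = 0. α = 0.05,
two-sided, uncorrected across taxa (each taxon is reported with its own
p-value); Benjamini–Hochberg adjusted p-values are emitted in an extra
column for transparency, but the M flag follows the per-taxon rule.

Bimodal taxa get a *split rule* before WMD/DVM: observations at depths ≤
split depth form a "shallow" group, the rest a "deep" group, each with its
own WMD and test. The default split depth is the OMZ midpoint
(`splits: {taxon: omz_mid}`), because the gap such taxa show *is* the OMZ;
any depth strictly inside the sampled range may be configured. Splits
apply only to WMD and migration testing — type classification uses the
unsplit profile, since bimodality is itself the signature of Type 2. A
split taxon is flagged M when any of its groups tests significant.

## Distribution types

The five types are operationalised from the pooled profile (mean over
stations per depth, then — for non-migrants — mean of day and night):

1. Compute per-stratum mean concentration across the transect depths in
   each stratum (a concentration basis, so a thick LOC does not out-vote a
   thin OMZ), and each stratum's share of the summed means.
2. **Bimodality first**: if the maxima above z2 and below z3 are both
   positive and the minimum concentration at OMZ depths is below
   `classify.trough_ratio` (default 0.25) of the smaller flanking maximum,
   the taxon is Type 2. The score 1 − trough/smaller-peak is reported.
3. Otherwise, if the largest stratum share is below
   `classify.evenness_threshold` (default 0.40) no stratum dominates:
   Type 5.
4. Otherwise the peak stratum decides: OMZ → 1, UL or UOC → 3, LOC → 4.

Migrants (significant DVM) are typed from their *daytime* pooled profile:
night pooling would smear an OMZ-daytime migrant into the upper layer, and
the daytime residence depth is what places a taxon relative to the OMZ.
The thresholds are config-exposed because the underlying type definitions
are verbal, not numeric; the defaults recover 100% of planted types in the
synthetic population test. Note the numbering convention — 3 = above,
4 = below the OMZ; since presentations of similar schemes occasionally
swap labels between figures and text, every output row also carries the
explicit peak stratum, which is unambiguous. Taxa with fewer than
`classify.min_observations` (default 20) total observations are reported
as "unclassified - low n" rather than forced into a type.

## Ordination

One sample = one transect within one period. The matrix holds all taxon
concentrations plus temperature, oxygen, chlorophyll-a (interpolated from
the mean CTD profile at the target depth) and particle concentration (sum
of the profiler's small and large size classes by default,
`ordination.particles_var`). Every column is min-max normalised to [0, 1];
constant columns map to 0 and are flagged. PCA is computed on the
covariance of the centred normalised matrix — the normalisation already
equalises ranges, so no additional unit-variance scaling is applied. Day
and night are analysed independently. The solver is the deterministic full
SVD with a sign convention (largest-magnitude loading entry positive) so
repeated runs are bit-identical; a brute-force covariance
eigendecomposition serves as the test oracle. Biplot output renders
environmental variables as vectors and taxa as points at their loadings.

## Synthetic data

The generator's defaults describe one fixed study condition, not a tuning
surface:

* Environment: 25 °C surface over a logistic thermocline to 6 °C at
  1000 m; oxygen 220 µmol kg⁻¹ minus a Gaussian deficit centred at 400 m
  with σ = 180 m reaching 35 µmol kg⁻¹ — the 60 µmol kg⁻¹ crossings of
  this curve sit near 303/497 m; chlorophyll maximum 0.9 mg m⁻³ at 50 m;
  salinity 34.8–36.3; particles with a surface maximum and a genuine
  secondary maximum inside the OMZ. Seven casts with independent Gaussian
  sensor noise.
* Design: six stations with paired day/night deployments plus one day-only
  station; target depths 50–1000 m (50 m spacing to 500 m, 100 m below);
  11 min tows above 350 m, 22 min below; true calibration factor
  15 m³ min⁻¹ (≈ 0.5 m² imaged cross-section × 0.51 m s⁻¹ × 60 s).
* Taxa: truncated-Gaussian, two-mode or uniform concentration profiles;
  night shifts plant migration. The five archetypes (OMZ resident, bimodal
  avoider, shallow resident, deep migrant shifted 200 m up at night,
  uniform) cover all five types with exactly one M.
* Counts: Poisson with λ = concentration × F × duration, expanded to one
  annotation event per individual. Negative-binomial overdispersion is
  available (gamma-mixed Poisson) to stress the migration test.

What the generator does **not** emulate: taxon-size-dependent
detectability, camera avoidance, depth wobble of the camera around the
target (real-data keying by target depth absorbs it), within-station
patchiness beyond Poisson, correlated day/night community change, or
multi-species composition of pooled groups. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
sampling model, not robustness to every field artefact.

## Problem sizes and tolerances

The reproduction script and acceptance tests use: 500 seeds for Gaussian
WMD recovery (|WMD − 400| ≤ 15 m, tolerating grid discretisation plus
Poisson noise); 2000 null and 1000 shifted replicates for the migration
test's empirical size ([0.03, 0.07] at α = 0.05, n = 6 pairs) and power
(≥ 0.9 at a 150 m shift, 30 m station SD); 200 seeds for calibration
recovery (median error ≤ 5% whenever total reference counts ≥ 200); 250
planted taxa (50 per type, peak expected counts ≥ 50 per transect) for
type recovery ≥ 90%; 20 seeds of the five-archetype community for the
end-to-end median 5/5 with correct M flags; 1e−8 absolute tolerance for
PCA eigenvalues against the oracle; byte-identity for pipeline reruns.

## Known limitations

Single global calibration factor; no detectability correction; strata from
oxygen and a fixed/gradient UL boundary only (no density or mixed-layer
criteria); the OMZ must be a single contiguous band around the global
minimum; t-tests assume approximately normal station-level WMD differences
(adequate at the simulated noise levels; ranks would be needed for heavy
tails); classification thresholds are conventions, not estimates, and
should be reported alongside any real-data use.
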