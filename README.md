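# midwater

Vertical community structure analysis for towed-camera pelagic video
surveys.

Horizontal video transects (a camera towed at ~0.51 m s⁻¹ for 11–22 min at
fixed target depths between 50 and 1000 m) are one of the few ways to
quantify large, fragile gelatinous zooplankton — medusae, ctenophores,
siphonophores, larvaceans — that nets destroy. This package turns the raw
annotation event log from such a survey into a quantitative picture of how
a midwater community is structured around an oxygen minimum zone (OMZ):

1. **Abundance** — per-transect counts become rates (ind min⁻¹) and then
   volumetric concentrations (ind / 1000 m³) via a calibration factor *F*
   (m³ imaged per minute), estimated from a slow-swimming reference taxon
   (the polychaete *Poeobius*) counted simultaneously by the camera and by
   a quantitative particle profiler (UVP):
   `F̂ = Σᵢ nᵢ / Σᵢ (tᵢ·cᵢ)` over co-observed transects.
2. **Habitat strata** — mean CTD profiles delimit four layers: upper layer
   (UL), upper oxycline (UOC), the OMZ where mean O₂ < 60 µmol kg⁻¹
   (boundaries by linear interpolation of the threshold crossings), and the
   lower oxycline (LOC).
3. **Weighted mean depth (WMD)** — per taxon, station and period,
   `WMD = Σ aᵢzᵢ / Σ aᵢ`; bimodal taxa are first split into shallow/deep
   groups at a configurable depth (default: mid-OMZ).
4. **Diel vertical migration (DVM)** — a two-sided paired t-test on
   per-station (day − night) WMDs; significant taxa get the modifier **M**.
5. **Distribution types** — each taxon is classified relative to the OMZ:
   Type 1 peak inside the OMZ, Type 2 bimodal (peaks above *and* below),
   Type 3 peak above, Type 4 peak below, Type 5 no obvious peak.
   Migrants are typed from their daytime profile.
6. **Ordination** — separate day and night PCAs of the min-max-normalised
   samples × (taxa + temperature, oxygen, chlorophyll-a, particles) matrix,
   with biplot coordinates (environmental vectors, taxon points).

A synthetic-data generator (`midwater.synthetic`) reproduces the
statistical structure of such a survey — smooth hydrography with a
mid-water oxygen minimum, surface and OMZ particle maxima, Poisson counts
from planted taxon distributions — so the entire pipeline is testable by
recovery of known truth, with no cruise data required.

## Worked example

Generate a synthetic survey (five archetype taxa plus the calibration
reference) and run the full analysis:

```bash
midwater synth --out-dir inputs --seed 42
cat > run.yaml <<'EOF'
inputs:
  annotations: inputs/annotations.csv
  transects: inputs/transects.csv
  ctd: inputs/ctd.csv
  particles: inputs/particles.csv
  reference_conc: inputs/reference_conc.csv
output_dir: out
seed: 42
calibration:
  mode: estimated
splits:
  Beroe: omz_mid
EOF
midwater run --config run.yaml
```

`out/strata.csv` then holds the detected habitat layers:

```
stratum,upper_m,lower_m,threshold_umol_kg
UL,0.0,92.0,60.0
UOC,92.0,303.21598331306046,60.0
OMZ,303.21598331306046,499.27829071064366,60.0
LOC,499.27829071064366,1000.0,60.0
```

i.e. the OMZ spans ≈ 303–499 m — bracketing the generator's planted oxygen
deficit centred at 400 m. `out/types.csv` and `out/dvm_tests.csv` recover
every planted distribution:

```
       taxon label peak_stratum    |        taxon  n_pairs  mean_diff_m  p_value  significant
      Atolla    4M          LOC    |       Atolla        6     213.8452   0.0000         True
       Beroe     2            -    |   Beroe_deep        6       1.1877   0.7699        False
Chaetognatha     5            -    | Beroe_shallow       6      -2.7325   0.6288        False
   Lilyopsis     1          OMZ    |    Lilyopsis        6       0.9982   0.7895        False
    Poeobius     5            -    |     Poeobius        6      -8.8558   0.0680        False
       Praya     3          UOC    |        Praya        6      -3.5163   0.2781        False
```

The deep migrant (*Atolla*-like, planted 200 m shallower at night) is the
only taxon flagged M, with a mean day−night WMD difference of ≈ 214 m; the
bimodal OMZ-avoider (*Beroe*-like) is Type 2 and its shallow/deep groups
show no migration. The manifest records the estimated calibration factor,
14.859 m³ min⁻¹ here against a generating truth of 15 (−0.9%).

The same pipeline runs unchanged on real survey exports: a one-row-per-
organism annotation CSV, a transect metadata CSV, a CTD cast CSV and a
depth-binned particle CSV (see `midwater.io` for the exact columns).

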