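# halospat

Spatial-scale analysis of halite endolith microbiomes.

Halite nodules — fist-sized salt rocks in hyperarid coastal deserts —
host microbial communities in their pore spaces. Because each nodule is a
physically isolated habitat, these communities are a natural model for
asking how much of microbiome composition is set by the environment
(water and light availability) and how much by ecological drift under
dispersal limitation. `halospat` packages the full analysis such a survey
needs, for microbial ecologists working with nested sampling designs
(regions ≫ sites ≫ nodules ≫ slices ≫ vertical positions):

- **`env_sensors`** — dew (RH > 95 %) and fog (RH > 99 %) event
  statistics from 30-minute logger series, site comparisons, daily
  profiles, and a local-polynomial kernel smoother.
- **`light_par`** — effective transmission spectra inside nodules,
  band-integrated PAR estimates (PAR = reduction ratio × PAR_max,
  default PAR_max = 2100 µmol m⁻² s⁻¹), and the isotropy correction
  1 + upwelling/downwelling (1.3 at the typical 30 %).
- **`biomass`** — cells per gram of halite from DAPI field counts with
  single-pass 2-SD outlier rejection.
- **`diversity`** — first-principles rarefaction, Shannon/Simpson/
  Pielou/Faith PD, Bray–Curtis, weighted UniFrac
  (Σ ℓ·|P_a − P_b| over branches), and classical-scaling PCoA.
- **`community_stats`** — PERMANOVA, Kruskal–Wallis group tests, the
  ANCOM W statistic, within-slice standardization, paired positional
  tests, abundance-versus-depth trends, distance-scale decay
  (3 cm / 10 cm / 10 m / 300 m / 20 km classes), and the replicate noise
  floor.
- **`synthetic_data`** — a seeded generator for every input above
  (logistic-normal count tables with nested drift, diel sensor series
  with injected events, Beer–Lambert spectra, Poisson field counts) with
  ground truth for parameter-recovery testing.

## Worked example

Simulate the intra-nodule survey (6 nodules × 3 slices × 3 vertical
positions) with a light-dependent phototroph and humidity-dependent
interior taxa, then test which taxa track the vertical gradient:

```python
import halospat as h
from halospat import synthetic_data as sd

design = sd.DesignSpec(n_regions=1, sites_per_region=1,
                       nodules_per_site=6, slices_per_nodule=3)
eff = sd.EffectSpec.intra_nodule_gradient(design.n_taxa)
meta = sd.generate_metadata(design, seed=1)
table, truth = sd.generate_counts(meta, eff, design, seed=2)

rel = table.div(table.sum(axis=1), axis=0)
std = h.slice_standardize(rel, meta["slice"])          # slice means -> 1
res = h.position_test(std[["ASV0000"]], meta["position"], meta["slice"])
print(res[["position_a", "position_b", "n_pairs", "mean_diff", "p"]].round(4))
```

```
  position_a position_b  n_pairs  mean_diff       p
0        top     middle       18     0.8379  0.0000
1        top     bottom       18     0.2621  0.0174
2     middle     bottom       18    -0.5758  0.0000
```

The phototroph (ASV0000) is strongly enriched at nodule tops relative to
middles (paired t-test on 18 slice pairs, standardized abundance
difference +0.84, p < 1e-4), exactly the gradient injected by the
generator. Community-level structure across scales:

```python
dm = h.bray_curtis(table)
decay = h.scale_decay(dm, meta)
print(decay.means().round(3))
pr = h.permanova(dm, meta["nodule"], n_perm=999, seed=3)
print(f"PERMANOVA: pseudo-F = {pr.pseudo_f:.2f}, p = {pr.p_value:.3f}")
```

```
3 cm     0.123
10 cm    0.155
10 m     0.174
300 m      NaN
20 km      NaN
PERMANOVA: pseudo-F = 4.49, p = 0.001
```

Mean Bray–Curtis dissimilarity grows from horizontal neighbours (3 cm)
through within-nodule (10 cm) to between-nodule (10 m) pairs — distance
decay of similarity — and nodule identity significantly structures the
communities (coarser classes are empty because this design has a single
site). A command-line interface mirrors the library
(`halospat simulate|events|compare-sites|par|biomass|beta|stats ...`).

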