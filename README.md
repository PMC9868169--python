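# hdikit

A raster-analysis toolkit for quantifying **human disturbances** on gridded
landscapes. It is written for landscape ecologists and environmental-impact
analysts who want a reproducible, scriptable alternative to a desktop-GIS
workflow for disturbance mapping and its spatiotemporal pattern analysis.

## The method

Human pressure on a land unit is decomposed into three components, each
scored per grid cell and summed into the composite **Human Disturbances
Index**:

```
HDI = LNI + RCI + PEI          HDI ∈ [0, 60]
```

- **LNI** (land-use naturalness index, 0–10): each of nine land-use classes
  (arable, forest, grassland, artificial/natural water, urban, rural,
  industrial, unused) carries a fixed naturalness score from the HAILS
  scheme — 0 for untouched cover up to 10 for sealed settlement and
  industrial surfaces.
- **RCI** (resource consumption index, 0–20): water- and energy-consumption
  density surfaces are built by spreading sectoral statistical totals over
  the land-use classes that generate the demand (energy carriers first
  converted to standard coal equivalent), plus residential consumption from
  population density × per-capita rates. Each surface is standardized to
  integer scores 0–10 and the two scores are summed.
- **PEI** (pollution emission index, 0–30): CO₂ and N₂O inventory fields
  (downscaled by ordinary kriging or IDW) and a non-point pollution surface
  confined to arable and rural land, each standardized to 0–10 and summed.

Standardization uses **Fisher–Jenks natural breaks** computed once on values
pooled across all periods of a dataset, so a given raw value receives the
same score in every period; exact-zero cells (no activity) score 0. HDI is
cut into ten equal-interval **disturbance levels** I–X of width 6
(0–6 → I, …, 55–60 → X).

Spatiotemporal pattern analytics:

- **Weighted centroid migration** — X = Σ xᵢⱼ·HDIᵢⱼ / Σ HDIᵢⱼ (and likewise
  Y) per period, chained into a track with displacement, compass bearing and
  speed (m/yr).
- **Global Moran's I** — I = ΣᵢΣⱼ Wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / (S² ΣᵢΣⱼ Wᵢⱼ) with
  binary contiguity weights and a Z test (normality or permutation null).
- **Getis-Ord Gi\*** — G\*ᵢ = Σⱼ Wᵢⱼ(d)·xⱼ / Σⱼ xⱼ with a binary distance
  band including the focal cell, standardized to Z scores and thresholded
  into hot/cold-spot categories at ±1.645 / ±1.960 / ±2.576.

A seeded synthetic-landscape module generates complete input bundles
(clustered land-use mosaics, population surfaces, sector statistics,
emission fields with plantable hot-spot clusters) so the full pipeline is
testable without any external data.

## Worked example

```python
import numpy as np
from hdikit.grid import GridSpec
from hdikit.synthetic import ScenarioConfig, generate_bundle
from hdikit.pipeline import run_pipeline

cfg = ScenarioConfig(seed=7,
                     grid=GridSpec(60, 60, 1000.0, 0.0, 60_000.0, "synthetic-meters"),
                     periods=("1990", "1995", "2000"))
res = run_pipeline(generate_bundle(cfg))

h = res["hdi"]["1990"].hdi
print("HDI 1990 range: %.2f - %.2f" % (np.nanmin(h), np.nanmax(h)))
print(res["level_tables"]["2000"].round(2).to_string(index=False))
seg = res["centroid_track"].segments[0]
print("centroid 1990->1995: %.1f m %s at %.1f m/yr"
      % (seg["displacement_m"], seg["direction"], seg["speed_m_per_year"]))
m = res["moran"]["1990"]
print("Moran's I 1990: I=%.3f Z=%.1f" % (m["i"], m["z"]))
```

prints

```
HDI 1990 range: 6.00 - 47.00
zone period    I   II   III    IV    V    VI  VII  VIII  IX   X
 all   2000 0.22 5.14 15.36 15.78 28.0 31.97 3.25  0.28 0.0 0.0
centroid 1990->1995: 2222.9 m S at 444.6 m/yr
Moran's I 1990: I=0.428 Z=50.8
```

The level table gives the percentage of cells in each disturbance level
(rows sum to 100); the strongly positive, highly significant Moran's I says
disturbance intensity is spatially clustered rather than random, and the
centroid segment summarizes where the bulk of disturbance moved between
periods and how fast.

The same steps are available from the shell:

```bash
hdikit simulate --seed 7 --rows 60 --cols 60 --out-dir scenario/
hdikit lni scenario/land_use.tif --out lni.tif
hdikit moran lni.tif
hdikit classify lni.tif --out levels.tif --table-out shares.csv
```

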