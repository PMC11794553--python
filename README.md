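# paleoiso

Testing cultural against environmental drivers of dietary variability in
Neolithic and Chalcolithic bone-collagen isotope data.

Archaeological human δ¹³C/δ¹⁵N values mix two signals: what people chose to
eat (culture) and what the local environment fed into the food web
(baseline). `paleoiso` implements an analysis pipeline that separates the
two for multi-site collagen datasets from a two-region study area such as
the Carpathian Basin:

1. **Collagen QC** — preservation screening on collagen yield, %C, %N and
   the atomic C/N ratio (Ambrose/DeNiro windows, C/N ∈ [2.9, 3.6] by
   default), plus explicit exclusions and a chronology requirement, with
   auditable reason codes.
2. **Isotope statistics** — five-number summaries with R-type-7 quartiles,
   one-way ANOVA and Kruskal–Wallis group tests, and the site-level trophic
   offset Δ = mean(human) − mean(contemporaneous herbivores+omnivores),
   computed only where both pools have ≥ 2 samples.
3. **Hydrology** — priority-flood sink filling and single-direction flow
   routing (deterministic D8 or stochastic Rho8), accumulating monthly
   precipitation weights downslope: ACC(c) = w(c) + Σ upstream.
4. **Drought index** — the monthly conditional model CON = rule[P-quartile,
   T-quartile] (class 1 = drought-vulnerable … 4 = humid) and its
   flow-weighted refinement wCON = rule[QA, QC], where QA and QC are the
   quartile ranks of rescaled ACC and of CON; top-quartile drainage raises a
   cell one class, bottom-quartile lowers it.
5. **Site typology** — all wCON months plus one-hot soil units within a
   3000 m site catchment are flattened to a feature vector, reduced by PCA
   to 99 % explained variance, and partitioned by K-means with gap-statistic
   (Tibshirani, firstSEmax) and silhouette selection of k. Cluster-by-region
   contingency tables are tested by χ² (Fisher fallback).
6. **Synthetic data** — terrain, seasonal climate, Voronoi soil mosaics,
   sites and isotope tables with known generating truth, so every stage is
   testable end to end without downloads.

The clustering stage is also exposed as a scikit-learn compatible estimator
(`CatchmentClusterer`) with `fit`/`predict`, `get_params` and fitted
`labels_`, `k_`, `inertia_` attributes.

## Worked example

```python
import numpy as np
from paleoiso import SyntheticConfig, generate_sites, generate_isotope_dataset
from paleoiso import apply_quality_filter, compute_offsets, summarize

cfg = SyntheticConfig(seed=1, n_sites=30, n_fauna_per_site=10, n_humans_per_site=10)
sites = generate_sites(cfg, margin_cells=1)
samples, truth = generate_isotope_dataset(cfg, sites)

kept, rejected = apply_quality_filter(samples)
print(len(samples), len(kept), len(rejected))       # 600 546 54

offsets = compute_offsets(kept[~kept["is_infant"]])
s = summarize(offsets["offset_d15N"])
print(len(offsets), round(s.median, 2))             # 30 3.11
```

600 samples are generated (30 sites × 10 humans + 10 fauna); 54 fail the
preservation screens (the configured 9 % failure rate plus sampling noise).
All 30 sites retain ≥ 2 humans and ≥ 2 fauna, so 30 offset records result,
and the median δ¹⁵N offset of 3.11 ‰ recovers the configured trophic
enrichment of 3.1 ‰ — one trophic step between humans and their herd.

The full pipeline (simulate → qc → stats → hydro → wcon → cluster → tests)
runs from a YAML config:

```bash
paleoiso run --config examples/pipeline.yaml
```

and writes per-stage CSV/ASCII-grid outputs plus a provenance manifest
under the configured run directory.

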