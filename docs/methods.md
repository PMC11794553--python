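# Methods

This note documents the models behind `paleoiso`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions made where the design was genuinely open.

## Collagen quality control

Diagenesis alters buried collagen; the standard preservation screens reject
samples whose chemistry no longer looks like collagen. Defaults: atomic C/N
in [2.9, 3.6], collagen yield ≥ 1 % of bone mass, %C ≥ 13, %N ≥ 4.8 — the
widely used Ambrose/DeNiro windows. All four are configurable because
published datasets vary in which variant they applied; reproducing a
specific deposited dataset's kept/rejected partition generally requires
honouring that table's own pass/fail annotations rather than re-deriving
them, since yield thresholds in particular are often unreported.

Two contextual screens ride along: an explicit exclusion list (for
individually identified outliers, e.g. an extreme C/N-plausible but
isotopically impossible herbivore), and `require_period`, which drops rows
without a chronological assignment. Rejection is always annotated with
reason codes (`cn_out_of_range`, `low_yield`, `low_pctC`, `low_pctN`,
`explicit_exclusion`, `no_chronology`), the kept/rejected pair always
partitions the input, and rows lacking QC fields (literature data) pass the
numeric screens vacuously. A robust per-taxon flag (median ± 4·IQR) is
provided for scouting outlier candidates but is off by default — automatic
exclusion of extreme values would hide exactly the ecological signal
(canopy feeding, C4 input) the flags are meant to surface.

Dietary-signal flags on δ¹³C (never exclusionary): `c4_suspect` above
−18.00 ‰, `forest_freshwater_suspect` below −22.00 ‰.

## Summary statistics and offsets

Quartiles use linear interpolation between order statistics (R's default
"type 7", `numpy`'s `method="linear"`), the convention under which published
collagen summaries in this field are produced; it is configurable through
`summarize(..., method=...)`.

The trophic offset at a site is mean(human) − mean(fauna) per isotope,
where the faunal pool contains contemporaneous herbivores and omnivores
only — carnivores (dogs) and fish are excluded because they sit on other
trophic pathways; a flag reinstates fish when a freshwater baseline is
wanted. "Contemporaneous" means the same period label at the same site.
Both pools must hold at least two samples (`min_n=2`); that limit is
deliberately permissive to keep small sites in the analysis, and records
report both pool sizes so downstream users can weight or filter. Expected
values: δ¹⁵N offsets of 3–6 ‰ indicate a plain trophic step; offsets below
3 ‰ point to plant-dominated diets, negative δ¹³C offsets to human use of
resources (forest, freshwater) outside the herd's isotopic space.

Group differences are tested twice — one-way ANOVA and Kruskal–Wallis —
because collagen samples are small, unbalanced and often non-normal; both
results are always reported, uncorrected (a Holm option exists but is off
by default, mirroring common practice of reporting raw test tables).
Degenerate input with no variation anywhere returns H = F = 0, p = 1.
Cluster-by-region tables get a χ² test of independence with a Fisher exact
fallback for sparse 2×2 tables (any expected count < 5).

## Hydrology

Sink removal uses priority-flood filling with an epsilon gradient (default
1 × 10⁻⁴ m per step): cells inside depressions are raised to their spill
elevation plus a tiny increment so flats stay strictly drainable; cells not
in depressions are untouched, and the operation is idempotent. Nodata cells
count as off-grid boundary, so interior holes drain like edges.

Routing assigns each cell exactly one receiver. D8 takes the
steepest-descent neighbour (drop divided by distance, diagonals √2) and is
the deterministic default for tests. Rho8 (Fairfield & Leymarie) draws,
with a fixed seed, between the two neighbour directions bracketing the
cell's aspect — computed here from the vector sum of downslope gradients —
weighted by angular proximity, falling back to the steeper candidate when
one is not downslope. Accumulation processes cells in topological (Kahn)
order: ACC(c) = weight(c) + Σ ACC(upstream), so total input weight equals
total outflow through boundary outlets exactly.

Stream extraction thresholds ACC, keeps the largest 8-connected component,
and walks the main stem down the routing directions and up the
maximum-accumulation inflows from the component's highest-ACC cell.
Watersheds are reverse-reachability sets over the routing forest.

## Drought index (CON/wCON)

Both conditional rules are ordinal 4×4 lookup tables on quartile classes,
validated for monotonicity and replaceable by custom tables.

* Quartile classes: thresholds are type-7 quantiles (25/50/75 %) of the
  grid's own non-nodata values; intervals are right-closed (class = number
  of thresholds strictly below the value, plus one). Constant grids warn
  and collapse to one class; min–max rescaling maps a constant grid to 0,
  not NaN, so the quartile machinery always sees finite input.
* CON (default): clip(2 + P_class − T_class, 1, 4) — the wettest class is
  forced where precipitation is top-quartile and temperature
  bottom-quartile, the driest in the opposite corner, moderate classes in
  between; non-decreasing in P, non-increasing in T.
* wCON (default): the CON-quartile class QC shifted up one class where the
  rescaled flow accumulation is top-quartile (QA = 4), down one where
  bottom-quartile (QA = 1), unchanged in the middle. Valley floors
  collecting upslope runoff therefore read wetter than interfluves under
  identical climate.

Accumulation is recomputed per month with that month's precipitation as
cell weights over the fixed routing directions, so wCON carries the
seasonal rainfall signal through the drainage network. QA and QC quartiles
are likewise computed per month (recorded in the output provenance); the
alternative — pooling all months — would let wet-season months saturate the
class range and flatten dry-season contrast. All 24 class grids plus every
threshold triple and both rule tables are serialised (ASCII grids + JSON
sidecar).

## Catchment features and clustering

Each site is characterised by the raster cells whose centres lie within a
3000 m radius (a fixed square window of ⌈2r/cell⌉+1 cells, out-of-radius
cells dropped), giving identical vector lengths across sites: 12 monthly
wCON classes per cell plus a one-hot encoding of the cell's soil unit.
One-hot was chosen over raw soil IDs because the unit codes (10…90) are
nominal — treating them as numbers would impose a fake ordering; a raw-ID
mode exists for fidelity to analyses that did exactly that. Sites closer
than the radius to the raster edge raise by default (`edge_policy="pad"`
zero-pads instead).

The sites × features matrix is centred, constant columns dropped, and
reduced to the leading principal components holding ≥ 99 % of the variance.
Sites (not cells) are the observations, because the output is a site
typology. K-means uses k-means++ with 25 restarts and a fixed seed; k is
selected by the gap statistic (uniform reference over the observed feature
ranges, B = 50 replicates by default, firstSEmax rule — the smallest k with
gap(k) ≥ gap(k+1) − se(k+1)) and by the mean silhouette. The gap statistic
is implemented here directly from its definition and cross-checked in the
test suite against R's `cluster::clusGap` on a blob fixture. At full scale
the published analysis of this study area retained k = 9 over 30 candidate
k; desk-scale synthetic scenarios in this package use smaller k_max so the
reference draws stay cheap.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical structure* the pipeline assumes,
at sizes chosen so the full test suite runs in seconds on one CPU:

* Terrain: low-pass-filtered Gaussian noise (σ = 4 cells, 30 m relief) on a
  linear tilt towards one corner, on a 64×64 grid of 150 m cells —
  guaranteed drainable, with its global outlet on the boundary. No fluvial
  geomorphology, terracing or avulsion.
* Climate: one smooth spatial field per variable plus a shared seasonal
  sinusoid (T peaks in July at ±10.5 °C around a 10.5 °C mean; monthly P
  averages 50 mm ± 20 mm seasonally, near the ~500 mm annual rainfall of a
  dry continental plain), with an optional −6.5 °C/km elevation lapse on T.
  No weather, no interannual variability, no orographic rain shadows.
* Soils: nearest-seed (Voronoi) tessellation over the nine categorical
  units, cycling codes across patches. Composition and patchiness are
  realistic targets; pedogenesis is not attempted.
* Isotopes: faunal values Normal(baseline + regional/period group effect +
  site effect, 0.5 ‰) around −20.5 ‰ δ¹³C and 7.3 ‰ δ¹⁵N (C3-plain faunal
  medians); humans at the site's *empirical* faunal mean plus configurable
  trophic offsets (defaults 0.35 ‰ and 3.1 ‰, the observed offset medians
  in this study region), with 0.5 ‰ within-site noise — published IQRs of
  ~0.5–1 ‰ motivate that default, and it remains configurable because
  within-site variance is rarely reported directly. 9 % of rows receive
  failing QC chemistry (out-of-window C/N), 5 % of humans are flagged
  infants with +2 ‰ δ¹⁵N (breastfeeding enrichment). Generating truth is
  returned in a sidecar object, never in the sample table.

Anchoring humans to the empirical faunal mean makes the site-offset
statistic exactly unbiased by construction, which is what parameter-recovery
tests need; real humans of course do not sample their baseline without
error. Passing tests therefore demonstrate that the *pipeline* recovers
what its model assumes — not that real Carpathian data satisfy those
assumptions, and not that the desk-scale drought index reproduces the
full-basin raster products (which require external DEM/climate/soil
downloads; the configuration supports such runs but no test depends on
them).

## Numerical choices and limitations

* Determinism: every stochastic component (generators, Rho8, K-means, gap
  references) takes an explicit seed; pipeline reruns with the same config
  are byte-identical for deterministic stages.
* Ties and degenerate inputs: right-closed quantile intervals; constant
  grids rescale to 0 and classify (with a warning) into class 1; empty
  tables pass through QC as empty partitions; k_max < 2 returns k = 1 with
  a warning.
* The priority-flood epsilon (10⁻⁴ m) bounds pit-floor distortion but means
  filled elevations are not hydraulically exact over large flats.
* Rho8's aspect is derived from downslope gradients rather than a plane
  fit; over many seeds its mean direction approximates the aspect, which is
  the property the method needs.
* Site coordinates must be in a projected metric CRS; the 3000 m buffer
  math refuses nothing explicitly but is meaningless in degrees, so inputs
  must be pre-projected (the synthetic world is metric throughout).
* The CON/wCON rule tables of the original full-scale analysis live in that
  study's supplementary material; the monotone defaults here implement the
  published verbal semantics and verbatim tables can be dropped in as
  config.
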