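"""Synthetic terrain, climate, soils, sites, and collagen-isotope tables.

Everything downstream — QC, offsets, hydrology, drought index, clustering —
is testable against data whose generating parameters are known. The
generators emulate the statistical structure the analysis assumes, not the
physics behind it:

* terrain is low-pass-filtered Gaussian noise on a linear tilt, which
  guarantees a drainable surface with its global outlet on the boundary;
* climate is one smooth spatial field per variable plus a shared sinusoidal
  seasonal cycle (wet/cool winters against the warm, drier summer peak of a
  continental plain) and an optional elevation lapse on temperature;
* soils are a nearest-seed (Voronoi) mosaic over the nine categorical units
  10..90 used for Carpathian-Basin soil mapping;
* isotope tables draw faunal collagen values around a configurable baseline
  (defaults at the C3-plain values of roughly -20.5 permil d13C and
  7.3 permil d15N), add region/period group effects, then place humans at
  the site's empirical faunal mean plus a configurable trophic offset
  (defaults 0.35 and 3.1 permil), with within-site noise of 0.5 permil,
  a configurable fraction of failing-QC rows and of d15N-enriched infants.

True generating parameters are returned in a sidecar :class:`TruthParams`,
never inside the sample table, so recovery tests cannot leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import MonthlyClimate, RasterGrid

__all__ = [
    "SyntheticConfig",
    "TruthParams",
    "SOIL_CODES",
    "generate_terrain",
    "generate_climate",
    "generate_soils",
    "generate_sites",
    "generate_isotope_dataset",
]

#: categorical soil unit codes: 10 skeletal, 20 sand, 30 lithomorphic,
#: 40 brown forest, 50 chernozem, 60 salt-affected, 70 meadow, 80 peat,
#: 90 alluvial
SOIL_CODES = tuple(range(10, 100, 10))

_PERIODS = ("EN", "MN", "LN")
_REGIONS = ("Alfold", "Transdanubia")
_FAUNA_TAXA = (
    ("Bos taurus", "herbivore"),
    ("ovicaprid", "herbivore"),
    ("Sus domesticus", "omnivore"),
    ("Cervus elaphus", "herbivore"),
)


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic world; the seed fixes every output."""

    seed: int = 0
    grid_shape: tuple[int, int] = (64, 64)
    cell_size: float = 150.0
    n_sites: int = 30

    # terrain
    base_elevation: float = 100.0
    relief_amplitude: float = 30.0
    smoothing_sigma: float = 4.0
    tilt: tuple[float, float] = (0.4, 0.25)  # m per cell along (rows, cols)

    # climate
    p_offset: float = 50.0  # mm, monthly mean precipitation
    p_seasonal_amplitude: float = 20.0
    p_noise_sd: float = 6.0
    t_mean: float = 10.5  # degC annual mean
    t_seasonal_amplitude: float = 10.5
    t_noise_sd: float = 0.8
    t_lapse_per_m: float = 0.0065  # degC lost per metre of elevation

    # soils
    n_soil_patches: int = 36

    # isotope tables
    n_fauna_per_site: int = 5
    n_humans_per_site: int = 8
    fauna_baseline_d13C: float = -20.5
    fauna_baseline_d15N: float = 7.3
    trophic_offset_d13C: float = 0.35
    trophic_offset_d15N: float = 3.1
    group_effects: dict = field(default_factory=dict)  # (region, period) -> (dd13C, dd15N)
    site_effect_sd: float = 0.3
    noise_sd_d13C: float = 0.5
    noise_sd_d15N: float = 0.5
    frac_qc_fail: float = 0.09
    frac_infant: float = 0.05
    infant_enrichment_d15N: float = 2.0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        for name in ("frac_qc_fail", "frac_infant"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible generator per stream."""
        return np.random.default_rng([int(self.seed), int(stream)])


def _smooth_noise(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float, amplitude: float
) -> np.ndarray:
    if amplitude == 0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    span = smooth.max() - smooth.min()
    if span == 0:
        return np.zeros(shape)
    return (smooth - smooth.min()) / span * amplitude


def generate_terrain(cfg: SyntheticConfig) -> RasterGrid:
    """Smooth drainable surface: filtered noise plus a regional tilt.

    The tilt slopes towards the (0, 0) corner, placing the global outlet on
    the boundary; after sink filling, every cell drains there or off the
    nearer edge.
    """
    rows, cols = cfg.grid_shape
    if rows < 8 or cols < 8:
        raise ValueError("terrain grids need shape >= 8x8")
    rng = cfg.rng(1)
    rr, cc = np.mgrid[0:rows, 0:cols]
    z = (
        cfg.base_elevation
        + cfg.tilt[0] * rr
        + cfg.tilt[1] * cc
        + _smooth_noise(rng, (rows, cols), cfg.smoothing_sigma, cfg.relief_amplitude)
    )
    return RasterGrid(values=z, cell_size=cfg.cell_size, crs_label="synthetic-metric")


def generate_climate(
    cfg: SyntheticConfig, terrain: RasterGrid | None = None
) -> MonthlyClimate:
    """Twelve monthly P and T grids with a shared seasonal sinusoid.

    One fixed spatial field per variable (smoothed noise) is offset by a
    month-dependent seasonal term: temperature peaks in July, precipitation
    in June. With ``terrain`` given, temperature additionally falls with
    elevation at the configured lapse rate. Zero seasonal amplitude makes
    all twelve months identical.
    """
    rows, cols = cfg.grid_shape
    if terrain is not None:
        if terrain.shape != (rows, cols):
            raise ValueError("terrain shape does not match grid_shape")
        elev = terrain.values
    else:
        elev = np.zeros((rows, cols))

    rng = cfg.rng(2)
    p_field = _smooth_noise(rng, (rows, cols), cfg.smoothing_sigma, cfg.p_noise_sd * 6)
    t_field = _smooth_noise(rng, (rows, cols), cfg.smoothing_sigma, cfg.t_noise_sd * 6)

    p_grids, t_grids = [], []
    for month in range(1, 13):
        p_season = cfg.p_seasonal_amplitude * np.cos(2 * np.pi * (month - 6) / 12)
        t_season = cfg.t_seasonal_amplitude * np.cos(2 * np.pi * (month - 7) / 12)
        p = np.clip(cfg.p_offset + p_season + p_field, 0, None)
        t = cfg.t_mean + t_season + t_field - cfg.t_lapse_per_m * elev
        common = dict(cell_size=cfg.cell_size, crs_label="synthetic-metric")
        p_grids.append(RasterGrid(values=p, **common))
        t_grids.append(RasterGrid(values=t, **common))
    return MonthlyClimate(p=p_grids, t=t_grids)


def generate_soils(cfg: SyntheticConfig, n_patches: int | None = None) -> RasterGrid:
    """Categorical soil mosaic by nearest-seed tessellation.

    Patch classes cycle through the nine unit codes, so any mosaic with at
    least nine patches contains every class.
    """
    rows, cols = cfg.grid_shape
    n_patches = cfg.n_soil_patches if n_patches is None else n_patches
    if n_patches < 1:
        raise ValueError("need at least one soil patch")
    rng = cfg.rng(3)
    seeds_r = rng.uniform(0, rows, size=n_patches)
    seeds_c = rng.uniform(0, cols, size=n_patches)
    codes = np.array([SOIL_CODES[i % len(SOIL_CODES)] for i in range(n_patches)])
    order = rng.permutation(n_patches)
    codes = codes[order]

    rr, cc = np.mgrid[0:rows, 0:cols]
    d2 = (rr[..., None] - seeds_r) ** 2 + (cc[..., None] - seeds_c) ** 2
    nearest = np.argmin(d2, axis=-1)
    values = codes[nearest]
    assert np.isin(values, SOIL_CODES).all()
    return RasterGrid(values=values, cell_size=cfg.cell_size, crs_label="synthetic-metric")


def generate_sites(
    cfg: SyntheticConfig, margin_cells: int = 0
) -> pd.DataFrame:
    """Site table with projected coordinates, region, period, and culture.

    Sites fall on distinct cells at least ``margin_cells`` from the grid
    edge (set this to the catchment radius in cells when catchments will be
    extracted). Region follows the column coordinate — the western half is
    labelled Transdanubia, the eastern Alfold — mirroring a two-region study
    area split by a major river.
    """
    rows, cols = cfg.grid_shape
    lo_r, hi_r = margin_cells, rows - margin_cells
    lo_c, hi_c = margin_cells, cols - margin_cells
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("margin leaves no room for sites")
    n_cells = (hi_r - lo_r) * (hi_c - lo_c)
    if cfg.n_sites > n_cells:
        raise ValueError("more sites than available cells")
    rng = cfg.rng(4)
    flat = rng.choice(n_cells, size=cfg.n_sites, replace=False)
    r = lo_r + flat // (hi_c - lo_c)
    c = lo_c + flat % (hi_c - lo_c)

    grid = RasterGrid(values=np.zeros(cfg.grid_shape), cell_size=cfg.cell_size)
    records = []
    cultures = {
        ("Alfold", "EN"): "Koros",
        ("Alfold", "MN"): "ALBK",
        ("Alfold", "LN"): "Tisza",
        ("Transdanubia", "EN"): "Starcevo",
        ("Transdanubia", "MN"): "TLBK",
        ("Transdanubia", "LN"): "Lengyel",
    }
    for i in range(cfg.n_sites):
        region = _REGIONS[0] if c[i] >= cols / 2 else _REGIONS[1]
        period = _PERIODS[rng.integers(len(_PERIODS))]
        x, y = grid.cell_center(int(r[i]), int(c[i]))
        records.append(
            {
                "site_id": f"S{i + 1:03d}",
                "x": x,
                "y": y,
                "row": int(r[i]),
                "col": int(c[i]),
                "region": region,
                "period": period,
                "culture": cultures[(region, period)],
            }
        )
    return pd.DataFrame(records)


@dataclass
class TruthParams:
    """Generating truth for recovery tests; kept out of the sample table."""

    trophic_offset_d13C: float
    trophic_offset_d15N: float
    site_fauna_means: pd.DataFrame  # site_id, mean_d13C, mean_d15N
    qc_fail_ids: list[str]
    infant_ids: list[str]
    group_effects: dict


def _qc_fields(rng: np.random.Generator, n: int, fail: np.ndarray) -> dict:
    cn = rng.uniform(3.05, 3.45, size=n)
    cyield = rng.uniform(1.5, 9.0, size=n)
    pc = rng.uniform(35.0, 46.0, size=n)
    pn = rng.uniform(12.0, 16.5, size=n)
    # failing rows get a C/N ratio outside the preservation window
    cn[fail] = rng.uniform(3.8, 4.6, size=int(fail.sum()))
    return {"CN_atomic": cn, "collagen_yield": cyield, "pct_C": pc, "pct_N": pn}


def generate_isotope_dataset(
    cfg: SyntheticConfig, sites: pd.DataFrame
) -> tuple[pd.DataFrame, TruthParams]:
    """Human and faunal collagen table for the given sites.

    Per site, faunal values are Normal(baseline + group effect + site
    effect, noise_sd); humans sit at the site's *empirical* faunal mean plus
    the configured trophic offset, plus noise — so with zero noise the
    site-level offset statistic recovers the configured offset exactly.
    A configured fraction of rows receives failing QC fields; a configured
    fraction of humans is flagged (and d15N-enriched) as infants.
    """
    if sites.empty:
        cols = [
            "sample_id", "site_id", "lab_id", "taxon", "category", "period",
            "culture", "region", "bone_element", "d13C", "d15N",
            "collagen_yield", "pct_C", "pct_N", "CN_atomic", "is_infant", "source",
        ]
        truth = TruthParams(
            cfg.trophic_offset_d13C, cfg.trophic_offset_d15N,
            pd.DataFrame(columns=["site_id", "mean_d13C", "mean_d15N"]),
            [], [], dict(cfg.group_effects),
        )
        return pd.DataFrame(columns=cols), truth

    rng = cfg.rng(5)
    rows: list[dict] = []
    fauna_means = []
    for site in sites.itertuples(index=False):
        eff13, eff15 = cfg.group_effects.get((site.region, site.period), (0.0, 0.0))
        site13 = cfg.fauna_baseline_d13C + eff13 + rng.normal(0, cfg.site_effect_sd)
        site15 = cfg.fauna_baseline_d15N + eff15 + rng.normal(0, cfg.site_effect_sd)

        f13 = site13 + rng.normal(0, cfg.noise_sd_d13C, size=cfg.n_fauna_per_site)
        f15 = site15 + rng.normal(0, cfg.noise_sd_d15N, size=cfg.n_fauna_per_site)
        fauna_means.append(
            {"site_id": site.site_id, "mean_d13C": float(f13.mean()), "mean_d15N": float(f15.mean())}
        )
        for j in range(cfg.n_fauna_per_site):
            taxon, category = _FAUNA_TAXA[int(rng.integers(len(_FAUNA_TAXA)))]
            rows.append(
                {
                    "sample_id": f"{site.site_id}F{j + 1:02d}",
                    "site_id": site.site_id,
                    "taxon": taxon,
                    "category": category,
                    "period": site.period,
                    "culture": site.culture,
                    "region": site.region,
                    "bone_element": "long bone",
                    "d13C": float(f13[j]),
                    "d15N": float(f15[j]),
                    "is_infant": False,
                }
            )
        h13 = f13.mean() + cfg.trophic_offset_d13C + rng.normal(0, cfg.noise_sd_d13C, size=cfg.n_humans_per_site)
        h15 = f15.mean() + cfg.trophic_offset_d15N + rng.normal(0, cfg.noise_sd_d15N, size=cfg.n_humans_per_site)
        infant = rng.random(cfg.n_humans_per_site) < cfg.frac_infant
        h15 = h15 + np.where(infant, cfg.infant_enrichment_d15N, 0.0)
        for j in range(cfg.n_humans_per_site):
            rows.append(
                {
                    "sample_id": f"{site.site_id}H{j + 1:02d}",
                    "site_id": site.site_id,
                    "taxon": "Homo sapiens",
                    "category": "human",
                    "period": site.period,
                    "culture": site.culture,
                    "region": site.region,
                    "bone_element": "rib",
                    "d13C": float(h13[j]),
                    "d15N": float(h15[j]),
                    "is_infant": bool(infant[j]),
                }
            )

    table = pd.DataFrame(rows)
    n = len(table)
    fail = rng.random(n) < cfg.frac_qc_fail
    table = table.assign(**_qc_fields(rng, n, fail))
    table["lab_id"] = [f"LAB{i + 1:04d}" for i in range(n)]
    table["source"] = "new"
    table = table[
        [
            "sample_id", "site_id", "lab_id", "taxon", "category", "period",
            "culture", "region", "bone_element", "d13C", "d15N",
            "collagen_yield", "pct_C", "pct_N", "CN_atomic", "is_infant", "source",
        ]
    ]
    truth = TruthParams(
        trophic_offset_d13C=cfg.trophic_offset_d13C,
        trophic_offset_d15N=cfg.trophic_offset_d15N,
        site_fauna_means=pd.DataFrame(fauna_means),
        qc_fail_ids=table.loc[fail, "sample_id"].tolist(),
        infant_ids=table.loc[table["is_infant"], "sample_id"].tolist(),
        group_effects=dict(cfg.group_effects),
    )
    return table, truth
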