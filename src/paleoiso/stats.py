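"""Summary statistics, group tests, and site-level human-fauna offsets.

Quartiles follow the linear-interpolation convention between order statistics
(R's default, "type 7"), since published collagen summaries in this field are
produced that way; the convention is configurable. The trophic offset at a
site is the mean human value minus the mean value of contemporaneous
herbivores and omnivores from the same site, computed only where each pool
has at least two samples. Group differences are tested both parametrically
(one-way ANOVA) and rank-based (Kruskal-Wallis); cluster-by-region style
contingency tables get a chi-square test of independence with a Fisher exact
fallback for sparse 2x2 tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "OffsetRecord",
    "GroupTestResult",
    "CrosstabResult",
    "summarize",
    "compute_offsets",
    "group_tests",
    "crosstab_test",
    "CARNIVORE_TAXA",
    "OFFSET_EXCLUDED_CATEGORIES",
]

log = logging.getLogger(__name__)

#: taxa always treated as carnivores when categories are derived from taxon
CARNIVORE_TAXA = ("Canis familiaris",)
#: categories excluded from the faunal baseline pool of the offset
OFFSET_EXCLUDED_CATEGORIES = ("carnivore", "fish", "human", "unknown")


@dataclass
class SummaryStats:
    """Five-number summary of one isotope series."""

    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float


def summarize(
    values,
    exclude_infants: bool = False,
    infant_mask=None,
    method: str = "linear",
) -> SummaryStats:
    """Five-number summary with type-7 (linear interpolation) quartiles.

    ``values`` is any 1-D numeric sequence, or a DataFrame column passed with
    ``infant_mask`` to drop rows flagged as infants (breastfeeding enriches
    infant d15N by roughly a trophic step, so they distort population
    summaries).
    """
    vals = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce").dropna(), dtype=float)
    if exclude_infants:
        if infant_mask is None:
            raise ValueError("exclude_infants requires an infant_mask")
        mask = np.asarray(infant_mask, dtype=bool)
        raw = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), dtype=float)
        vals = raw[~mask & np.isfinite(raw)]
    if vals.size == 0:
        raise ValueError("no values left to summarize")
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method=method)
    return SummaryStats(
        n=int(vals.size),
        min=float(vals.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(vals.max()),
    )


@dataclass
class OffsetRecord:
    site_id: str
    period: str
    culture: str
    n_human: int
    n_fauna: int
    offset_d13C: float
    offset_d15N: float


def compute_offsets(samples: pd.DataFrame, min_n: int = 2) -> pd.DataFrame:
    """Site-level human-fauna offsets for contemporaneous pools.

    One record per (site, period) where at least ``min_n`` humans and
    ``min_n`` herbivores/omnivores coexist; carnivores and fish never enter
    the faunal baseline. Offsets are mean(human) - mean(fauna) for both
    isotopes. Sites failing the rule are skipped (and logged), never
    recorded.
    """
    required = {"site_id", "period", "category", "d13C", "d15N"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")

    records: list[OffsetRecord] = []
    for (site, period), grp in samples.groupby(["site_id", "period"], dropna=False, sort=True):
        humans = grp[grp["category"] == "human"]
        fauna = grp[~grp["category"].isin(OFFSET_EXCLUDED_CATEGORIES)]
        if len(humans) < min_n or len(fauna) < min_n:
            log.debug("skipping %s/%s: %d humans, %d fauna", site, period, len(humans), len(fauna))
            continue
        culture = ""
        if "culture" in grp.columns and not humans["culture"].dropna().empty:
            culture = str(humans["culture"].dropna().mode().iloc[0])
        records.append(
            OffsetRecord(
                site_id=str(site),
                period=str(period),
                culture=culture,
                n_human=len(humans),
                n_fauna=len(fauna),
                offset_d13C=float(humans["d13C"].mean() - fauna["d13C"].mean()),
                offset_d15N=float(humans["d15N"].mean() - fauna["d15N"].mean()),
            )
        )
    return pd.DataFrame([r.__dict__ for r in records], columns=[f.name for f in OffsetRecord.__dataclass_fields__.values()])


@dataclass
class GroupTestResult:
    """Parametric and rank-based one-way test results for one grouping."""

    grouping: str
    statistic_anova_F: float
    p_anova: float
    statistic_kw_H: float
    p_kw: float
    group_ns: dict


def group_tests(
    samples: pd.DataFrame, value: str = "d15N", grouping: str = "period"
) -> GroupTestResult:
    """One-way ANOVA and Kruskal-Wallis across the levels of one factor."""
    if value not in samples.columns or grouping not in samples.columns:
        raise ValueError(f"columns {value!r} and {grouping!r} required")
    groups = {
        str(name): pd.to_numeric(grp[value], errors="coerce").dropna().to_numpy()
        for name, grp in samples.groupby(grouping, dropna=True)
    }
    groups = {k: v for k, v in groups.items() if v.size > 0}
    if len(groups) < 2:
        raise ValueError("group tests require at least two non-empty groups")
    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # no variation anywhere: no evidence against equality by construction
        f_stat, p_f, h_stat, p_h = 0.0, 1.0, 0.0, 1.0
    else:
        f_stat, p_f = sps.f_oneway(*arrays)
        h_stat, p_h = sps.kruskal(*arrays)
    return GroupTestResult(
        grouping=grouping,
        statistic_anova_F=float(f_stat),
        p_anova=float(p_f),
        statistic_kw_H=float(h_stat),
        p_kw=float(p_h),
        group_ns={k: int(v.size) for k, v in groups.items()},
    )


@dataclass
class CrosstabResult:
    """Independence test on a contingency table."""

    grouping: str
    statistic: float
    p_value: float
    method: str
    table: np.ndarray


def crosstab_test(
    sites: pd.DataFrame | np.ndarray,
    rows: str = "cluster",
    cols: str = "region",
) -> CrosstabResult:
    """Chi-square test of independence on a site contingency table.

    Accepts either a site table (counted on ``rows`` x ``cols``) or a
    ready-made count matrix. Falls back to Fisher's exact test when any
    expected count of a 2x2 table is below 5.
    """
    if isinstance(sites, pd.DataFrame) and rows in sites.columns:
        table = pd.crosstab(sites[rows], sites[cols]).to_numpy()
    else:
        table = np.asarray(sites, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs at least 2x2 levels")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table: a margin is zero")

    chi2, p_chi, _, expected = sps.chi2_contingency(table)
    stat, p, method = float(chi2), float(p_chi), "chi-square"
    if table.shape == (2, 2) and (expected < 5).any():
        odds, p_fisher = sps.fisher_exact(table)
        stat, p, method = float(odds), float(p_fisher), "fisher-exact"
    return CrosstabResult(
        grouping=f"{rows}x{cols}", statistic=stat, p_value=p, method=method, table=table
    )
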