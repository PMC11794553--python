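"""Collagen preservation screening and contextual exclusions.

Diagenetically altered bone collagen gives isotope ratios that no longer
reflect diet, so samples are screened on quantitative collagen yield, the
atomic C/N ratio, and the elemental percentages of C and N. The default
windows are the standard Ambrose/DeNiro preservation criteria (atomic C/N in
[2.9, 3.6], yield >= 1 %, %C >= 13, %N >= 4.8); all are configurable.
Contextual screens — an explicit exclusion list for known outliers and a
chronology requirement — ride along with reason codes, so the kept/rejected
partition is always auditable. Literature rows that ship without QC fields
pass the numeric screens vacuously but still face the contextual ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "apply_quality_filter",
    "flag_dietary_outliers",
    "flag_robust_outliers",
    "C4_SUSPECT_D13C",
    "FOREST_FRESHWATER_D13C",
]

# d13C cut-offs (permil VPDB) for dietary-signal flags; flags never exclude.
C4_SUSPECT_D13C = -18.00
FOREST_FRESHWATER_D13C = -22.00

#: columns apply_quality_filter needs to see (QC fields may be null)
REQUIRED_COLUMNS = (
    "sample_id",
    "d13C",
    "d15N",
    "CN_atomic",
    "collagen_yield",
    "pct_C",
    "pct_N",
    "period",
)


@dataclass
class QCThresholds:
    """Preservation windows and contextual exclusion settings."""

    cn_min: float = 2.9
    cn_max: float = 3.6
    yield_min: float = 1.0
    pctC_min: float = 13.0
    pctN_min: float = 4.8
    exclusion_ids: list[str] = field(default_factory=list)
    require_period: bool = False

    def __post_init__(self) -> None:
        if not self.cn_min < self.cn_max:
            raise ValueError("cn_min must be below cn_max")
        if min(self.yield_min, self.pctC_min, self.pctN_min) < 0:
            raise ValueError("minimum thresholds must be non-negative")


def _check_schema(samples: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing required columns: {missing}")


def apply_quality_filter(
    samples: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a sample table into kept and rejected rows.

    Returns ``(kept, rejected)``; the rejected frame carries a
    ``reject_reason`` column of semicolon-joined codes drawn from
    ``cn_out_of_range``, ``low_yield``, ``low_pctC``, ``low_pctN``,
    ``explicit_exclusion`` and ``no_chronology``. A null QC field never
    triggers its numeric screen (literature rows lack them), and
    ``kept + rejected`` is always the input, row for row.
    """
    thresholds = thresholds or QCThresholds()
    _check_schema(samples)
    if samples.empty:
        empty = samples.copy()
        rejected = empty.copy()
        rejected["reject_reason"] = pd.Series(dtype=str)
        return empty, rejected

    cn = pd.to_numeric(samples["CN_atomic"], errors="coerce")
    cyield = pd.to_numeric(samples["collagen_yield"], errors="coerce")
    pc = pd.to_numeric(samples["pct_C"], errors="coerce")
    pn = pd.to_numeric(samples["pct_N"], errors="coerce")

    reasons = pd.DataFrame(index=samples.index)
    reasons["cn_out_of_range"] = cn.notna() & ~cn.between(thresholds.cn_min, thresholds.cn_max)
    reasons["low_yield"] = cyield.notna() & (cyield < thresholds.yield_min)
    reasons["low_pctC"] = pc.notna() & (pc < thresholds.pctC_min)
    reasons["low_pctN"] = pn.notna() & (pn < thresholds.pctN_min)
    reasons["explicit_exclusion"] = samples["sample_id"].isin(thresholds.exclusion_ids)
    if thresholds.require_period:
        period = samples["period"].astype("string")
        reasons["no_chronology"] = period.isna() | period.str.upper().eq("NA")
    else:
        reasons["no_chronology"] = False

    bad = reasons.any(axis=1)
    kept = samples.loc[~bad].copy()
    rejected = samples.loc[bad].copy()
    rejected["reject_reason"] = reasons.loc[bad].apply(
        lambda row: ";".join(code for code, hit in row.items() if hit), axis=1
    )
    return kept, rejected


def flag_dietary_outliers(samples: pd.DataFrame) -> pd.DataFrame:
    """Add advisory dietary-signal flags on d13C; never excludes rows.

    ``c4_suspect`` marks values above -18.00 permil (possible C4-plant input,
    or a post-Neolithic intrusion), ``forest_freshwater_suspect`` values
    below -22.00 permil (canopy or freshwater-resource signal).
    """
    if "d13C" not in samples.columns:
        raise ValueError("sample table has no d13C column")
    out = samples.copy()
    d13c = pd.to_numeric(out["d13C"], errors="coerce")
    out["c4_suspect"] = (d13c > C4_SUSPECT_D13C).fillna(False)
    out["forest_freshwater_suspect"] = (d13c < FOREST_FRESHWATER_D13C).fillna(False)
    return out


def flag_robust_outliers(
    samples: pd.DataFrame, value: str = "d13C", k: float = 4.0
) -> pd.DataFrame:
    """Optional per-taxon robust outlier flag: outside median +/- k*IQR.

    Off the main QC path by default — extreme individuals are handled by the
    explicit exclusion list — but useful to scout candidates.
    """
    out = samples.copy()
    vals = pd.to_numeric(out[value], errors="coerce")

    def _flag(group: pd.Series) -> pd.Series:
        med = group.median()
        iqr = group.quantile(0.75) - group.quantile(0.25)
        if not np.isfinite(iqr) or iqr == 0:
            return pd.Series(False, index=group.index)
        return (group - med).abs() > k * iqr

    key = out["taxon"] if "taxon" in out.columns else pd.Series("all", index=out.index)
    out[f"{value}_robust_outlier"] = (
        vals.groupby(key, group_keys=False).apply(_flag).reindex(out.index).fillna(False)
    )
    return out
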