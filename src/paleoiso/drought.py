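"""Monthly conditional drought/wetness index (CON) and its flow-weighted
refinement (wCON).

CON classifies each cell, month by month, from the quartile ranks of
precipitation (P) and temperature (T): low P with high T marks drought
vulnerability, high P with low T humid conditions, mid-quartile combinations
moderate conditions. wCON then folds in the landscape's water routing: the
quartile rank (QA) of that month's rainfall-weighted flow accumulation
raises or lowers the CON quartile rank (QC), so valley floors collecting
upslope runoff read wetter than interfluves under the same climate. Classes
are ordinal 1..4, increasing with wetness.

Both conditional rules are first-class 4x4 integer lookup tables: the
defaults implement the ordinal semantics above and custom tables (for
instance, the original analysis' own rule tables) can be dropped in, subject
to a monotonicity check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hydrology import NOFLOW, FlowField, accumulate
from .raster import MonthlyClimate, RasterGrid, minmax_rescale, write_ascii_grid

__all__ = [
    "DroughtIndex",
    "default_con_rule",
    "default_wcon_rule",
    "validate_rule",
    "quantile_classes",
    "monthly_con",
    "weighted_con",
    "build_drought_index",
]

N_CLASSES = 4


def default_con_rule() -> np.ndarray:
    """CON = clip(2 + P_class - T_class, 1, 4).

    Forces the wettest class at (P=4, T=1) and the driest at (P=1, T=4);
    non-decreasing in P and non-increasing in T everywhere.
    """
    p = np.arange(1, N_CLASSES + 1)[:, None]
    t = np.arange(1, N_CLASSES + 1)[None, :]
    return np.clip(2 + p - t, 1, N_CLASSES).astype(int)


def default_wcon_rule() -> np.ndarray:
    """wCON = QC shifted one class up in the top ACC quartile, one down in
    the bottom quartile, unchanged in between; clipped to 1..4."""
    qa = np.arange(1, N_CLASSES + 1)[:, None]
    qc = np.arange(1, N_CLASSES + 1)[None, :]
    shift = np.where(qa == N_CLASSES, 1, np.where(qa == 1, -1, 0))
    return np.clip(qc + shift, 1, N_CLASSES).astype(int)


def validate_rule(rule: np.ndarray, decreasing_axis: int | None = None) -> np.ndarray:
    """Check a 4x4 class-lookup table.

    The table must be integer-valued in 1..4 and monotone: non-decreasing
    along both axes, except that ``decreasing_axis`` (the T axis of the CON
    rule) must be non-increasing.
    """
    rule = np.asarray(rule, dtype=int)
    if rule.shape != (N_CLASSES, N_CLASSES):
        raise ValueError("rule table must be 4x4")
    if rule.min() < 1 or rule.max() > N_CLASSES:
        raise ValueError("rule classes must lie in 1..4")
    for axis in (0, 1):
        diffs = np.diff(rule, axis=axis)
        if axis == decreasing_axis:
            ok = (diffs <= 0).all()
        else:
            ok = (diffs >= 0).all()
        if not ok:
            raise ValueError(f"rule table not monotone along axis {axis}")
    return rule


def quantile_classes(
    grid: RasterGrid,
    probs: tuple[float, ...] = (0.25, 0.5, 0.75),
    return_thresholds: bool = False,
):
    """Classify cells into quartile classes 1..4 from the grid's own values.

    Thresholds are the (linear-interpolation) quantiles of the non-nodata
    cells; intervals are right-closed, i.e. a cell's class is the number of
    thresholds strictly below its value, plus one. A constant grid emits a
    warning and collapses to a single class.
    """
    mask = grid.valid_mask()
    vals = grid.values[mask].astype(float)
    if vals.size == 0:
        raise ValueError("cannot classify an all-nodata grid")
    thresholds = np.quantile(vals, probs)  # type 7 / linear interpolation
    if np.unique(vals).size < len(probs) + 1:
        warnings.warn(
            "fewer distinct values than classes; quantile classes degenerate",
            stacklevel=2,
        )
    classes = np.full(grid.shape, int(grid.nodata) if grid.nodata == int(grid.nodata) else -9999, dtype=int)
    classes[mask] = np.searchsorted(thresholds, grid.values[mask], side="left") + 1
    out = grid.with_values(np.where(mask, classes, grid.nodata))
    if return_thresholds:
        return out, thresholds
    return out


def _lookup(rule: np.ndarray, a: RasterGrid, b: RasterGrid) -> RasterGrid:
    mask = a.valid_mask() & b.valid_mask()
    ai = a.values.astype(int)
    bi = b.values.astype(int)
    out = np.full(a.shape, a.nodata, dtype=float)
    out[mask] = rule[ai[mask] - 1, bi[mask] - 1]
    return a.with_values(out)


def monthly_con(
    climate: MonthlyClimate, month: int, rule: np.ndarray | None = None
) -> RasterGrid:
    """One month's conditional climate classes from P and T quartile ranks."""
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    rule = default_con_rule() if rule is None else validate_rule(rule, decreasing_axis=1)
    p = minmax_rescale(climate.p[month - 1])
    t = minmax_rescale(climate.t[month - 1])
    p_cls = quantile_classes(p)
    t_cls = quantile_classes(t)
    return _lookup(rule, p_cls, t_cls)


def weighted_con(
    con: RasterGrid, acc_rescaled: RasterGrid, rule: np.ndarray | None = None
) -> RasterGrid:
    """Refine CON classes by the quartile rank of rescaled flow accumulation."""
    if con.shape != acc_rescaled.shape:
        raise ValueError("CON and ACC grids have different shapes")
    rule = default_wcon_rule() if rule is None else validate_rule(rule)
    qa = quantile_classes(acc_rescaled)
    qc = quantile_classes(con)
    return _lookup(rule, qa, qc)


@dataclass
class DroughtIndex:
    """Twelve monthly CON and wCON class grids plus every threshold used."""

    con: list
    wcon: list
    p_thresholds: list
    t_thresholds: list
    qa_thresholds: list
    qc_thresholds: list
    con_rule: np.ndarray
    wcon_rule: np.ndarray
    provenance: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> Path:
        """Write the 24 class grids as ASCII rasters plus a JSON sidecar."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for m in range(12):
            write_ascii_grid(self.con[m], out_dir / f"con_{m + 1:02d}.asc")
            write_ascii_grid(self.wcon[m], out_dir / f"wcon_{m + 1:02d}.asc")
        sidecar = {
            "p_thresholds": [list(map(float, t)) for t in self.p_thresholds],
            "t_thresholds": [list(map(float, t)) for t in self.t_thresholds],
            "qa_thresholds": [list(map(float, t)) for t in self.qa_thresholds],
            "qc_thresholds": [list(map(float, t)) for t in self.qc_thresholds],
            "con_rule": self.con_rule.tolist(),
            "wcon_rule": self.wcon_rule.tolist(),
            "provenance": self.provenance,
        }
        with open(out_dir / "drought_index.json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2)
        return out_dir


def build_drought_index(
    climate: MonthlyClimate,
    flow: FlowField,
    con_rule: np.ndarray | None = None,
    wcon_rule: np.ndarray | None = None,
) -> DroughtIndex:
    """Assemble the full 12-month CON/wCON index.

    Flow accumulation is recomputed for every month with that month's
    precipitation as the cell weights over the fixed routing directions, so
    wCON tracks the seasonal rainfall signal through the drainage network.
    QA and QC quartiles are computed per month.
    """
    if climate.shape != flow.shape:
        raise ValueError("climate and flow field grids have different shapes")
    con_rule = default_con_rule() if con_rule is None else validate_rule(con_rule, decreasing_axis=1)
    wcon_rule = default_wcon_rule() if wcon_rule is None else validate_rule(wcon_rule)

    con_grids, wcon_grids = [], []
    p_thr, t_thr, qa_thr, qc_thr = [], [], [], []
    for m in range(1, 13):
        p = minmax_rescale(climate.p[m - 1])
        t = minmax_rescale(climate.t[m - 1])
        p_cls, pt = quantile_classes(p, return_thresholds=True)
        t_cls, tt = quantile_classes(t, return_thresholds=True)
        con = _lookup(con_rule, p_cls, t_cls)

        acc_m = accumulate(flow.directions, climate.p[m - 1])
        acc_valid = np.where(flow.directions != NOFLOW, acc_m.values, acc_m.nodata)
        acc_rs = minmax_rescale(acc_m.with_values(acc_valid))
        qa, qat = quantile_classes(acc_rs, return_thresholds=True)
        qc, qct = quantile_classes(con, return_thresholds=True)
        wcon = _lookup(wcon_rule, qa, qc)

        con_grids.append(con)
        wcon_grids.append(wcon)
        p_thr.append(pt)
        t_thr.append(tt)
        qa_thr.append(qat)
        qc_thr.append(qct)

    provenance = {
        "routing_algorithm": flow.algorithm,
        "routing_seed": flow.seed,
        "qc_quartiles": "per month",
        "acc_weights": "monthly precipitation",
    }
    return DroughtIndex(
        con=con_grids,
        wcon=wcon_grids,
        p_thresholds=p_thr,
        t_thresholds=t_thr,
        qa_thresholds=qa_thr,
        qc_thresholds=qc_thr,
        con_rule=con_rule,
        wcon_rule=wcon_rule,
        provenance=provenance,
    )
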