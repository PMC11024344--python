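"""Scratch-wound and attachment (detachment) assay metrics.

Scratch ingression is ``1 - area(t) / area(0)``: 0 means no closure, 1
complete closure; each scratch is normalised to its own 0 h area.  Values
are not clamped — a widening scratch yields a negative, flagged value.

Attachment (adhesion) is read out as retention: post-detachment nucleus
count divided by the pre-detachment count of the same well, as a percent.
Wells are analysed in adjacent vehicle/treated pairs from the same plate
(matching physical handling); the treatment effect is the per-pair percent
reduction in retention, tested across experiment blocks with two-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .images import ImageStack
from .stats import StatsResult, compare_groups

__all__ = ["ScratchSeries", "WellPair", "scratch_area", "ingression",
           "count_nuclei", "retention", "paired_effect"]


@dataclass
class ScratchSeries:
    """Scratch areas over time for one well."""

    well_id: str
    condition: str
    timepoints_h: np.ndarray
    area_um2: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints_h = np.asarray(self.timepoints_h, float)
        self.area_um2 = np.asarray(self.area_um2, float)
        order = np.argsort(self.timepoints_h)
        self.timepoints_h = self.timepoints_h[order]
        self.area_um2 = self.area_um2[order]
        if self.timepoints_h[0] != 0:
            raise ValueError("series must include t = 0")
        if self.area_um2[0] <= 0:
            raise ValueError("area at t = 0 must be positive")


@dataclass
class WellPair:
    """An adjacent vehicle/treated well pair on one plate."""

    plate_id: str
    pair_id: int
    vehicle_pre: int
    vehicle_post: int
    treated_pre: int
    treated_post: int

    @property
    def vehicle_retention(self) -> float:
        return retention(self.vehicle_pre, self.vehicle_post)

    @property
    def treated_retention(self) -> float:
        return retention(self.treated_pre, self.treated_post)

    @property
    def percent_reduction(self) -> float:
        return 100.0 * (1.0 - self.treated_retention / self.vehicle_retention)


def scratch_area(img: ImageStack, channel: str | None = None,
                 threshold: float | str = "otsu",
                 min_area_um2: float = 500.0) -> float:
    """Area (µm²) of the contiguous cell-free region in a scratch image.

    The cell-free region is taken as the largest connected below-threshold
    component (Otsu by default).  Returns 0 with a warning on fully
    confluent images.
    """
    data = (img.channel(channel) if channel else img.pixels[0]).astype(float)
    if np.ptp(data) == 0:
        warnings.warn("uniform image: no cell-free region found")
        return 0.0
    thr = threshold_otsu(data) if threshold == "otsu" else float(threshold)
    free = data < thr
    labels, n = ndimage.label(free)
    if n == 0:
        warnings.warn("no cell-free region found")
        return 0.0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    px_area = img.pixel_size_um ** 2
    best = float(sizes.max()) * px_area
    if best < min_area_um2:
        warnings.warn("largest cell-free component below min_area; treating as 0")
        return 0.0
    return best


def ingression(series: ScratchSeries) -> pd.DataFrame:
    """Per-timepoint ingression ``1 - area(t)/area(0)``.

    Negative values (scratch widening) are reported, not clamped, and
    flagged in the ``widened`` column.
    """
    a0 = series.area_um2[0]
    vals = 1.0 - series.area_um2 / a0
    out = pd.DataFrame({"well_id": series.well_id, "condition": series.condition,
                        "time_h": series.timepoints_h, "ingression": vals,
                        "widened": vals < 0})
    return out


def count_nuclei(img: ImageStack, channel: str = "Hoechst",
                 threshold: float | str = "otsu",
                 min_area_um2: float = 20.0) -> int:
    """Count nuclei by threshold -> connected components -> size filter.

    The automated analogue of particle analysis on a thresholded image.
    Touching nuclei merge into one component and undercount; this is a
    property of the measurement, shared by pre and post images.
    """
    data = img.channel(channel).astype(float)
    if np.ptp(data) == 0:
        return 0
    thr = threshold_otsu(data) if threshold == "otsu" else float(threshold)
    fg = data > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    min_px = min_area_um2 / img.pixel_size_um ** 2
    return int(np.sum(sizes >= min_px))


def retention(pre_count: int, post_count: int) -> float:
    """Percent of cells retained after detachment: 100 * post / pre.

    Values above 100% (counting noise) are allowed with a warning.
    """
    if pre_count <= 0:
        raise ValueError("pre-detachment count must be positive")
    pct = 100.0 * post_count / pre_count
    if pct > 100.0:
        warnings.warn(f"retention {pct:.1f}% > 100% (counting noise?)")
    return pct


def paired_effect(pairs: list[WellPair] | pd.DataFrame,
                  treatment_col: str = "treatment",
                  vehicle_label: str = "vehicle") -> tuple[pd.DataFrame, StatsResult]:
    """Treatment effect on retention across paired wells and experiments.

    Accepts either :class:`WellPair` objects or a tidy per-well frame with
    columns ``experiment, pair_id, treatment, pre_count, post_count``.
    Returns (per-pair table with percent reduction; two-way stats with
    treatment and experiment as factors, per-well retention as response).
    The summary percent reduction is the mean ± SEM over pairs.
    """
    if isinstance(pairs, list):
        tidy = []
        for p in pairs:
            tidy.append({"experiment": p.plate_id, "pair_id": p.pair_id,
                         "treatment": vehicle_label, "pre_count": p.vehicle_pre,
                         "post_count": p.vehicle_post})
            tidy.append({"experiment": p.plate_id, "pair_id": p.pair_id,
                         "treatment": "treated", "pre_count": p.treated_pre,
                         "post_count": p.treated_post})
        wells = pd.DataFrame(tidy)
    else:
        wells = pairs.copy()
    required = {"experiment", "pair_id", treatment_col, "pre_count", "post_count"}
    if not required.issubset(wells.columns):
        raise ValueError(f"need columns {sorted(required)}")
    wells["retention_pct"] = [retention(a, b) for a, b in
                              zip(wells["pre_count"], wells["post_count"])]
    treatments = [t for t in pd.unique(wells[treatment_col]) if t != vehicle_label]
    if len(treatments) != 1:
        raise ValueError("exactly one non-vehicle treatment expected")
    treated_label = treatments[0]

    per_pair = []
    for (exp, pid), grp in wells.groupby(["experiment", "pair_id"], observed=True):
        v = grp.loc[grp[treatment_col] == vehicle_label, "retention_pct"]
        t = grp.loc[grp[treatment_col] == treated_label, "retention_pct"]
        if len(v) != 1 or len(t) != 1:
            warnings.warn(f"pair ({exp}, {pid}) incomplete; skipped")
            continue
        per_pair.append({"experiment": exp, "pair_id": pid,
                         "vehicle_retention_pct": float(v.iloc[0]),
                         "treated_retention_pct": float(t.iloc[0]),
                         "percent_reduction":
                         100.0 * (1.0 - float(t.iloc[0]) / float(v.iloc[0]))})
    per_pair = pd.DataFrame(per_pair)
    if len(per_pair) < 2:
        raise ValueError("need at least 2 complete pairs")

    n_exp = wells["experiment"].nunique()
    factors = [treatment_col, "experiment"] if n_exp > 1 else [treatment_col]
    stats = compare_groups(wells.rename(columns={"retention_pct": "value"}),
                           value="value", factors=factors)
    return per_pair, stats
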