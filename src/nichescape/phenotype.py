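"""Marker/morphology-based phenotyping of niche cells.

Cells arrive as a table of boolean marker calls plus morphology flags
(radial process, bipolar shape, primary dendrite) and an in-SGZ flag;
phenotypes are assigned by rule sets mirroring standard immunolabeling
practice in the dentate gyrus:

* ``reporter`` rules (recombination-reporter experiments): RGL-NSCs are
  EYFP+/GFAP+ with a radial process; IPCs are EYFP+/MCM2+ in the SGZ;
  neuroblasts are DCX+ bipolar cells in the SGZ; immature neurons are DCX+
  with a primary dendrite.
* ``antigen`` rules (antigen-only experiments): RGL-NSCs are GFAP+/SOX2+
  with a radial process; IPCs are GFAP-/SOX2+ in the SGZ; astrocytes are
  GFAP+/SOX2+ stellate (no radial process) cells outside the SGZ band.

Rules are applied in a fixed priority order (RGL-NSC > IPC > NB > IN >
astrocyte > other) so every cell receives exactly one label; multi-positive
edge cases resolve to the highest-priority match.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["PHENOTYPES", "RULE_SETS", "classify_cells", "composition",
           "count_colabeled", "call_markers_from_image"]

PHENOTYPES = ["RGL-NSC", "IPC", "astrocyte", "NB", "IN", "other"]

#: rule sets: (phenotype, required columns, vectorized predicate), priority order
RULE_SETS: dict[str, list[tuple[str, list[str], object]]] = {
    "reporter": [
        ("RGL-NSC", ["EYFP", "GFAP", "radial_process"],
         lambda v: v["EYFP"] & v["GFAP"] & v["radial_process"]),
        ("IPC", ["EYFP", "MCM2", "in_sgz"],
         lambda v: v["EYFP"] & v["MCM2"] & v["in_sgz"]),
        ("NB", ["DCX", "bipolar", "in_sgz"],
         lambda v: v["DCX"] & v["bipolar"] & v["in_sgz"]),
        ("IN", ["DCX", "primary_dendrite"],
         lambda v: v["DCX"] & v["primary_dendrite"]),
        ("astrocyte", ["GFAP", "radial_process", "in_sgz"],
         lambda v: v["GFAP"] & ~v["radial_process"] & ~v["in_sgz"]),
    ],
    "antigen": [
        ("RGL-NSC", ["GFAP", "SOX2", "radial_process"],
         lambda v: v["GFAP"] & v["SOX2"] & v["radial_process"]),
        ("IPC", ["GFAP", "SOX2", "in_sgz"],
         lambda v: ~v["GFAP"] & v["SOX2"] & v["in_sgz"]),
        ("NB", ["DCX", "bipolar", "in_sgz"],
         lambda v: v["DCX"] & v["bipolar"] & v["in_sgz"]),
        ("IN", ["DCX", "primary_dendrite"],
         lambda v: v["DCX"] & v["primary_dendrite"]),
        ("astrocyte", ["GFAP", "SOX2", "radial_process", "in_sgz"],
         lambda v: v["GFAP"] & v["SOX2"] & ~v["radial_process"] & ~v["in_sgz"]),
    ],
}

_COLUMN_ALIASES = {"GFP": "EYFP"}  # GFP reporter columns satisfy EYFP rules


def _get_bool(cells: pd.DataFrame, col: str) -> pd.Series:
    if col in cells.columns:
        return cells[col].fillna(False).astype(bool)
    for alias, target in _COLUMN_ALIASES.items():
        if col == target and alias in cells.columns:
            return cells[alias].fillna(False).astype(bool)
    raise KeyError(col)


def classify_cells(cells: pd.DataFrame, rule_set: str = "reporter") -> pd.DataFrame:
    """Assign one phenotype per cell; returns a copy with a ``phenotype`` column.

    Rules whose marker columns are entirely absent from the table raise a
    ``ValueError`` naming the rule, except the optional DCX-based rules,
    which are skipped when no DCX column exists (not every stain includes
    DCX).  Classification is row-wise, so the label distribution is
    invariant to row order.
    """
    if rule_set not in RULE_SETS:
        raise ValueError(f"unknown rule set {rule_set!r}; choose from {list(RULE_SETS)}")
    out = cells.copy()
    label = pd.Series("other", index=out.index, dtype=object)
    assigned = pd.Series(False, index=out.index)
    for pheno, required, predicate in RULE_SETS[rule_set]:
        cols = {}
        missing = []
        for c in required:
            try:
                cols[c] = _get_bool(out, c)
            except KeyError:
                missing.append(c)
        if missing:
            if "DCX" in missing:
                continue  # DCX rules optional when the stain lacks DCX
            raise ValueError(
                f"rule {pheno!r} ({rule_set}) needs missing column(s) {missing}"
            )
        hit = predicate(cols) & ~assigned
        label[hit] = pheno
        assigned |= hit
    out["phenotype"] = label
    return out


def composition(cells: pd.DataFrame, numerator: list[str] | str,
                denominator: pd.Series | None = None,
                by: str = "animal_id") -> pd.DataFrame:
    """Per-animal percent of cells (within a selection) of given phenotype(s).

    ``denominator`` is a boolean selection over rows (e.g. GFP+ cells);
    default all rows.  Returns a tidy frame with columns ``[by, phenotype,
    percent]`` where phenotypes iterate over ``numerator``; an exhaustive
    phenotype partition sums to 100% per animal.  Animals with an empty
    denominator get NaN.
    """
    if isinstance(numerator, str):
        numerator = [numerator]
    sel = cells if denominator is None else cells[np.asarray(denominator, bool)]
    rows = []
    for animal, sub in sel.groupby(by, observed=True):
        n = len(sub)
        for pheno in numerator:
            pct = float("nan") if n == 0 else 100.0 * (sub["phenotype"] == pheno).sum() / n
            rows.append({by: animal, "phenotype": pheno, "percent": pct})
    return pd.DataFrame(rows)


def count_colabeled(cells: pd.DataFrame, marker_a: str, marker_b: str,
                    by: str = "animal_id") -> pd.Series:
    """Count cells positive for both markers, per animal.

    Zero is a valid, expected outcome (e.g. no proliferating or apoptotic
    endothelia).  Symmetric in the two markers.
    """
    a = _get_bool(cells, marker_a)
    b = _get_bool(cells, marker_b)
    both = cells.loc[a & b]
    counts = both.groupby(by, observed=True).size()
    # include animals present in the table but with zero double-positives
    all_animals = pd.unique(cells[by])
    return counts.reindex(all_animals, fill_value=0).astype(int)


def call_markers_from_image(img, cells: pd.DataFrame, channels: list[str],
                            radius_um: float = 2.0) -> pd.DataFrame:
    """Helper: threshold per-channel intensities at nucleus neighborhoods into
    boolean marker calls (per-channel Otsu over the sampled neighborhoods).

    Annotation tables may instead supply calls directly, mirroring manual
    scoring by a blind observer.
    """
    from skimage.filters import threshold_otsu

    out = cells.copy()
    s = img.pixel_size_um
    r_px = max(1, int(round(radius_um / s)))
    rows, cols = img.um_to_pixel(cells["x_um"].to_numpy(), cells["y_um"].to_numpy())
    for ch in channels:
        data = img.channel(ch)
        vals = np.empty(len(cells))
        for i, (r, c) in enumerate(zip(rows, cols)):
            r0, r1 = max(0, r - r_px), min(data.shape[0], r + r_px + 1)
            c0, c1 = max(0, c - r_px), min(data.shape[1], c + r_px + 1)
            vals[i] = data[r0:r1, c0:c1].mean()
        thr = threshold_otsu(vals) if np.ptp(vals) > 0 else np.inf
        out[ch] = vals > thr
    return out
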