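"""Shared fixtures: small, fast synthetic inputs with known truth."""

import numpy as np
import pandas as pd
import pytest

from nichescape import NicheConfig, generate_niche


def small_config(**overrides) -> NicheConfig:
    """A reduced niche (shorter midline, fewer cells) for fast unit tests."""
    defaults = dict(
        image_size_px=(256, 768),
        n_cells_per_type={"RGL-NSC": 12, "IPC": 15, "astrocyte": 8,
                          "NB": 10, "IN": 8},
        n_sections=1,
        seed=0,
    )
    defaults.update(overrides)
    return NicheConfig(**defaults)


@pytest.fixture(scope="session")
def niche():
    """One small generated niche: (image, cells, midline, regions, truth)."""
    return generate_niche(small_config(seed=42))


def brute_force_distance(mask: np.ndarray, pixel_size_um: float = 1.0) -> np.ndarray:
    """Exhaustive nearest-vessel-pixel Euclidean distance, per pixel."""
    mask = np.asarray(mask, bool)
    out = np.full(mask.shape, np.inf)
    vr, vc = np.nonzero(mask)
    if len(vr) == 0:
        return out
    rr, cc = np.mgrid[: mask.shape[0], : mask.shape[1]]
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    vess = np.stack([vr, vc], axis=1).astype(float)
    # chunk to bound memory on 64x64 x n_vessel products
    for i in range(0, len(pts), 2048):
        chunk = pts[i:i + 2048]
        d2 = ((chunk[:, None, :] - vess[None, :, :]) ** 2).sum(-1)
        out.ravel()[i:i + 2048] = np.sqrt(d2.min(axis=1))
    return out * pixel_size_um


def brute_force_distance_at(mask: np.ndarray, rows, cols,
                            pixel_size_um: float = 1.0) -> np.ndarray:
    """Exhaustive nearest-vessel distance at specific pixel positions only."""
    vr, vc = np.nonzero(np.asarray(mask, bool))
    pts = np.column_stack([np.asarray(rows, float), np.asarray(cols, float)])
    vess = np.column_stack([vr, vc]).astype(float)
    d2 = ((pts[:, None, :] - vess[None, :, :]) ** 2).sum(-1)
    return np.sqrt(d2.min(axis=1)) * pixel_size_um


def brute_force_components(mask: np.ndarray, min_px: int = 1) -> int:
    """Count 4-connected foreground components of at least min_px pixels
    by explicit breadth-first traversal (independent of scipy labelling)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    n = 0
    nr, nc = mask.shape
    for r0 in range(nr):
        for c0 in range(nc):
            if mask[r0, c0] and not seen[r0, c0]:
                stack = [(r0, c0)]
                seen[r0, c0] = True
                size = 0
                while stack:
                    r, c = stack.pop()
                    size += 1
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nr and 0 <= cc < nc and mask[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                if size >= min_px:
                    n += 1
    return n


def toy_cells(**cols) -> pd.DataFrame:
    """One-row cell table with given marker/flag columns, rest defaulted False."""
    base = {"cell_id": "c1", "animal_id": "m1", "group": "WT",
            "x_um": 1.0, "y_um": 1.0, "EYFP": False, "GFAP": False,
            "SOX2": False, "MCM2": False, "DCX": False, "Hoechst": True,
            "radial_process": False, "bipolar": False,
            "primary_dendrite": False, "in_sgz": False}
    base.update(cols)
    return pd.DataFrame([base])
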