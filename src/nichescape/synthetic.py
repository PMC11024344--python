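"""Synthetic neurovascular-niche data with known ground truth.

This module simulates the statistical structure of dentate-gyrus niche
measurements so that every pipeline stage can be validated against truth:

* a curvilinear capillary network concentrated around the SGZ band,
  rendered into a CD31-like channel as tubes of configurable radius;
* a dense Hoechst nucleus field along the SGZ midline;
* phenotype-labelled cells whose nearest-vessel distance distribution is
  shifted by a configurable offset relative to the random-nucleus baseline
  (the generator's ground-truth analogue of "closer/farther than random");
* per-animal cohorts with normally distributed animal-level offsets;
* RNAscope-like images with Poisson puncta counts per nucleus;
* scratch-wound area time series and pre/post detachment nuclei fields
  with configurable retention fractions.

Cells with a target mean offset are drawn from a large candidate pool of
in-band positions by exponential tilting of the pool's empirical distance
distribution: weights ``exp(lam * d)`` with ``lam`` solved so the weighted
mean equals (baseline + offset).  This realises the offset as a property of
the *mean*, not of each cell, which is how the study reports it.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning; identical configs and seeds give
bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.interpolate import splev, splprep
from shapely.geometry import Polygon

from .geometry import MidlinePolyline, RegionMap
from .images import ImageStack
from .vessels import DistanceField, VesselMask, distance_field

__all__ = [
    "NoiseModel", "NicheConfig", "NicheTruth", "NicheSection", "AnimalNiche",
    "generate_niche", "generate_cohort", "generate_puncta_image",
    "generate_scratch_series", "render_scratch_image",
    "generate_attachment_plate",
]

PHENOTYPES = ["RGL-NSC", "IPC", "astrocyte", "NB", "IN", "other"]
_HILAR_PHENOTYPES = {"astrocyte"}  # placed in the hilar strip, not the band


@dataclass
class NoiseModel:
    """Additive read noise plus intensity-proportional shot noise.

    Pixel values are ``signal + N(0, sqrt(read_sd^2 + shot_k * signal))``,
    clipped at zero.  Defaults approximate a moderately clean widefield
    acquisition with background well separated from foreground.
    """

    background: float = 100.0
    foreground: float = 800.0
    read_sd: float = 15.0
    shot_k: float = 0.5


@dataclass
class NicheConfig:
    """Parameters of one synthetic niche image/section.

    Attributes
    ----------
    image_size_px:
        (rows, cols).  With the default pixel size the default frame spans
        192 x 800 µm, enough midline for ~8 systematic null samples at
        100 µm spacing.
    pixel_size_um:
        µm per pixel (default 0.5, a 20x air objective scale).
    midline_control_points_um:
        Polyline control points of the SGZ midline; ``None`` builds a
        gentle sinusoid spanning the frame.
    band_halfwidth_um:
        Half-width of the SGZ band ("two cell body widths" total,
        default 10 µm).
    vessel_density_um_per_um2:
        Expected capillary centreline length per unit area of the
        perivascular corridor around the band.
    vessel_radius_um:
        Capillary tube radius (default 2.5 µm, i.e. ~5 µm diameter).
    n_cells_per_type:
        Phenotype -> number of cells to place in one section.
    n_sections:
        Tissue sections imaged per animal (cohorts average per-animal
        measures over sections, as section series from one mouse would be).
    distance_offset_um:
        Ground-truth shift of each phenotype's mean nearest-vessel
        distance relative to the random-nucleus baseline.  Accepted
        shapes: ``{(phenotype, group): µm}``, ``{group: {phenotype: µm}}``
        or ``{phenotype: µm}`` (all groups).
    hoechst_density_per_100um:
        Random nuclei per 100 µm of midline arc length.
    """

    image_size_px: tuple[int, int] = (384, 1600)
    pixel_size_um: float = 0.5
    midline_control_points_um: np.ndarray | None = None
    band_halfwidth_um: float = 10.0
    vessel_density_um_per_um2: float = 0.05
    vessel_radius_um: float = 2.5
    n_sections: int = 4
    n_cells_per_type: dict[str, int] = field(
        default_factory=lambda: {"RGL-NSC": 15, "IPC": 20, "astrocyte": 10,
                                 "NB": 15, "IN": 12})
    distance_offset_um: dict = field(default_factory=dict)
    hoechst_density_per_100um: float = 30.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    group: str = "WT"
    animal_id: str = "A1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in [("pixel_size_um", self.pixel_size_um),
                        ("band_halfwidth_um", self.band_halfwidth_um),
                        ("vessel_radius_um", self.vessel_radius_um),
                        ("hoechst_density_per_100um", self.hoechst_density_per_100um)]:
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive")
        nr, nc = self.image_size_px
        extent = min(nr, nc) * self.pixel_size_um
        if self.band_halfwidth_um >= extent / 4:
            raise ValueError("band_halfwidth_um must be < min image extent / 4")
        for ph in self.n_cells_per_type:
            if ph not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {ph!r}; use one of {PHENOTYPES}")

    def offset_for(self, phenotype: str, group: str | None = None) -> float:
        """Resolve the configured offset for (phenotype, group); default 0."""
        group = group if group is not None else self.group
        off = self.distance_offset_um
        if (phenotype, group) in off:
            return float(off[(phenotype, group)])
        if group in off and isinstance(off[group], dict):
            return float(off[group].get(phenotype, 0.0))
        if phenotype in off and not isinstance(off[phenotype], dict):
            return float(off[phenotype])
        return 0.0


@dataclass
class NicheTruth:
    """Ground truth recorded by a generator; the oracle for recovery tests."""

    cells: pd.DataFrame | None = None           # cell_id, phenotype, x/y, true dist
    nuclei: pd.DataFrame | None = None          # random Hoechst nuclei + distances
    vessel_mask: np.ndarray | None = None
    random_baseline_um: float | None = None     # mean distance of a random nucleus
    offsets_um: dict = field(default_factory=dict)      # (phenotype -> target offset)
    realized_offsets_um: dict = field(default_factory=dict)
    puncta_counts: pd.DataFrame | None = None   # nucleus_id, phenotype, count, merged
    scratch_areas: pd.DataFrame | None = None   # condition, time_h, area (noiseless)
    wells: pd.DataFrame | None = None           # well/pair table with true fractions
    retention: dict = field(default_factory=dict)


@dataclass
class NicheSection:
    """One simulated tissue section: image, cells, geometry, truth."""

    image: ImageStack
    cells: pd.DataFrame
    midline: MidlinePolyline
    regions: RegionMap
    truth: NicheTruth


@dataclass
class AnimalNiche:
    """One simulated animal: a series of sections plus its true offsets."""

    animal_id: str
    group: str
    sections: list[NicheSection]
    true_offsets_um: dict = field(default_factory=dict)  # phenotype -> µm

    @property
    def cells(self) -> pd.DataFrame:
        """All cells of the animal, across sections."""
        return pd.concat([s.cells for s in self.sections], ignore_index=True)


# ---------------------------------------------------------------------------
# midline machinery


class _MidlineFrame:
    """Dense arc-length parameterisation of a midline polyline.

    Provides points, unit normals (pointing toward the hilus, +offset side)
    and mapping (s, t) -> (x, y) for placing structures in band coordinates.
    """

    def __init__(self, vertices: np.ndarray, step_um: float = 1.0):
        v = np.asarray(vertices, float)
        if len(v) >= 4:
            # smooth cubic spline: analytic tangents, no kink jitter in the
            # normals (kinks would make offset curves self-intersect)
            tck, _ = splprep([v[:, 0], v[:, 1]], s=0, k=3)
            u = np.linspace(0, 1, max(len(v) * 16, 256))
            x, y = splev(u, tck)
            dx, dy = splev(u, tck, der=1)
        else:
            seg = np.hypot(*np.diff(v, axis=0).T)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            u = np.linspace(0, cum[-1], max(int(cum[-1]), 8))
            x = np.interp(u, cum, v[:, 0])
            y = np.interp(u, cum, v[:, 1])
            dx, dy = np.gradient(x, u), np.gradient(y, u)
        x, y, dx, dy = map(np.asarray, (x, y, dx, dy))
        seg = np.hypot(np.diff(x), np.diff(y))
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        self.length = float(cum[-1])
        n = max(int(self.length / step_um), 8)
        self.s = np.linspace(0, self.length, n)
        self.x = np.interp(self.s, cum, x)
        self.y = np.interp(self.s, cum, y)
        norm = np.hypot(dx, dy)
        tx = np.interp(self.s, cum, dx / norm)
        ty = np.interp(self.s, cum, dy / norm)
        norm = np.hypot(tx, ty)
        tx, ty = tx / norm, ty / norm
        nx, ny = -ty, tx
        if ny.mean() < 0:  # orient normals toward +y (hilus side)
            nx, ny = -nx, -ny
        self.nx, self.ny = nx, ny

    def at(self, s, t):
        """Map arc length ``s`` and signed normal offset ``t`` to (x, y) µm."""
        s = np.asarray(s, float)
        t = np.asarray(t, float)
        x = np.interp(s, self.s, self.x) + t * np.interp(s, self.s, self.nx)
        y = np.interp(s, self.s, self.y) + t * np.interp(s, self.s, self.ny)
        return x, y

    def offset_polyline(self, t: float) -> np.ndarray:
        return np.column_stack([self.x + t * self.nx, self.y + t * self.ny])


def _default_midline(config: NicheConfig) -> np.ndarray:
    nr, nc = config.image_size_px
    w = nc * config.pixel_size_um
    h = nr * config.pixel_size_um
    margin = 4 * config.band_halfwidth_um
    x = np.linspace(margin, w - margin, 64)
    wavelength = w / 2
    # keep the curvature radius above the outermost region offset so the
    # offset band polygons stay simple
    amp = min(15.0, h / 8, wavelength ** 2 / (4 * np.pi ** 2 * 150.0))
    y = h / 2 + amp * np.sin(2 * np.pi * x / wavelength)
    return np.column_stack([x, y])


def _truncnorm(rng: np.random.Generator, sd: float, lo: float, hi: float,
               size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(0.0, sd, size=2 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# vessels


def _generate_vessel_mask(config: NicheConfig, frame: _MidlineFrame,
                          rng: np.random.Generator) -> np.ndarray:
    """Planar capillary network near the band, dilated to tube radius.

    SGZ capillary architecture is stereotyped: a set of long, roughly
    midline-parallel capillaries spans the band corridor.  Lanes are evenly
    spaced across the corridor (count set by ``vessel_density_um_per_um2``)
    with per-animal jitter of their offsets and a smooth transverse meander
    along their length, so different simulated animals share the same
    statistical architecture without sharing the exact vessel positions.
    """
    nr, nc = config.image_size_px
    s_px = config.pixel_size_um
    corridor = config.band_halfwidth_um + 15.0
    # lane count from the corridor's expected vessel length per area,
    # discounted by the capillary gap fraction
    gap_fraction = 0.35
    gap_scale_um = 60.0
    n_lanes = max(2, int(round(config.vessel_density_um_per_um2 * 2 * corridor
                               / (1.0 - gap_fraction))))
    lane_offsets = np.linspace(-corridor + 3.0, corridor - 3.0, n_lanes)
    centerline = np.zeros((nr, nc), bool)
    for t_lane in lane_offsets:
        t0 = t_lane + rng.normal(0.0, 2.0)
        n_ctrl = max(6, int(frame.length / 60.0))
        s_ctrl = np.linspace(0.0, frame.length, n_ctrl)
        meander = np.cumsum(rng.normal(0.0, 3.0, n_ctrl))
        meander -= np.linspace(meander[0], meander[-1], n_ctrl)  # stay in lane
        t_ctrl = np.clip(t0 + meander, -corridor, corridor)
        xc, yc = frame.at(s_ctrl, t_ctrl)
        tck, _ = splprep([xc, yc], s=0, k=min(3, n_ctrl - 1))
        n_dense = int(frame.length / (0.4 * s_px)) + 2
        u = np.linspace(0, 1, n_dense)
        xs, ys = splev(u, tck)
        # capillaries are discontinuous in any single plane: alternate
        # present/absent runs along the lane (exponential run lengths)
        present = np.ones(n_dense, bool)
        pos = 0.0
        on = rng.uniform() > gap_fraction
        s_dense = u * frame.length
        while pos < frame.length:
            mean_run = (gap_scale_um * (1 - gap_fraction) / gap_fraction
                        if on else gap_scale_um)
            run = rng.exponential(mean_run)
            if not on:
                present[(s_dense >= pos) & (s_dense < pos + run)] = False
            pos += run
            on = not on
        cols = np.floor(np.asarray(xs)[present] / s_px).astype(int)
        rows = np.floor(np.asarray(ys)[present] / s_px).astype(int)
        ok = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
        centerline[rows[ok], cols[ok]] = True
    if not centerline.any():
        return centerline
    dist = ndimage.distance_transform_edt(~centerline, sampling=s_px)
    return dist <= config.vessel_radius_um


# ---------------------------------------------------------------------------
# cell placement by exponential tilting


def _tilted_sample(dists: np.ndarray, target_mean: float, n: int,
                   rng: np.random.Generator, label: str) -> np.ndarray:
    """Indices of ``n`` pool members whose expected mean distance is
    ``target_mean``, via exponential tilting of the empirical pool.

    Targets slightly outside the achievable range (as can happen when an
    animal-level deviate meets an unusually vessel-rich section) are clamped
    to the range edge with a warning; targets far outside (> 1 µm beyond)
    are infeasible and raise.
    """
    lo, hi = float(dists.min()), float(dists.max())
    span = hi - lo
    lo_t, hi_t = lo + 0.02 * span, hi - 0.02 * span
    if not (lo_t <= target_mean <= hi_t):
        clamped = min(max(target_mean, lo_t), hi_t)
        if abs(clamped - target_mean) > max(1.0, 0.02 * span):
            raise ValueError(
                f"infeasible distance offset for {label}: target mean "
                f"{target_mean:.2f} µm outside achievable range "
                f"({lo:.2f}, {hi:.2f}) µm")
        warnings.warn(f"target mean for {label} clamped from "
                      f"{target_mean:.2f} to {clamped:.2f} µm")
        target_mean = clamped

    d0 = dists - dists.mean()

    def tilted_mean(lam: float) -> float:
        w = np.exp(lam * d0 - np.max(lam * d0))
        return float(np.sum(w * dists) / np.sum(w))

    f = lambda lam: tilted_mean(lam) - target_mean  # noqa: E731
    lam_lo, lam_hi = -1.0, 1.0
    while f(lam_lo) > 0 and lam_lo > -80:
        lam_lo *= 2
    while f(lam_hi) < 0 and lam_hi < 80:
        lam_hi *= 2
    lam = optimize.brentq(f, lam_lo, lam_hi, xtol=1e-6)
    w = np.exp(lam * d0 - np.max(lam * d0))
    p = w / w.sum()
    return rng.choice(len(dists), size=n, replace=False, p=p)


# ---------------------------------------------------------------------------
# rendering


def _stamp_disks(canvas: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                 radius_px: float, value: float) -> None:
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    stamp = (yy ** 2 + xx ** 2 <= radius_px ** 2) * value
    nr, nc = canvas.shape
    for rr, cc in zip(rows, cols):
        r0, r1 = rr - r, rr + r + 1
        c0, c1 = cc - r, cc + r + 1
        sr0, sc0 = max(0, -r0), max(0, -c0)
        r0, c0 = max(0, r0), max(0, c0)
        r1, c1 = min(nr, r1), min(nc, c1)
        if r1 <= r0 or c1 <= c0:
            continue
        patch = stamp[sr0:sr0 + (r1 - r0), sc0:sc0 + (c1 - c0)]
        np.maximum(canvas[r0:r1, c0:c1], patch, out=canvas[r0:r1, c0:c1])


def _apply_noise(signal: np.ndarray, noise: NoiseModel,
                 rng: np.random.Generator) -> np.ndarray:
    sd = np.sqrt(noise.read_sd ** 2 + noise.shot_k * np.maximum(signal, 0.0))
    out = signal + rng.normal(0.0, 1.0, signal.shape) * sd
    return np.clip(out, 0.0, None).astype(np.float32)


# ---------------------------------------------------------------------------
# main generators


def _build_regions(config: NicheConfig, frame: _MidlineFrame) -> RegionMap:
    hw = config.band_halfwidth_um
    gcl = 60.0  # granule cell layer thickness, µm
    ml = 60.0   # molecular layer band, µm
    hl = 60.0   # hilus strip, µm
    bands = {
        "ML": (-(hw + gcl + ml), -(hw + gcl)),
        "GCL": (-(hw + gcl), -hw),
        "SGZ": (-hw, hw),
        "HL": (hw, hw + hl),
    }
    regions = {}
    for name, (a, b) in bands.items():
        top = frame.offset_polyline(a)
        bot = frame.offset_polyline(b)[::-1]
        regions[name] = Polygon(np.vstack([top, bot]))
    return RegionMap(regions)


def generate_niche(config: NicheConfig) -> tuple[ImageStack, pd.DataFrame,
                                                 MidlinePolyline, RegionMap,
                                                 NicheTruth]:
    """Simulate one niche section with known ground truth.

    Returns the rendered image (CD31 + Hoechst channels), the cell table
    (markers and morphology flags consistent with both shipped rule sets),
    the SGZ midline, a subregion map (ML/GCL/SGZ/HL) and the truth record.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    nr, nc = config.image_size_px
    s_px = config.pixel_size_um

    verts = (config.midline_control_points_um
             if config.midline_control_points_um is not None
             else _default_midline(config))
    midline = MidlinePolyline(np.asarray(verts, float), config.band_halfwidth_um)
    frame = _MidlineFrame(midline.vertices)
    regions = _build_regions(config, frame)

    vessel_mask = _generate_vessel_mask(config, frame, rng)
    vm = VesselMask(vessel_mask, s_px)
    dfield = distance_field(vm)

    hw = config.band_halfwidth_um

    def band_pool(n: int, hilar: bool) -> tuple[np.ndarray, np.ndarray]:
        s = rng.uniform(0.0, frame.length, n)
        if hilar:
            t = rng.uniform(hw + 4.0, hw + 30.0, n)
        else:
            t = _truncnorm(rng, hw / 2.0, -hw, hw, n)
        x, y = frame.at(s, t)
        x = np.clip(x, 0.5 * s_px, nc * s_px - 0.5 * s_px)
        y = np.clip(y, 0.5 * s_px, nr * s_px - 0.5 * s_px)
        return x, y

    # random Hoechst nuclei along the band (the null population)
    n_nuc = max(2, int(round(config.hoechst_density_per_100um
                             * frame.length / 100.0)))
    nx_um, ny_um = band_pool(n_nuc, hilar=False)
    nuc_d = dfield.at(nx_um, ny_um)
    nuclei = pd.DataFrame({"nucleus_id": np.arange(n_nuc), "x_um": nx_um,
                           "y_um": ny_um, "true_dist_um": nuc_d})

    # candidate pool shared distributionally with the nuclei: its mean
    # distance is the random-nucleus baseline the offsets are defined against
    pool_n = max(4000, 60 * max(config.n_cells_per_type.values(), default=0))
    px_um, py_um = band_pool(pool_n, hilar=False)
    pool_d = dfield.at(px_um, py_um)
    baseline = float(pool_d.mean())

    hx_um, hy_um = band_pool(pool_n // 4, hilar=True)
    hpool_d = dfield.at(hx_um, hy_um)
    hilar_baseline = float(hpool_d.mean())

    rows = []
    realized: dict[str, float] = {}
    offsets: dict[str, float] = {}
    cid = 0
    for pheno, n_cells in config.n_cells_per_type.items():
        if n_cells <= 0:
            continue
        off = config.offset_for(pheno, config.group)
        offsets[pheno] = off
        hilar = pheno in _HILAR_PHENOTYPES
        pool_x, pool_y, pool_dist, base = (
            (hx_um, hy_um, hpool_d, hilar_baseline) if hilar
            else (px_um, py_um, pool_d, baseline))
        if off == 0.0:
            idx = rng.choice(len(pool_dist), size=n_cells, replace=False)
        else:
            idx = _tilted_sample(pool_dist, base + off, n_cells, rng,
                                 f"phenotype {pheno!r} (offset {off:+.3f} µm)")
        cx, cy, cd = pool_x[idx], pool_y[idx], pool_dist[idx]
        realized[pheno] = float(cd.mean()) - base
        m = _marker_profile(pheno)
        in_band = midline.in_band(np.column_stack([cx, cy]))
        for x, y, d, ib in zip(cx, cy, cd, in_band):
            rows.append({"cell_id": f"{config.animal_id}-c{cid}",
                         "animal_id": config.animal_id, "group": config.group,
                         "x_um": float(x), "y_um": float(y),
                         "phenotype_true": pheno, "true_dist_um": float(d),
                         "in_sgz": bool(ib), **m})
            cid += 1
    cells = pd.DataFrame(rows)

    # render channels
    cd31 = np.where(vessel_mask, config.noise.foreground, 0.0)
    cd31 = ndimage.gaussian_filter(cd31, sigma=1.0) + config.noise.background
    hoechst = np.zeros((nr, nc), float)
    all_x = np.concatenate([nx_um, cells["x_um"].to_numpy()]) if len(cells) else nx_um
    all_y = np.concatenate([ny_um, cells["y_um"].to_numpy()]) if len(cells) else ny_um
    rr = np.clip(np.floor(all_y / s_px).astype(int), 0, nr - 1)
    cc = np.clip(np.floor(all_x / s_px).astype(int), 0, nc - 1)
    _stamp_disks(hoechst, rr, cc, radius_px=2.5 / s_px,
                 value=config.noise.foreground)
    hoechst = ndimage.gaussian_filter(hoechst, sigma=1.0) + config.noise.background
    img = ImageStack(
        np.stack([_apply_noise(cd31, config.noise, rng),
                  _apply_noise(hoechst, config.noise, rng)]),
        ["CD31", "Hoechst"], s_px)

    truth = NicheTruth(cells=cells.copy(), nuclei=nuclei,
                       vessel_mask=vessel_mask,
                       random_baseline_um=baseline,
                       offsets_um=offsets, realized_offsets_um=realized)
    return img, cells, midline, regions, truth


def _marker_profile(pheno: str) -> dict:
    base = {"EYFP": False, "GFAP": False, "SOX2": False, "MCM2": False,
            "DCX": False, "BrdU": False, "CD31": False, "aCas3": False,
            "Hoechst": True, "radial_process": False, "bipolar": False,
            "primary_dendrite": False}
    if pheno == "RGL-NSC":
        base.update(EYFP=True, GFAP=True, SOX2=True, radial_process=True)
    elif pheno == "IPC":
        base.update(EYFP=True, SOX2=True, MCM2=True)
    elif pheno == "astrocyte":
        base.update(GFAP=True, SOX2=True)
    elif pheno == "NB":
        base.update(EYFP=True, DCX=True, bipolar=True)
    elif pheno == "IN":
        base.update(EYFP=True, DCX=True, primary_dendrite=True)
    return base


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2 ** 31))


def generate_cohort(config: NicheConfig, n_animals_per_group: int | dict[str, int],
                    between_animal_sd_um: float = 0.8,
                    seed: int | None = None,
                    groups: tuple[str, str] = ("WT", "iKD")) -> list[AnimalNiche]:
    """Simulate a cohort of animals, one niche per animal.

    Each animal's phenotype offsets are the configured group offsets plus an
    independent animal-level normal deviate (sd ``between_animal_sd_um``,
    drawn per animal and phenotype), reflecting that per-animal means are
    the unit of analysis.  Every animal contributes ``config.n_sections``
    independent sections sharing that animal's true offsets.
    ``n_animals_per_group`` may be one integer for all groups or a
    per-group mapping (e.g. ``{"WT": 10, "iKD": 12}``).
    """
    if isinstance(n_animals_per_group, int):
        n_map = {g: n_animals_per_group for g in groups}
    else:
        n_map = dict(n_animals_per_group)
    if any(n < 2 for n in n_map.values()):
        raise ValueError("need at least 2 animals per group")
    master = np.random.SeedSequence(seed if seed is not None else config.seed)
    animals: list[AnimalNiche] = []
    idx = 1
    for group in n_map:
        for _ in range(n_map[group]):
            child = master.spawn(1)[0]
            dev_rng = np.random.default_rng(_spawn_seed(child))
            offsets = {}
            for pheno in config.n_cells_per_type:
                off = config.offset_for(pheno, group)
                if between_animal_sd_um > 0:
                    off += dev_rng.normal(0.0, between_animal_sd_um)
                offsets[(pheno, group)] = off
            animal_id = f"{group}-{idx:02d}"
            sections = []
            for k, sec_ss in enumerate(child.spawn(max(1, config.n_sections))):
                acfg = replace(config, group=group,
                               animal_id=f"{animal_id}-s{k + 1}",
                               distance_offset_um=offsets,
                               seed=_spawn_seed(sec_ss))
                img, cells, midline, regions, truth = generate_niche(acfg)
                cells = cells.assign(animal_id=animal_id, section=k + 1)
                truth.cells = truth.cells.assign(animal_id=animal_id,
                                                 section=k + 1)
                sections.append(NicheSection(img, cells, midline, regions,
                                             truth))
            animals.append(AnimalNiche(
                animal_id, group, sections,
                true_offsets_um={ph: offsets[(ph, group)]
                                 for ph in config.n_cells_per_type}))
            idx += 1
    return animals


# ---------------------------------------------------------------------------
# RNAscope-like puncta images


def generate_puncta_image(n_cells_per_type: dict[str, int],
                          mean_puncta: dict[str, float],
                          nucleus_radius_um: float = 4.0,
                          pixel_size_um: float = 0.25,
                          min_separation_px: int = 3,
                          seed: int = 0) -> tuple[ImageStack, np.ndarray, NicheTruth]:
    """Render nuclei with Poisson-distributed in-nucleus puncta.

    Nuclei are laid out on a jittered grid (guaranteed non-overlap) and
    each receives ``Poisson(mean_puncta[phenotype])`` puncta, placed inside
    the nucleus with at least ``min_separation_px`` between spots where
    feasible; when a nucleus cannot hold its draw at that separation a
    warning is raised, the spots are allowed to merge and the event is
    recorded in the truth table.  Returns the image (channels ``Vegfa``,
    ``Hoechst``), the labeled nucleus mask and the truth.
    """
    for ph, rate in mean_puncta.items():
        if rate < 0:
            raise ValueError(f"negative puncta rate for {ph!r}")
    rng = np.random.default_rng(seed)
    r_px = nucleus_radius_um / pixel_size_um
    cell_px = int(np.ceil(2.6 * r_px))
    n_total = sum(n_cells_per_type.values())
    n_cols = int(np.ceil(np.sqrt(n_total)))
    n_rows = int(np.ceil(n_total / n_cols))
    nr, nc = n_rows * cell_px, n_cols * cell_px

    labels = np.zeros((nr, nc), np.int32)
    spot_map = np.zeros((nr, nc), float)
    hoechst = np.zeros((nr, nc), float)
    yy, xx = np.mgrid[:nr, :nc]
    records = []
    order = [ph for ph, n in n_cells_per_type.items() for _ in range(n)]
    rng.shuffle(order)
    for i, pheno in enumerate(order):
        gr, gc = divmod(i, n_cols)
        jit = 0.1 * cell_px
        cy = gr * cell_px + cell_px / 2 + rng.uniform(-jit, jit)
        cx = gc * cell_px + cell_px / 2 + rng.uniform(-jit, jit)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px ** 2
        labels[disk] = i + 1
        hoechst[disk] = 400.0
        count = int(rng.poisson(mean_puncta.get(pheno, 0.0)))
        pts: list[tuple[int, int]] = []
        merged = False
        for _ in range(count):
            placed = False
            for _try in range(200):
                ang = rng.uniform(0, 2 * np.pi)
                rad = (r_px - 1.5) * np.sqrt(rng.uniform())
                pr = int(round(cy + rad * np.sin(ang)))
                pc = int(round(cx + rad * np.cos(ang)))
                # Chebyshev separation on the pixel grid: conservative for
                # any detector whose suppression footprint is a square
                if all(max(abs(pr - q[0]), abs(pc - q[1])) >= min_separation_px
                       for q in pts):
                    pts.append((pr, pc))
                    placed = True
                    break
            if not placed:
                # nucleus too crowded at the requested separation
                merged = True
                ang = rng.uniform(0, 2 * np.pi)
                rad = (r_px - 1.5) * np.sqrt(rng.uniform())
                pts.append((int(round(cy + rad * np.sin(ang))),
                            int(round(cx + rad * np.cos(ang)))))
        if merged:
            warnings.warn(
                f"nucleus {i + 1} ({pheno}) too small for {count} puncta at "
                f"separation {min_separation_px}px; spots may merge")
        for pr, pc in pts:
            if 0 <= pr < nr and 0 <= pc < nc:
                spot_map[pr, pc] += 1200.0
        records.append({"nucleus_id": i + 1, "phenotype": pheno,
                        "true_count": count, "merged": merged})

    puncta_chan = ndimage.gaussian_filter(spot_map, sigma=0.8) + 40.0
    hoechst = ndimage.gaussian_filter(hoechst, sigma=1.0) + 40.0
    noise = NoiseModel(background=40.0, foreground=1200.0, read_sd=4.0, shot_k=0.1)
    img = ImageStack(np.stack([_apply_noise(puncta_chan, noise, rng),
                               _apply_noise(hoechst, noise, rng)]),
                     ["Vegfa", "Hoechst"], pixel_size_um)
    truth = NicheTruth(puncta_counts=pd.DataFrame(records))
    return img, labels, truth


# ---------------------------------------------------------------------------
# scratch assay


def generate_scratch_series(initial_area_um2: float,
                            closure_fraction_per_h: dict[str, float],
                            timepoints_h: list[float] = (0, 1, 4, 8),
                            noise_cv: float = 0.03,
                            seed: int = 0) -> tuple[dict[str, pd.DataFrame], NicheTruth]:
    """Simulate scratch-area time series per condition.

    The noiseless area shrinks linearly: ``A(t) = A0 * max(0, 1 - rate*t)``;
    observed areas carry multiplicative log-normal noise.  Rate 0 models the
    non-motile (quiescent) case: the scratch never closes.  Truth stores the
    noiseless trajectory.
    """
    t = np.asarray(sorted(timepoints_h), float)
    if initial_area_um2 <= 0:
        raise ValueError("initial_area_um2 must be positive")
    if t[0] != 0:
        raise ValueError("timepoints must include 0")
    rng = np.random.default_rng(seed)
    series = {}
    truth_rows = []
    for cond, rate in closure_fraction_per_h.items():
        clean = initial_area_um2 * np.clip(1.0 - rate * t, 0.0, None)
        noisy = clean * np.exp(rng.normal(0.0, noise_cv, len(t)))
        noisy[clean == 0] = 0.0
        series[cond] = pd.DataFrame({"time_h": t, "area_um2": noisy})
        for ti, a in zip(t, clean):
            truth_rows.append({"condition": cond, "time_h": ti, "area_um2": a,
                               "ingression": 0.0 if ti == 0
                               else 1.0 - a / initial_area_um2})
    return series, NicheTruth(scratch_areas=pd.DataFrame(truth_rows))


def render_scratch_image(field_um: tuple[float, float] = (600.0, 600.0),
                         scratch_width_um: float = 200.0,
                         pixel_size_um: float = 2.0,
                         seed: int = 0) -> tuple[ImageStack, float]:
    """Render a confluent monolayer with a vertical cell-free stripe.

    Returns the image and the analytic stripe area (µm²); used to exercise
    image-based scratch-area measurement against a known value.
    """
    rng = np.random.default_rng(seed)
    nr = int(round(field_um[1] / pixel_size_um))
    nc = int(round(field_um[0] / pixel_size_um))
    cells = rng.uniform(300.0, 600.0, (nr, nc))
    cells = ndimage.gaussian_filter(cells, 1.0)
    img = cells.copy()
    w_px = int(round(scratch_width_um / pixel_size_um))
    c0 = (nc - w_px) // 2
    img[:, c0:c0 + w_px] = rng.uniform(20.0, 60.0, (nr, w_px))
    area = w_px * nr * pixel_size_um ** 2
    return ImageStack(img[None].astype(np.float32), ["phase"], pixel_size_um), area


# ---------------------------------------------------------------------------
# attachment assay


def _separated_positions(n: int, nr: int, nc: int, min_sep_px: float,
                         rng: np.random.Generator) -> np.ndarray:
    """n random (row, col) positions with pairwise separation >= min_sep_px,
    via a jittered grid (cell pitch >= 2 * min_sep so jitter cannot collide)."""
    pitch = 2.0 * min_sep_px
    rows = int((nr - 2) // pitch)
    cols = int((nc - 2) // pitch)
    if rows * cols < n:
        warnings.warn(f"well holds only {rows * cols} nuclei at separation "
                      f"{min_sep_px}px; requested {n}")
        n = rows * cols
    rr, cc = np.mgrid[:rows, :cols]
    centers = np.column_stack([(rr.ravel() + 0.5) * pitch + 1,
                               (cc.ravel() + 0.5) * pitch + 1])
    pick = rng.choice(len(centers), size=n, replace=False)
    jitter = rng.uniform(-(pitch - min_sep_px) / 2, (pitch - min_sep_px) / 2,
                         (n, 2))
    return centers[pick] + jitter


def generate_attachment_plate(n_pairs: int, cells_per_well: int,
                              retention: dict[str, float],
                              pixel_size_um: float = 2.0,
                              well_px: int = 640,
                              nucleus_radius_um: float = 5.0,
                              experiment_id: str = "exp1",
                              seed: int = 0,
                              render: bool = True):
    """Simulate adjacent vehicle/treated well pairs of a detachment assay.

    Each well seeds ``Poisson(cells_per_well)`` nuclei; after detachment a
    binomial draw at the treatment's retention fraction remains, as a subset
    of the pre positions (wells are re-imaged at the same anchored
    location).  Returns ``(wells, images, truth)`` where ``wells`` is a
    per-well table, ``images`` maps ``(pair, treatment, phase)`` to
    Hoechst-channel ImageStacks (empty dict when ``render=False``) and the
    truth records true fractions and counts.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    treatments = list(retention)
    if len(treatments) != 2:
        raise ValueError("retention must map exactly two treatments")
    for tr, f in retention.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"retention fraction for {tr!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    noise = NoiseModel(background=30.0, foreground=500.0, read_sd=5.0, shot_k=0.2)
    r_px = nucleus_radius_um / pixel_size_um
    rows, images = [], {}
    for pair in range(1, n_pairs + 1):
        for tr in treatments:
            n_pre = int(rng.poisson(cells_per_well))
            if render:
                pos = _separated_positions(n_pre, well_px, well_px,
                                           2.4 * r_px + 2, rng)
                n_pre = len(pos)
            keep = rng.uniform(size=n_pre) < retention[tr]
            n_post = int(keep.sum())
            rows.append({"experiment": experiment_id, "pair_id": pair,
                         "treatment": tr, "well_id": f"{experiment_id}-p{pair}-{tr}",
                         "pre_count_true": n_pre, "post_count_true": n_post,
                         "retention_true": retention[tr]})
            if render:
                for phase, sel in [("pre", np.ones(n_pre, bool)), ("post", keep)]:
                    canvas = np.zeros((well_px, well_px), float)
                    p = pos[sel]
                    _stamp_disks(canvas, p[:, 0].astype(int), p[:, 1].astype(int),
                                 r_px, noise.foreground)
                    canvas = (ndimage.gaussian_filter(canvas, 1.0)
                              + noise.background)
                    images[(pair, tr, phase)] = ImageStack(
                        _apply_noise(canvas, noise, rng)[None],
                        ["Hoechst"], pixel_size_um)
    wells = pd.DataFrame(rows)
    truth = NicheTruth(wells=wells.copy(), retention=dict(retention))
    return wells, images, truth
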