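"""Circular reference polygons: placement, cover annotation, splits.

Field plots are circles of radius 2 m; a plot's pixels are those whose
centres fall inside the circle (13 pixels on a 1 m grid when the centre
coincides with a pixel centre; the nominal bookkeeping count is 15).  Target
plots are annotated with the mean target cover over their pixels, rounded
to the nearest 10 %, and stratified into the cover classes 20-40, 50-70 and
80-100 %.  Background plots contain no target cover at all.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geo import GeoTransform
from .scene import CoverScene

NOMINAL_PIXELS_PER_POLYGON = 15   # the field-design arithmetic constant

STRATA: tuple[str, ...] = ("20-40", "50-70", "80-100")
_STRATUM_BOUNDS = {"20-40": (20, 40), "50-70": (50, 70), "80-100": (80, 100)}


class SamplingError(RuntimeError):
    pass


def stratum_of(cover_pct: int) -> str | None:
    """Cover class of a decile-grid cover percentage (None below 20 %)."""
    for name, (lo, hi) in _STRATUM_BOUNDS.items():
        if lo <= cover_pct <= hi:
            return name
    return None


def stratum_deciles(name: str) -> tuple[int, ...]:
    lo, hi = _STRATUM_BOUNDS[name]
    return tuple(range(lo, hi + 1, 10))


@dataclass
class ReferencePolygon:
    """One circular field plot with its pixel membership and annotations."""

    id: int
    center: tuple[float, float]            # map coords (x, y)
    radius: float
    klass: str                             # "target" | "background"
    cover_pct: int                         # decile grid; 0 for background
    stratum: str | None
    pixels: list[tuple[int, int]]
    role: str = "unassigned"               # "train" | "validation" | "unassigned"


@dataclass
class SampleDesign:
    """The full reference-plot set for one species/scene."""

    target_polygons: list[ReferencePolygon]
    background_polygons: list[ReferencePolygon]
    seed: int = 0
    transform: GeoTransform = field(default_factory=GeoTransform)

    @property
    def all_polygons(self) -> list[ReferencePolygon]:
        return list(self.target_polygons) + list(self.background_polygons)

    def strata_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in STRATA}
        for p in self.target_polygons:
            if p.stratum is not None:
                counts[p.stratum] += 1
        return counts

    def to_dataframe(self):
        import pandas as pd

        rows = [{"id": p.id, "x": p.center[0], "y": p.center[1],
                 "radius_m": p.radius, "class": p.klass,
                 "cover_pct": p.cover_pct, "stratum": p.stratum or "none",
                 "n_pixels": len(p.pixels), "role": p.role}
                for p in self.all_polygons]
        return pd.DataFrame(rows)

    def to_geojson(self) -> dict:
        feats = []
        for p in self.all_polygons:
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(p.center)},
                "properties": {"id": p.id, "radius_m": p.radius,
                               "class": p.klass, "cover_pct": p.cover_pct,
                               "stratum": p.stratum or "none", "role": p.role},
            })
        return {"type": "FeatureCollection", "features": feats}


def rasterize_circle(center: tuple[float, float], radius: float,
                     transform: GeoTransform,
                     raster_shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Pixels whose centres lie within ``radius`` of ``center`` (centre-in rule)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    cx, cy = center
    rows, cols = raster_shape
    r0, c0 = transform.to_rowcol(cx, cy)
    halo = int(np.ceil(radius / transform.gsd)) + 1
    r_lo, r_hi = max(r0 - halo, 0), min(r0 + halo + 1, rows)
    c_lo, c_hi = max(c0 - halo, 0), min(c0 + halo + 1, cols)
    if r_lo >= r_hi or c_lo >= c_hi:
        warnings.warn("circle entirely outside raster", RuntimeWarning)
        return []
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    px, py = transform.pixel_center(rr, cc)
    inside = (px - cx) ** 2 + (py - cy) ** 2 <= radius ** 2
    pix = list(zip(rr[inside].tolist(), cc[inside].tolist()))
    if not pix:
        warnings.warn("circle contains no pixel centres", RuntimeWarning)
    return pix


def annotate_cover(pixels: Sequence[tuple[int, int]], scene: CoverScene) -> int:
    """Mean target cover over member pixels, as a percentage on the 10 % grid."""
    if len(pixels) == 0:
        raise SamplingError("polygon has no member pixels")
    rows, cols = zip(*pixels)
    mean = float(scene.cover[list(rows), list(cols)].mean())
    return int(round(mean * 10.0)) * 10


def place_reference_polygons(scene: CoverScene, n_target: int = 110,
                             strata_counts: Sequence[int] = (30, 30, 50),
                             n_background: int = 200, radius: float = 2.0,
                             min_spacing_m: float = 10.0, seed: int = 0,
                             max_attempts: int = 500_000) -> SampleDesign:
    """Seeded rejection sampling of the reference-plot design.

    Target plots fill the per-stratum quotas (default 30/30/50 across the
    20-40/50-70/80-100 % cover classes); background plots must contain zero
    target cover at every member pixel.  All plots are pairwise disjoint in
    pixels and their centres keep a minimum spacing so the design is spread
    across the scene.
    """
    if len(strata_counts) != len(STRATA):
        raise ValueError("strata_counts must have three entries")
    if sum(strata_counts) != n_target:
        raise ValueError("strata_counts must sum to n_target")
    rng = np.random.default_rng(seed)
    shape = scene.shape
    gt = scene.transform

    quotas = dict(zip(STRATA, strata_counts))
    filled = {s: 0 for s in STRATA}
    used_pixels: set[tuple[int, int]] = set()
    centers: list[tuple[float, float]] = []
    target_polys: list[ReferencePolygon] = []
    background_polys: list[ReferencePolygon] = []
    next_id = 0

    def spaced(cx, cy):
        for ox, oy in centers:
            if (cx - ox) ** 2 + (cy - oy) ** 2 < min_spacing_m ** 2:
                return False
        return True

    def try_place(r, c, klass):
        nonlocal next_id
        cx, cy = gt.pixel_center(r, c)
        cx, cy = float(cx), float(cy)
        if not spaced(cx, cy):
            return False
        pix = rasterize_circle((cx, cy), radius, gt, shape)
        if not pix or any(p in used_pixels for p in pix):
            return False
        if klass == "target":
            pct = annotate_cover(pix, scene)
            strat = stratum_of(pct)
            if strat is None or filled[strat] >= quotas[strat]:
                return False
        else:
            rows_, cols_ = zip(*pix)
            if np.any(scene.cover[list(rows_), list(cols_)] > 0):
                return False
            pct, strat = 0, None
        poly = ReferencePolygon(id=next_id, center=(cx, cy), radius=radius,
                                klass=klass, cover_pct=pct, stratum=strat,
                                pixels=pix)
        next_id += 1
        used_pixels.update(pix)
        centers.append((cx, cy))
        if klass == "target":
            filled[strat] += 1
            target_polys.append(poly)
        else:
            background_polys.append(poly)
        return True

    # target plots: candidates are pixels that could round to >= 20 % cover
    cand = np.argwhere(scene.cover >= 0.15)
    if cand.size == 0 and n_target > 0:
        raise SamplingError(
            "no candidate centres with >= 15 % cover; scene has no target "
            "presence (stratum 20-40 unfillable)")
    cand = cand[rng.permutation(len(cand))]
    attempts = 0
    for r, c in cand:
        if sum(filled.values()) >= n_target or attempts >= max_attempts:
            break
        attempts += 1
        try_place(int(r), int(c), "target")
    for s in STRATA:
        if filled[s] < quotas[s]:
            raise SamplingError(
                f"could not fill stratum {s}: placed {filled[s]} of "
                f"{quotas[s]} plots (candidates exhausted)")

    # background plots: zero-cover pixels only
    zero = np.argwhere(scene.cover == 0)
    zero = zero[rng.permutation(len(zero))]
    attempts = 0
    for r, c in zero:
        if len(background_polys) >= n_background or attempts >= max_attempts:
            break
        attempts += 1
        try_place(int(r), int(c), "background")
    if len(background_polys) < n_background:
        raise SamplingError(
            f"could only place {len(background_polys)} of {n_background} "
            "background plots")

    return SampleDesign(target_polygons=target_polys,
                        background_polygons=background_polys, seed=seed,
                        transform=gt)


def split_stage0(design: SampleDesign, seed: int = 0):
    """Polygon-level 50/50 random split, no cover stratification.

    Mirrors the naive first-pass design: 55 target + 100 background plots
    per side, split at the polygon level so no plot contributes pixels to
    both sides.
    """
    rng = np.random.default_rng(seed)
    t = list(design.target_polygons)
    b = list(design.background_polygons)
    t_order = rng.permutation(len(t))
    b_order = rng.permutation(len(b))
    t_half, b_half = len(t) // 2, len(b) // 2
    train = ([replace(t[i], role="train") for i in t_order[:t_half]]
             + [replace(b[i], role="train") for i in b_order[:b_half]])
    val = ([replace(t[i], role="validation") for i in t_order[t_half:]]
           + [replace(b[i], role="validation") for i in b_order[b_half:]])
    return train, val


def _greedy_farthest(cands: list[ReferencePolygon], k: int, rng) -> list[int]:
    """Indices of k candidates chosen by greedy farthest-point spread."""
    if len(cands) < k:
        raise SamplingError(f"need {k} polygons, only {len(cands)} available")
    xy = np.array([p.center for p in cands])
    chosen = [int(rng.integers(len(cands)))]
    d = np.linalg.norm(xy - xy[chosen[0]], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(xy - xy[nxt], axis=1))
    return chosen


def build_fixed_validation(design: SampleDesign, seed: int = 0,
                           per_stratum: int = 10,
                           n_background: int = 100) -> list[ReferencePolygon]:
    """The fixed validation set reused across all scenario runs.

    10 target plots per cover stratum (30 total) plus 100 background plots,
    chosen by greedy farthest-point spread so validation covers the scene
    evenly.  Fixed once per experiment; every scenario is scored against it.
    """
    rng = np.random.default_rng(seed)
    val: list[ReferencePolygon] = []
    for s in STRATA:
        pool = [p for p in design.target_polygons if p.stratum == s]
        idx = _greedy_farthest(pool, per_stratum, rng)
        val.extend(replace(pool[i], role="validation") for i in idx)
    bg_pool = list(design.background_polygons)
    idx = _greedy_farthest(bg_pool, n_background, rng)
    val.extend(replace(bg_pool[i], role="validation") for i in idx)
    return val


def training_pool(design: SampleDesign,
                  validation: Sequence[ReferencePolygon]) -> tuple[list, list]:
    """(target, background) polygons not reserved for validation."""
    val_ids = {p.id for p in validation}
    t = [p for p in design.target_polygons if p.id not in val_ids]
    b = [p for p in design.background_polygons if p.id not in val_ids]
    return t, b
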