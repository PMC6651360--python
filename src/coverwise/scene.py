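"""Synthetic hyperspectral scenes with known target-species cover.

The simulator emulates the structure of an airborne reflectance mosaic over
a heterogeneous herbaceous landscape: every pixel is a linear mixture of one
target-species endmember and several background endmembers, the target's
fractional cover forms spatially autocorrelated patches occupying a few
percent of the scene, and additive Gaussian sensor noise is applied per
band.  Ground truth (the per-pixel cover field and the field-mappable
patches derived from it) is exact by construction, which makes every
downstream stage of the classification experiment testable without airborne
data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geo import GeoTransform


class ConfigurationError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# spectral library
# --------------------------------------------------------------------------

@dataclass
class SpectralLibrary:
    """Endmember reflectance spectra on a common wavelength grid.

    Exactly one endmember is the target species; the rest are background
    vegetation types.  Reflectance is unitless in [0, 1], wavelengths in nm.
    """

    wavelengths: np.ndarray
    spectra: np.ndarray          # (n_endmembers, B)
    labels: list[str]
    target_index: int = 0

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.wavelengths.ndim != 1 or np.any(np.diff(self.wavelengths) <= 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        if self.spectra.shape != (len(self.labels), self.wavelengths.size):
            raise ConfigurationError("spectra shape inconsistent with labels/wavelengths")
        if np.any(self.spectra < 0) or np.any(self.spectra > 1):
            raise ConfigurationError("reflectance must lie in [0, 1]")
        if not 0 <= self.target_index < len(self.labels):
            raise ConfigurationError("target_index out of range")

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    @property
    def target_spectrum(self) -> np.ndarray:
        return self.spectra[self.target_index]

    @property
    def background_spectra(self) -> np.ndarray:
        idx = [i for i in range(len(self.labels)) if i != self.target_index]
        return self.spectra[idx]


def make_wavelength_grid(n_bands: int = 430, lo_nm: float = 400.0,
                         hi_nm: float = 2500.0) -> np.ndarray:
    if n_bands < 2 or hi_nm <= lo_nm:
        raise ConfigurationError("invalid wavelength grid")
    return np.linspace(lo_nm, hi_nm, n_bands)


def _gauss(wl, center, width):
    return np.exp(-((wl - center) / width) ** 2)


def make_endmember(wavelengths: np.ndarray, kind: str = "background",
                   jitter_seed: int = 0, separability: float = 0.0) -> np.ndarray:
    """One smooth vegetation-like reflectance curve with seeded jitter.

    The curve has the canonical green-vegetation features: a green peak near
    550 nm, a chlorophyll absorption trough near 680 nm, a red-edge rise to
    a NIR plateau, and water-absorption dips near 1450 and 1940 nm.  For
    ``kind="target"`` the NIR plateau and red-edge position are shifted by
    ``separability``, which tunes how distinguishable the target species is
    from the background flora.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
        raise ConfigurationError("wavelengths must be strictly increasing")
    rng = np.random.default_rng(jitter_seed)
    u = lambda: rng.uniform(-1.0, 1.0)

    base = 0.045 + 0.012 * u()
    green_amp = 0.060 + 0.020 * u()
    trough_depth = 0.025 + 0.010 * u()
    nir = 0.42 + 0.07 * u()
    edge_pos = 715.0 + 10.0 * u()
    edge_width = 14.0 + 3.0 * u()
    swir_slope = 0.35 + 0.10 * u()
    d1450 = 0.55 + 0.15 * u()
    d1940 = 0.75 + 0.15 * u()
    if kind == "target":
        nir = np.clip(nir + separability, 0.05, 0.95)
        edge_pos += 120.0 * separability
    elif kind != "background":
        raise ConfigurationError(f"unknown endmember kind: {kind!r}")

    plateau = nir / (1.0 + np.exp(-(wl - edge_pos) / edge_width))
    # gentle SWIR decline beyond 1300 nm
    plateau *= 1.0 - swir_slope * np.clip(wl - 1300.0, 0.0, None) / 1200.0
    r = (base
         + green_amp * _gauss(wl, 550.0, 32.0)
         - trough_depth * _gauss(wl, 680.0, 26.0)
         + plateau)
    # liquid-water absorption features
    r *= (1.0
          - 0.12 * _gauss(wl, 970.0, 30.0)
          - 0.18 * _gauss(wl, 1200.0, 40.0)
          - d1450 * _gauss(wl, 1450.0, 45.0)
          - d1940 * _gauss(wl, 1940.0, 70.0))
    return _ensure_green_peak(wl, np.clip(r, 0.0, 1.0))


def _ensure_green_peak(wl: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Guarantee reflectance(550) > reflectance(680) even on coarse grids."""
    i550 = int(np.argmin(np.abs(wl - 550.0)))
    i680 = int(np.argmin(np.abs(wl - 680.0)))
    if r[i680] >= r[i550]:
        r = np.clip(r - (r[i680] - r[i550] + 0.01) * _gauss(wl, 680.0, 26.0),
                    0.0, 1.0)
    return r


def make_spectral_library(wavelengths: np.ndarray | None = None,
                          n_background: int = 5, seed: int = 0,
                          separability: float = 0.03) -> SpectralLibrary:
    """Target + ``n_background`` background endmembers with jittered shapes.

    ``separability`` controls how spectrally distinct the target species is
    from the background flora: the target spectrum is the mean background
    signature displaced along a vegetation-shaped direction so that its
    largest per-band reflectance deviation equals ``separability``.  Small
    values emulate a species whose signature is strongly entangled with its
    co-occurring vegetation; the default sits in the regime where low-cover
    mixtures are genuinely hard to tell from pure background under sensor
    noise.
    """
    if wavelengths is None:
        wavelengths = make_wavelength_grid()
    wl = np.asarray(wavelengths, dtype=float)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_background + 1)]
    bg = np.array([make_endmember(wl, "background", seeds[i + 1])
                   for i in range(n_background)])
    proto = make_endmember(wl, "target", seeds[0])
    mean_bg = bg.mean(axis=0)
    delta = proto - mean_bg
    peak = np.max(np.abs(delta))
    if peak > 0:
        delta = delta * (separability / peak)
    target = _ensure_green_peak(wl, np.clip(mean_bg + delta, 0.0, 1.0))
    spectra = np.vstack([target[None], bg])
    labels = ["target"] + [f"background_{i + 1}" for i in range(n_background)]
    return SpectralLibrary(wavelengths=wl, spectra=spectra, labels=labels,
                           target_index=0)


# --------------------------------------------------------------------------
# cover field
# --------------------------------------------------------------------------

# decile-aligned stratum edges on the continuous cover scale: covers in
# [0.15, 0.45) round to 20-40 %, [0.45, 0.75) to 50-70 %, [0.75, 1] to 80-100 %
_STRATUM_EDGES = (0.2, 0.45, 0.75, 1.0)
# share of covered pixels per stratum; weighted toward high cover so dense
# patch cores large enough for field plots exist at low scene prevalence
_STRATUM_MASS = (0.30, 0.30, 0.40)


@dataclass
class CoverScene:
    """Ground truth for one synthetic scene.

    ``cover`` is the per-pixel target-species cover fraction; the background
    share of every pixel is split across background endmembers by the convex
    ``background_weights``.
    """

    cover: np.ndarray                 # (R, C) in [0, 1]
    background_weights: np.ndarray    # (R, C, n_background), rows sum to 1
    gsd: float = 1.0
    transform: GeoTransform = field(default_factory=GeoTransform)
    scene_max_prevalence: float = 0.05

    def __post_init__(self):
        self.cover = np.asarray(self.cover, dtype=float)
        self.background_weights = np.asarray(self.background_weights, dtype=float)
        if np.any(self.cover < 0) or np.any(self.cover > 1):
            raise SimulationError("cover out of [0, 1]")
        if self.background_weights.shape[:2] != self.cover.shape:
            raise SimulationError("background_weights shape mismatch")
        if np.any(self.background_weights < -1e-12):
            raise SimulationError("background weights must be nonnegative")
        sums = self.background_weights.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise SimulationError("background weights must sum to 1 per pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cover.shape

    @property
    def prevalence(self) -> float:
        """Fraction of pixels at or above 20 % target cover."""
        return float(np.mean(self.cover >= 0.2))


def _smooth_field(rng, shape, sigma_px):
    z = rng.standard_normal(shape)
    if sigma_px > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma_px, mode="wrap")
    return z


def simulate_cover_field(rows: int = 500, cols: int = 500,
                         correlation_length_m: float = 20.0,
                         prevalence_target: float = 0.04,
                         gsd: float = 1.0, n_background: int = 5,
                         seed: int = 0,
                         scene_max_prevalence: float = 0.05) -> CoverScene:
    """Spatially autocorrelated cover field with controlled prevalence.

    Seeded white noise is smoothed with a Gaussian kernel of the given
    correlation length and then transformed monotonically so that exactly the
    top ``prevalence_target`` quantile of pixels reaches >= 20 % cover, with
    the covered pixels' values spread across the three cover strata
    (20-40, 50-70, 80-100 %) in proportion ``_STRATUM_MASS``.  A narrow
    quantile fringe below the threshold ramps from 0 to 20 % so patches have
    soft edges.
    """
    if prevalence_target > scene_max_prevalence:
        raise ConfigurationError(
            f"prevalence_target {prevalence_target} exceeds scene_max_prevalence "
            f"{scene_max_prevalence}")
    rng = np.random.default_rng(seed)
    shape = (rows, cols)
    sigma_px = correlation_length_m / gsd

    weights = _background_weights(rng, shape, n_background, sigma_px)

    if prevalence_target <= 0:
        return CoverScene(np.zeros(shape), weights, gsd=gsd,
                          scene_max_prevalence=scene_max_prevalence)

    z = _smooth_field(rng, shape, sigma_px)
    n = rows * cols
    n_cov = int(round(prevalence_target * n))
    if n_cov < 3:
        raise SimulationError(
            "scene too small: fewer than 3 pixels would reach 20 % cover, "
            "so the cover strata cannot all be populated")
    order = np.argsort(z, axis=None)          # ascending
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)

    cover = np.zeros(n)
    # covered pixels: map the within-tail rank through the piecewise-linear
    # inverse CDF defined by the stratum masses
    tail = ranks >= n - n_cov
    u = (ranks[tail] - (n - n_cov) + 1.0) / n_cov      # (0, 1]
    cover[tail] = _stratum_inverse_cdf(u)
    # fringe: same-width quantile band below threshold ramps 0 -> 0.2
    n_fringe = n_cov
    fringe = (ranks >= n - n_cov - n_fringe) & ~tail
    uf = (ranks[fringe] - (n - n_cov - n_fringe)) / n_fringe
    cover[fringe] = 0.199 * uf
    cover = cover.reshape(shape)

    scene = CoverScene(cover, weights, gsd=gsd,
                       transform=GeoTransform(gsd=gsd),
                       scene_max_prevalence=scene_max_prevalence)
    realized = scene.prevalence
    if not (0.8 * prevalence_target <= realized <= 1.2 * prevalence_target):
        raise SimulationError(
            f"realized prevalence {realized:.4f} outside +/-20 % of target "
            f"{prevalence_target}")
    for lo, hi in ((0.15, 0.45), (0.45, 0.75), (0.75, 1.01)):
        if not np.any((cover >= lo) & (cover < hi)):
            raise SimulationError(
                f"scene too small to populate cover stratum [{lo}, {hi}); "
                "increase size or prevalence")
    return scene


def _stratum_inverse_cdf(u: np.ndarray) -> np.ndarray:
    """Map uniform ranks in (0, 1] to covers in [0.2, 1] with stratum masses."""
    edges = np.asarray(_STRATUM_EDGES)
    cum = np.concatenate([[0.0], np.cumsum(_STRATUM_MASS)])
    cum /= cum[-1]
    return np.interp(u, cum, edges)


def _background_weights(rng, shape, n_background, sigma_px,
                        concentration: float = 3.0):
    """Convex background-composition fields with patchy species dominance.

    Each background endmember gets a smooth Gaussian random field; the
    per-pixel weights are a softmax over the standardized fields.  With the
    default concentration most locations are dominated by one or two
    species while transitions stay smooth — a species-rich mosaic rather
    than a homogeneous blend.
    """
    fields = []
    for _ in range(n_background):
        g = _smooth_field(rng, shape, sigma_px)
        fields.append((g - g.mean()) / max(g.std(), 1e-12))
    fields = np.stack(fields, axis=2) * concentration
    fields -= fields.max(axis=2, keepdims=True)
    w = np.exp(fields)
    return w / w.sum(axis=2, keepdims=True)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

@dataclass
class HyperCube:
    """Band x row x col reflectance raster with georeferencing."""

    data: np.ndarray                  # (B, R, C)
    wavelengths: np.ndarray           # (B,)
    gsd: float = 1.0
    transform: GeoTransform = field(default_factory=GeoTransform)
    nodata_mask: np.ndarray | None = None   # (R, C) True where invalid

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != self.wavelengths.size:
            raise ConfigurationError("cube bands must match wavelengths")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.data.shape[1:], dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.data.shape[1:]:
            raise ConfigurationError("nodata mask shape mismatch")
        if not np.all(np.isfinite(self.data[:, ~self.nodata_mask])):
            raise ConfigurationError("non-finite values outside nodata mask")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def valid_pixels(self) -> np.ndarray:
        """(n_valid, B) matrix of spectra outside the nodata mask."""
        return self.data[:, ~self.nodata_mask].T


def render_cube(scene: CoverScene, library: SpectralLibrary,
                noise_sd: float = 0.003, seed: int = 0) -> HyperCube:
    """Linear-mixture rendering: r = c*S_target + (1-c)*sum_i w_i*B_i + noise."""
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be nonnegative")
    bg = library.background_spectra
    if scene.background_weights.shape[2] != bg.shape[0]:
        raise ConfigurationError(
            "scene background composition does not match library size")
    c = scene.cover[..., None]
    mixed = c * library.target_spectrum + (1.0 - c) * (
        scene.background_weights @ bg)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mixed = mixed + rng.normal(0.0, noise_sd, size=mixed.shape)
    data = np.clip(np.transpose(mixed, (2, 0, 1)), 0.0, 1.0)
    return HyperCube(data=data, wavelengths=library.wavelengths,
                     gsd=scene.gsd, transform=scene.transform)


# --------------------------------------------------------------------------
# truth patches
# --------------------------------------------------------------------------

def truth_mask(scene: CoverScene, min_area_m2: float = 10.0,
               min_cover: float = 0.2) -> np.ndarray:
    """Boolean mask of field-mappable target patches.

    4-connected components of (cover >= min_cover) whose area (pixel count
    times gsd^2) reaches ``min_area_m2``.
    """
    binary = scene.cover >= min_cover
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return np.zeros_like(binary)
    counts = np.bincount(labels.ravel())
    min_px = int(np.ceil(min_area_m2 / scene.gsd ** 2))
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = counts[1:] >= min_px
    return keep[labels]


def extract_truth_patches(scene: CoverScene, min_area_m2: float = 10.0,
                          min_cover: float = 0.2) -> list:
    """Field-mappable patches as shapely polygons (map coordinates).

    Mirrors the field-mapping protocol: every patch of target cover >= 20 %
    with area >= 10 m2 is delineated.  Patch area equals pixel count x gsd^2.
    """
    from shapely.geometry import box
    from shapely.ops import unary_union

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    binary = scene.cover >= min_cover
    labels, n = ndimage.label(binary, structure=structure)
    min_px = int(np.ceil(min_area_m2 / scene.gsd ** 2))
    patches = []
    gt = scene.transform
    g = scene.gsd
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        rr, cc = np.nonzero(labels[sl] == lab)
        if rr.size < min_px:
            continue
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        boxes = [box(gt.x0 + c * g, gt.y0 - (r + 1) * g,
                     gt.x0 + (c + 1) * g, gt.y0 - r * g)
                 for r, c in zip(rr, cc)]
        patches.append(unary_union(boxes))
    return patches
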