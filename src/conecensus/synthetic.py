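"""Seeded synthetic retinal flat-mount and two-channel sensor images.

The generator emulates the statistical structure of en-face flat-mount
microscopy of H2BGFP-labeled cones: a roughly circular tissue region,
nuclei placed with a hard-core minimum separation and an optional radial
density gradient, partial labeling (only labeled nuclei fluoresce),
circumscribed cone-free "craters", and a background offset plus noise.
Every image comes with exact ground truth, so detection and counting can
be validated without real data.

Conventions
-----------
Pixel coordinates are 0-based ``(x, y) = (column, row)`` with the spot
center at the pixel center. Images are float64 in memory, clipped at the
16-bit saturation value; quantization to ``uint16`` happens only on file
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "FlatMountSpec",
    "GroundTruth",
    "RatioGroundTruth",
    "PlacementError",
    "generate_flatmount",
    "generate_ratio_pair",
    "preset",
    "PRESETS",
    "SATURATION",
]

SATURATION = 65535.0

#: Candidate-draw budget: at most 100x oversampling before erroring.
_OVERSAMPLE_CAP = 100


class PlacementError(RuntimeError):
    """Raised when ``n_cones_total`` nuclei cannot be packed into the retina."""


@dataclass(frozen=True)
class FlatMountSpec:
    """Parameter bundle describing one synthetic flat-mounted retina.

    Parameters
    ----------
    image_size : (H, W) in pixels.
    retina_center : (x, y) in pixels; ``None`` means the image center.
    retina_radius : nominal outline radius in pixels.
    boundary_roughness : amplitude of the angular modulation of the
        outline, as a fraction of the radius (>= 0).
    n_cones_total : total nuclei (labeled + unlabeled) to place.
    labeling_efficiency : fraction of nuclei carrying the fluorescent
        label, in [0, 1]. Only labeled nuclei are rendered.
    density_profile : "uniform" or "central_depleted". The depleted
        profile has density d(r) proportional to 1 + g*(r/R) with
        g = ``gradient_strength``, emulating faster central degeneration.
    psf_sigma : isotropic Gaussian spot scale in pixels.
    amplitude_mean, amplitude_cv : lognormal peak-amplitude distribution
        (mean and coefficient of variation) in intensity units.
    min_separation : hard-core minimum center-to-center distance, pixels.
    n_craters, crater_radius_range : circular cone-free patches; nuclei
        are excluded from crater disks, tissue background is unchanged.
    background_level : additive offset in intensity units.
    noise_model : "gaussian" (sd = ``noise_sd``), "poisson", or "none".
    seed : integer seed; same spec + same seed is bit-identical.
    """

    image_size: tuple[int, int] = (1024, 1024)
    retina_center: tuple[float, float] | None = None
    retina_radius: float = 481.0
    boundary_roughness: float = 0.0
    n_cones_total: int = 20000
    labeling_efficiency: float = 0.2
    density_profile: str = "uniform"
    gradient_strength: float = 2.0
    psf_sigma: float = 1.3
    amplitude_mean: float = 2000.0
    amplitude_cv: float = 0.2
    min_separation: float = 4.0
    n_craters: int = 0
    crater_radius_range: tuple[float, float] = (20.0, 60.0)
    background_level: float = 200.0
    noise_model: str = "gaussian"
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.labeling_efficiency <= 1.0):
            raise ValueError("labeling_efficiency must lie in [0, 1]")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.boundary_roughness < 0:
            raise ValueError("boundary_roughness must be >= 0")
        if self.retina_radius <= 0:
            raise ValueError("retina_radius must be > 0")
        if self.n_cones_total < 0:
            raise ValueError("n_cones_total must be >= 0")
        if self.density_profile not in ("uniform", "central_depleted"):
            raise ValueError(f"unknown density_profile {self.density_profile!r}")
        if self.noise_model not in ("gaussian", "poisson", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        h, w = self.image_size
        cx, cy = self.center
        rmax = self.retina_radius * (1.0 + self.boundary_roughness)
        if cx - rmax < -0.5 or cy - rmax < -0.5 or cx + rmax > w - 0.5 or cy + rmax > h - 0.5:
            raise ValueError("retina (incl. boundary roughness) must fit inside the image")

    @property
    def center(self) -> tuple[float, float]:
        if self.retina_center is not None:
            return self.retina_center
        h, w = self.image_size
        return ((w - 1) / 2.0, (h - 1) / 2.0)


@dataclass
class GroundTruth:
    """Exact generator output: every nucleus, its label flag, and craters.

    ``centers`` is an (n, 2) array of (x, y); ``amplitudes`` holds the
    rendered peak amplitude of labeled nuclei (NaN for unlabeled ones).
    """

    centers: np.ndarray
    labeled: np.ndarray
    amplitudes: np.ndarray
    crater_disks: list[tuple[tuple[float, float], float]]
    retina_center: tuple[float, float]
    retina_radius: float

    @property
    def n_all(self) -> int:
        return int(self.centers.shape[0])

    @property
    def n_labeled(self) -> int:
        return int(self.labeled.sum())

    @property
    def n_labeled_half_radius(self) -> int:
        """Labeled nuclei strictly inside the central half-radius disk."""
        if self.n_all == 0:
            return 0
        d = np.hypot(
            self.centers[:, 0] - self.retina_center[0],
            self.centers[:, 1] - self.retina_center[1],
        )
        return int(np.sum(self.labeled & (d < self.retina_radius / 2.0)))

    @property
    def labeled_centers(self) -> np.ndarray:
        return self.centers[self.labeled]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "all": self.n_all,
            "labeled": self.n_labeled,
            "labeled_half_radius": self.n_labeled_half_radius,
        }


@dataclass
class RatioGroundTruth:
    """Ground truth for a two-channel sensor pair."""

    centers: np.ndarray
    amplitudes: np.ndarray
    true_ratio: float
    cell_mask: np.ndarray
    retina_center: tuple[float, float]
    retina_radius: float


# ---------------------------------------------------------------------------
# boundary + placement


def _boundary_profile(spec: FlatMountSpec, rng: np.random.Generator):
    """Return R(theta): the rough outline radius as a function of angle.

    Low-order Fourier modulation normalized so the peak deviation equals
    ``boundary_roughness * retina_radius``.
    """
    if spec.boundary_roughness == 0:
        return lambda theta: np.full_like(np.asarray(theta, float), spec.retina_radius)
    ks = np.arange(2, 6)
    a = rng.normal(size=ks.size)
    b = rng.normal(size=ks.size)

    def f(theta):
        theta = np.asarray(theta, float)
        mod = sum(a[i] * np.cos(k * theta) + b[i] * np.sin(k * theta) for i, k in enumerate(ks))
        return mod

    tgrid = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    peak = np.max(np.abs(f(tgrid)))
    scale = spec.boundary_roughness / peak if peak > 0 else 0.0

    def radius_of(theta):
        return spec.retina_radius * (1.0 + scale * f(theta))

    return radius_of


def retina_mask(spec: FlatMountSpec) -> np.ndarray:
    """Boolean tissue mask for the spec's (possibly rough) outline."""
    rng = np.random.default_rng(spec.seed)
    radius_of = _boundary_profile(spec, rng)
    h, w = spec.image_size
    cx, cy = spec.center
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    return r < radius_of(theta)


def _sample_crater_disks(spec: FlatMountSpec, rng: np.random.Generator):
    disks = []
    lo, hi = spec.crater_radius_range
    for _ in range(spec.n_craters):
        cr = rng.uniform(lo, hi)
        # keep the crater disk well inside the nominal outline
        rr = (spec.retina_radius - cr) * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        cx = spec.center[0] + rr * math.cos(th)
        cy = spec.center[1] + rr * math.sin(th)
        disks.append(((cx, cy), cr))
    return disks


def _place_nuclei(
    spec: FlatMountSpec,
    rng: np.random.Generator,
    radius_of,
    craters,
) -> np.ndarray:
    """Hard-core dart throwing honoring density profile and crater exclusion.

    Batched: each round draws a block of candidates, thins it by the
    density profile, crater disks, the rough boundary, proximity to
    already-accepted nuclei (cKDTree query) and intra-batch conflicts.
    The candidate budget is capped at 100x ``n_cones_total``.
    """
    n_target = spec.n_cones_total
    if n_target == 0:
        return np.empty((0, 2))
    cx, cy = spec.center
    R = spec.retina_radius
    rmax = R * (1.0 + spec.boundary_roughness)
    g = spec.gradient_strength if spec.density_profile == "central_depleted" else 0.0
    d = spec.min_separation

    accepted = np.empty((n_target, 2))
    n_acc = 0
    budget = _OVERSAMPLE_CAP * n_target
    drawn = 0
    while n_acc < n_target and drawn < budget:
        m = int(min(max(4 * (n_target - n_acc), 5000), budget - drawn))
        drawn += m
        # uniform over the bounding disk, then thin
        u = rng.uniform(size=m)
        th = rng.uniform(0, 2 * np.pi, size=m)
        rr = rmax * np.sqrt(u)
        accept = rng.uniform(size=m)  # one density draw per candidate
        pts = np.column_stack([cx + rr * np.cos(th), cy + rr * np.sin(th)])

        keep = rr < radius_of(th)
        if g > 0:
            keep &= accept < (1.0 + g * np.minimum(rr / R, 1.0)) / (1.0 + g)
        for (ccx, ccy), cr in craters:
            keep &= np.hypot(pts[:, 0] - ccx, pts[:, 1] - ccy) >= cr
        pts = pts[keep]
        if pts.shape[0] == 0:
            continue

        if d > 0:
            if n_acc > 0:
                tree = cKDTree(accepted[:n_acc])
                dist, _ = tree.query(pts, k=1)
                pts = pts[dist >= d]
            if pts.shape[0] > 1:
                # drop the later candidate of every intra-batch conflict
                btree = cKDTree(pts)
                bad = np.zeros(pts.shape[0], dtype=bool)
                for i, j in btree.query_pairs(d):
                    bad[max(i, j)] = True
                pts = pts[~bad]

        take = min(pts.shape[0], n_target - n_acc)
        accepted[n_acc : n_acc + take] = pts[:take]
        n_acc += take

    if n_acc < n_target:
        raise PlacementError(
            f"could not place {n_target} nuclei at min_separation="
            f"{spec.min_separation}: achieved {n_acc} within the "
            f"{_OVERSAMPLE_CAP}x oversampling cap"
        )
    return accepted


# ---------------------------------------------------------------------------
# rendering


def _render_spots(shape, centers, amplitudes, sigma) -> np.ndarray:
    """Sum isotropic 2-D Gaussians onto a zero image (vectorized stamping)."""
    img = np.zeros(shape, dtype=np.float64)
    if centers.shape[0] == 0:
        return img
    h, w = shape
    wr = max(1, int(math.ceil(4.0 * sigma)))
    off = np.arange(-wr, wr + 1)
    ox, oy = np.meshgrid(off, off)  # (k, k)

    px = np.round(centers[:, 0]).astype(int)
    py = np.round(centers[:, 1]).astype(int)
    cols = px[:, None, None] + ox[None]
    rows = py[:, None, None] + oy[None]
    dx = cols - centers[:, 0, None, None]
    dy = rows - centers[:, 1, None, None]
    vals = amplitudes[:, None, None] * np.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))
    inb = (cols >= 0) & (cols < w) & (rows >= 0) & (rows < h)
    np.add.at(img, (rows[inb], cols[inb]), vals[inb])
    return img


def _add_noise(img: np.ndarray, spec: FlatMountSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "gaussian":
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    elif spec.noise_model == "poisson":
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    return np.clip(img, 0.0, SATURATION)


def _amplitudes(spec: FlatMountSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if spec.amplitude_cv <= 0:
        return np.full(n, spec.amplitude_mean)
    s2 = math.log1p(spec.amplitude_cv**2)
    mu = math.log(spec.amplitude_mean) - s2 / 2.0
    return rng.lognormal(mu, math.sqrt(s2), size=n)


def generate_flatmount(spec: FlatMountSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one flat-mount image and its exact ground truth.

    Nuclei are placed by hard-core sampling honoring the density profile
    and crater exclusion; each *labeled* nucleus is rendered as an
    isotropic 2-D Gaussian of sd ``psf_sigma`` with a lognormal peak
    amplitude; background offset and noise are added last.

    Raises
    ------
    PlacementError
        If ``n_cones_total`` nuclei cannot be packed at
        ``min_separation`` inside the retina (names the achieved count).
    """
    rng = np.random.default_rng(spec.seed)
    radius_of = _boundary_profile(spec, rng)
    craters = _sample_crater_disks(spec, rng)
    centers = _place_nuclei(spec, rng, radius_of, craters)

    labeled = rng.uniform(size=centers.shape[0]) < spec.labeling_efficiency
    amplitudes = np.full(centers.shape[0], np.nan)
    amplitudes[labeled] = _amplitudes(spec, rng, int(labeled.sum()))

    img = _render_spots(spec.image_size, centers[labeled], amplitudes[labeled], spec.psf_sigma)
    img += spec.background_level
    img = _add_noise(img, spec, rng)

    truth = GroundTruth(
        centers=centers,
        labeled=labeled,
        amplitudes=amplitudes,
        crater_disks=craters,
        retina_center=spec.center,
        retina_radius=spec.retina_radius,
    )
    return img, truth


def generate_ratio_pair(
    spec: FlatMountSpec, true_ratio: float, sensor: str = "PercevalHR"
) -> tuple[np.ndarray, np.ndarray, RatioGroundTruth]:
    """Render two registered sensor channels with a known intensity ratio.

    The denominator channel is background plus the rendered cell signal;
    the numerator channel is ``true_ratio`` times the denominator before
    noise, so the expected ROI-mean ratio equals ``true_ratio`` exactly
    in the noiseless case. Noise is drawn independently per channel.
    """
    if not true_ratio > 0:
        raise ValueError("true_ratio must be > 0")
    rng = np.random.default_rng(spec.seed)
    radius_of = _boundary_profile(spec, rng)
    craters = _sample_crater_disks(spec, rng)
    centers = _place_nuclei(spec, rng, radius_of, craters)
    amplitudes = _amplitudes(spec, rng, centers.shape[0])

    signal = _render_spots(spec.image_size, centers, amplitudes, spec.psf_sigma)
    den = signal + spec.background_level
    num = true_ratio * den
    num = _add_noise(num, spec, rng)
    den = _add_noise(den, spec, rng)

    h, w = spec.image_size
    mask = np.zeros((h, w), dtype=bool)
    if centers.shape[0]:
        yy, xx = np.mgrid[0:h, 0:w]
        tree = cKDTree(centers)
        dist, _ = tree.query(np.column_stack([xx.ravel(), yy.ravel()]), k=1)
        mask = (dist.reshape(h, w) <= 2.0 * spec.psf_sigma)

    truth = RatioGroundTruth(
        centers=centers,
        amplitudes=amplitudes,
        true_ratio=float(true_ratio),
        cell_mask=mask,
        retina_center=spec.center,
        retina_radius=spec.retina_radius,
    )
    return num, den, truth


# ---------------------------------------------------------------------------
# presets

_REF_SIZE = 3328  # full-scale reference image edge, pixels

#: Census-anchored presets. "wt": ~50,000 cones in the central half-radius
#: (uniform density, so a quarter of the total lies inside); at 20% labeling
#: the labeled count there is ~10,000. "rd1_P20": ~11,000 *labeled* cones in
#: the half-radius just before central degeneration begins.
PRESETS: dict[str, dict] = {
    "wt": dict(n_cones_total=200_000, labeling_efficiency=0.2, density_profile="uniform"),
    "rd1_P20": dict(n_cones_total=220_000, labeling_efficiency=0.2, density_profile="uniform"),
}


def preset(name: str, image_size: int | None = None, **overrides) -> FlatMountSpec:
    """Build a census-anchored spec, optionally scaled to a smaller image.

    Scaling keeps pixel-level quantities (``psf_sigma``,
    ``min_separation``, noise) fixed and shrinks the retina radius
    linearly and the nucleus census by the area factor, so per-area
    densities — and hence detectability — are preserved.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    size = _REF_SIZE if image_size is None else int(image_size)
    s = size / _REF_SIZE
    base = PRESETS[name]
    kw = dict(
        image_size=(size, size),
        retina_radius=0.47 * _REF_SIZE * s,
        n_cones_total=int(round(base["n_cones_total"] * s * s)),
        labeling_efficiency=base["labeling_efficiency"],
        density_profile=base["density_profile"],
    )
    kw.update(overrides)
    return FlatMountSpec(**kw)


def rescale(spec: FlatMountSpec, image_size: int) -> FlatMountSpec:
    """Scale an existing spec to a new (square) image size, area-preserving."""
    s = image_size / spec.image_size[1]
    return replace(
        spec,
        image_size=(image_size, image_size),
        retina_center=None,
        retina_radius=spec.retina_radius * s,
        n_cones_total=int(round(spec.n_cones_total * s * s)),
        crater_radius_range=(spec.crater_radius_range[0] * s, spec.crater_radius_range[1] * s),
    )
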