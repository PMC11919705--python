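"""Ground-truthed synthetic inputs for the whole pipeline.

Generates everything the quantification, behaviour and statistics stages
consume, with known ground truth:

* nucleus fields — elliptical nuclei placed in an ROI polygon, each carrying
  activity flags for the two test entries drawn from a bivariate Bernoulli
  with marginals (p_first, p_second) and correlation rho, and per-IEG
  transcription-focus counts;
* confocal-like 3-channel z-stacks rendered from those nuclei with a
  Gaussian PSF and Poisson-Gaussian noise;
* biased random-walk trajectories over the 5-region cage whose stationary
  occupancy is proportional to per-region attractiveness weights;
* animals x descriptors feature tables with planted group effects and
  missing-completely-at-random entries, for exercising the statistics and
  feature-selection stages.

All randomness flows from a single explicit seed per call.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from skimage.filters import gaussian

from .behavior import REGIONS, CageGeometry, Trajectory
from .descriptors import DESCRIPTOR_NAMES
from .errors import PackingError, ParameterError
from .imagequant import CHANNELS, ZStack

__all__ = [
    "ActivityModel",
    "CageGeometry",
    "GroundTruthNucleus",
    "sample_activity",
    "sample_nuclei",
    "render_zstack",
    "simulate_trajectory",
    "simulate_descriptor_table",
    "true_fractions",
    "save_ground_truth",
    "load_ground_truth",
]


@dataclass(frozen=True)
class GroundTruthNucleus:
    """One simulated nucleus with known activity and focus counts."""

    id: int
    center: tuple[float, float]  # (x, y) pixels
    axes: tuple[float, float]  # (major, minor) semi-axis lengths, pixels
    angle: float  # radians from +x axis
    z_layer: int
    active_first: bool
    active_second: bool
    n_dots_first: int
    n_dots_second: int


@dataclass(frozen=True)
class ActivityModel:
    """Bivariate-Bernoulli activity model for the two test entries.

    The probability that a nucleus is active in both entries is

        P(both) = p_first*p_second
                  + rho*sqrt(p_first(1-p_first) p_second(1-p_second)),

    which must stay inside the Frechet bounds
    [max(0, p_first+p_second-1), min(p_first, p_second)]; rho = 0 is the
    independence null against which the co-localisation coefficient is
    calibrated. Active nuclei carry 1 + Poisson(dot_count_mean - 1) foci per
    IEG, so "active" and "has at least one focus" coincide in ground truth.
    """

    p_first: float
    p_second: float
    rho: float = 0.0
    dot_count_mean: float = 3.0

    def joint(self) -> tuple[float, float, float, float]:
        """(p_both, p_first_only, p_second_only, p_neither); validates."""
        p1, p2, rho = self.p_first, self.p_second, self.rho
        for name, p in (("p_first", p1), ("p_second", p2)):
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"{name}={p} outside [0, 1]")
        if not (-1.0 <= rho <= 1.0):
            raise ParameterError(f"rho={rho} outside [-1, 1]")
        if self.dot_count_mean < 1.0:
            raise ParameterError("dot_count_mean must be >= 1")
        p11 = p1 * p2 + rho * math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
        lo = max(0.0, p1 + p2 - 1.0)
        hi = min(p1, p2)
        if not (lo - 1e-12 <= p11 <= hi + 1e-12):
            raise ParameterError(
                f"rho={rho} infeasible for marginals ({p1}, {p2}): implied "
                f"P(both)={p11:.4f} outside [{lo:.4f}, {hi:.4f}]"
            )
        p11 = min(max(p11, lo), hi)
        return p11, p1 - p11, p2 - p11, 1.0 - p1 - p2 + p11


def sample_activity(
    model: ActivityModel,
    n: int,
    rng_seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (active_first, active_second) boolean arrays for n nuclei from
    the bivariate Bernoulli implied by the model."""
    p11, p10, p01, _ = model.joint()
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    u = rng.uniform(size=n)
    first = u < p11 + p10
    second = (u < p11) | ((u >= p11 + p10) & (u < p11 + p10 + p01))
    return first, second


def sample_nuclei(
    roi_polygon: Sequence[tuple[float, float]] | np.ndarray,
    density: float,
    model: ActivityModel,
    n_layers: int = 1,
    rng_seed: int = 0,
    *,
    major_axis_range: tuple[float, float] = (5.5, 8.0),
    aspect_range: tuple[float, float] = (0.6, 0.95),
    overlap_factor: float = 1.0,
    max_attempts: int = 500,
) -> list[GroundTruthNucleus]:
    """Place non-overlapping elliptical nuclei inside an ROI polygon.

    ``density`` is nuclei per unit pixel area *per z-layer*; each nucleus
    lives on a single layer (the downstream analysis is strictly per-layer
    2-D, so layers are independent fields). Within a layer, two nuclei must
    satisfy center distance > (a_i + a_j) * overlap_factor. Activity flags
    are drawn from the bivariate Bernoulli implied by the model, and focus
    counts as 1 + Poisson(dot_count_mean - 1) for active flags.
    """
    if density <= 0:
        raise ParameterError("density must be positive")
    if n_layers < 1:
        raise ParameterError("n_layers must be >= 1")
    poly = Polygon(np.asarray(roi_polygon, dtype=float))
    if not poly.is_valid or poly.area <= 0:
        raise ParameterError("roi_polygon is degenerate")
    model.joint()  # validate before any work
    rng = np.random.default_rng(rng_seed)
    n_per_layer = int(round(density * poly.area))
    minx, miny, maxx, maxy = poly.bounds

    nuclei: list[GroundTruthNucleus] = []
    nid = 0
    for z in range(n_layers):
        px_arr = np.empty(n_per_layer)
        py_arr = np.empty(n_per_layer)
        pa_arr = np.empty(n_per_layer)
        n_placed = 0
        for _ in range(n_per_layer):
            for attempt in range(max_attempts):
                x = rng.uniform(minx, maxx)
                y = rng.uniform(miny, maxy)
                if not poly.contains(Point(x, y)):
                    continue
                a = rng.uniform(*major_axis_range)
                b = a * rng.uniform(*aspect_range)
                if n_placed:
                    d2 = (px_arr[:n_placed] - x) ** 2 + (py_arr[:n_placed] - y) ** 2
                    min_d = (pa_arr[:n_placed] + a) * overlap_factor
                    if np.any(d2 <= min_d**2):
                        continue
                break
            else:
                raise PackingError(
                    f"could not place nucleus {nid} on layer {z} after "
                    f"{max_attempts} attempts; density {density} too high for "
                    f"overlap_factor {overlap_factor}"
                )
            px_arr[n_placed], py_arr[n_placed], pa_arr[n_placed] = x, y, a
            n_placed += 1
            first, second = sample_activity(model, 1, rng=rng)
            first, second = bool(first[0]), bool(second[0])
            lam = model.dot_count_mean - 1.0
            nd1 = int(1 + rng.poisson(lam)) if first else 0
            nd2 = int(1 + rng.poisson(lam)) if second else 0
            nuclei.append(
                GroundTruthNucleus(
                    id=nid,
                    center=(x, y),
                    axes=(a, b),
                    angle=float(rng.uniform(0, math.pi)),
                    z_layer=z,
                    active_first=first,
                    active_second=second,
                    n_dots_first=nd1,
                    n_dots_second=nd2,
                )
            )
            nid += 1
    return nuclei


def true_fractions(nuclei: Sequence[GroundTruthNucleus]) -> dict[str, float]:
    """Ground-truth four-class fractions (homer = first entry, arc = second)."""
    n = len(nuclei)
    if n == 0:
        raise ParameterError("no nuclei")
    both = sum(1 for u in nuclei if u.active_first and u.active_second)
    first_only = sum(1 for u in nuclei if u.active_first and not u.active_second)
    second_only = sum(1 for u in nuclei if u.active_second and not u.active_first)
    return {
        "both": both / n,
        "homer_only": first_only / n,
        "arc_only": second_only / n,
        "negative": (n - both - first_only - second_only) / n,
    }


def _add_gaussian_bump(
    img: np.ndarray, x0: float, y0: float, sigma: float, amplitude: float
) -> None:
    ny, nx = img.shape
    r = int(math.ceil(4 * sigma))
    x_lo, x_hi = max(0, int(x0) - r), min(nx, int(x0) + r + 1)
    y_lo, y_hi = max(0, int(y0) - r), min(ny, int(y0) + r + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    xs = np.arange(x_lo, x_hi)
    ys = np.arange(y_lo, y_hi)[:, None]
    img[y_lo:y_hi, x_lo:x_hi] += amplitude * np.exp(
        -((xs - x0) ** 2 + (ys - y0) ** 2) / (2 * sigma**2)
    )


def _fill_ellipse(
    img: np.ndarray, nuc: GroundTruthNucleus, amplitude: float
) -> None:
    x0, y0 = nuc.center
    a, b = nuc.axes
    ny, nx = img.shape
    r = int(math.ceil(a)) + 1
    x_lo, x_hi = max(0, int(x0) - r), min(nx, int(x0) + r + 1)
    y_lo, y_hi = max(0, int(y0) - r), min(ny, int(y0) + r + 1)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    xs = np.arange(x_lo, x_hi) - x0
    ys = (np.arange(y_lo, y_hi) - y0)[:, None]
    c, s = math.cos(nuc.angle), math.sin(nuc.angle)
    u = xs * c + ys * s
    v = -xs * s + ys * c
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    patch = img[y_lo:y_hi, x_lo:x_hi]
    patch[inside] = np.maximum(patch[inside], amplitude)


def _dot_positions(
    nuc: GroundTruthNucleus,
    n: int,
    rng: np.random.Generator,
    margin: float,
    min_separation: float,
    max_attempts: int = 200,
) -> list[tuple[float, float]]:
    """Uniform positions inside the (shrunken) parent ellipse, kept at least
    ``min_separation`` apart so each rendered focus is an isolated blob."""
    a, b = nuc.axes[0] * margin, nuc.axes[1] * margin
    c, s = math.cos(nuc.angle), math.sin(nuc.angle)
    pts: list[tuple[float, float]] = []
    for _ in range(n):
        for attempt in range(max_attempts):
            r = math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * math.pi)
            u, v = a * r * math.cos(th), b * r * math.sin(th)
            x = nuc.center[0] + u * c - v * s
            y = nuc.center[1] + u * s + v * c
            if all(math.hypot(x - px, y - py) >= min_separation for px, py in pts):
                break
        pts.append((x, y))
    return pts


def render_zstack(
    nuclei: Sequence[GroundTruthNucleus],
    shape: tuple[int, int],
    psf_sigma: float = 1.2,
    noise: tuple[float, float] = (2.0, 1.0),
    rng_seed: int = 0,
    *,
    n_layers: int | None = None,
    background: float = 10.0,
    nucleus_amplitude: float = 60.0,
    spot_amplitude: float = 150.0,
    dot_margin: float = 0.8,
    min_dot_separation: float = 4.0,
    pixel_size: float = 0.32,
) -> ZStack:
    """Render a 3-channel z-stack (DAPI, Homer/FITC, Arc/Cy3) from nuclei.

    Channel 0 holds filled nucleus ellipses blurred by the PSF; channels 1
    and 2 hold Gaussian foci of width ``psf_sigma`` at positions sampled
    uniformly inside the parent ellipse (first-entry foci on the Homer
    channel, second-entry foci on Arc). Poisson-Gaussian noise:
    pixel ~ Poisson(signal*scale)/scale + N(0, gaussian_sd), clipped at 0.
    """
    if psf_sigma <= 0:
        raise ParameterError("psf_sigma must be positive")
    ny, nx = shape
    if n_layers is None:
        n_layers = (max((u.z_layer for u in nuclei), default=0)) + 1
    for u in nuclei:
        if not (0 <= u.center[0] < nx and 0 <= u.center[1] < ny):
            raise ParameterError(f"nucleus {u.id} lies outside shape {shape}")
        if u.z_layer >= n_layers:
            raise ParameterError(f"nucleus {u.id} z_layer exceeds n_layers")
    rng = np.random.default_rng(rng_seed)
    gaussian_sd, poisson_scale = noise
    pixels = np.zeros((3, n_layers, ny, nx), dtype=np.float64)

    by_layer: dict[int, list[GroundTruthNucleus]] = {}
    for u in nuclei:
        by_layer.setdefault(u.z_layer, []).append(u)

    for z in range(n_layers):
        for u in by_layer.get(z, ()):  # DAPI
            _fill_ellipse(pixels[0, z], u, nucleus_amplitude)
        if by_layer.get(z):
            pixels[0, z] = gaussian(pixels[0, z], sigma=psf_sigma, preserve_range=True)
        for u in by_layer.get(z, ()):  # IEG foci
            for ch, count in ((1, u.n_dots_first), (2, u.n_dots_second)):
                for x, y in _dot_positions(
                    u, count, rng, dot_margin, min_dot_separation
                ):
                    _add_gaussian_bump(pixels[ch, z], x, y, psf_sigma, spot_amplitude)

    pixels += background
    if poisson_scale > 0:
        pixels = rng.poisson(pixels * poisson_scale).astype(np.float32)
        pixels /= poisson_scale
    else:
        pixels = pixels.astype(np.float32)
    if gaussian_sd > 0:
        pixels += gaussian_sd * rng.standard_normal(pixels.shape, dtype=np.float32)
    pixels = np.clip(pixels, 0.0, None)
    return ZStack(pixels=pixels, channel_names=CHANNELS, pixel_size=pixel_size)


def save_ground_truth(
    nuclei: Sequence[GroundTruthNucleus], path: str | Path
) -> None:
    """JSON sidecar with the full ground-truth nucleus list."""
    data = [
        {
            "id": u.id,
            "center": list(u.center),
            "axes": list(u.axes),
            "angle": u.angle,
            "z_layer": u.z_layer,
            "active_first": u.active_first,
            "active_second": u.active_second,
            "n_dots_first": u.n_dots_first,
            "n_dots_second": u.n_dots_second,
        }
        for u in nuclei
    ]
    with open(path, "w") as fh:
        json.dump(data, fh)


def load_ground_truth(path: str | Path) -> list[GroundTruthNucleus]:
    with open(path) as fh:
        data = json.load(fh)
    return [
        GroundTruthNucleus(
            id=d["id"],
            center=tuple(d["center"]),
            axes=tuple(d["axes"]),
            angle=d["angle"],
            z_layer=d["z_layer"],
            active_first=d["active_first"],
            active_second=d["active_second"],
            n_dots_first=d["n_dots_first"],
            n_dots_second=d["n_dots_second"],
        )
        for d in data
    ]


def simulate_trajectory(
    geometry: CageGeometry,
    bias: Mapping[str, float] | None = None,
    duration_s: float = 300.0,
    dt_s: float = 0.1,
    step_sd: float = 0.05,
    rng_seed: int = 0,
    entry_label: str = "first",
) -> Trajectory:
    """Reflecting-boundary biased random walk over the 5-region cage.

    Implemented as a Metropolis walk: a Gaussian step (SD ``step_sd`` meters,
    reflected at the walls) is accepted with probability
    min(1, w_new / w_old) where w is the attractiveness weight of the region
    the position falls in, so the long-run occupancy density is proportional
    to the region weights. Equal weights give a plain reflected random walk
    with near-uniform occupancy.
    """
    if duration_s <= 0 or dt_s <= 0:
        raise ParameterError("duration_s and dt_s must be positive")
    if step_sd <= 0:
        raise ParameterError("step_sd must be positive")
    weights = {r: 1.0 for r in REGIONS}
    if bias:
        unknown = set(bias) - set(REGIONS)
        if unknown:
            raise ParameterError(f"unknown regions in bias: {sorted(unknown)}")
        weights.update({r: float(w) for r, w in bias.items()})
    if any(w < 0 for w in weights.values()) or all(
        w == 0 for w in weights.values()
    ):
        raise ParameterError("bias weights must be non-negative, not all zero")

    rng = np.random.default_rng(rng_seed)
    n = int(round(duration_s / dt_s)) + 1
    side = geometry.side
    xs = np.empty(n)
    ys = np.empty(n)
    x, y = geometry.center_point()
    xs[0], ys[0] = x, y
    w_old = weights[geometry.region_of(x, y)]
    for i in range(1, n):
        px = x + rng.normal(0.0, step_sd)
        py = y + rng.normal(0.0, step_sd)
        # reflect into [0, side]
        px = abs(px)
        py = abs(py)
        if px > side:
            px = 2 * side - px
        if py > side:
            py = 2 * side - py
        px = min(max(px, 0.0), side)
        py = min(max(py, 0.0), side)
        w_new = weights[geometry.region_of(px, py)]
        if w_old <= 0:
            accept = True  # escape a zero-weight region immediately
        elif w_new >= w_old:
            accept = True
        else:
            accept = rng.uniform() < w_new / w_old
        if accept:
            x, y, w_old = px, py, w_new
        xs[i], ys[i] = x, y
    t = np.arange(n) * dt_s
    return Trajectory(t=t, x=xs, y=ys, entry_label=entry_label)


def simulate_descriptor_table(
    n_animals: int,
    structures: Sequence[str],
    planted: Mapping[str, float] | None = None,
    missing_rate: float = 0.0,
    rng_seed: int = 0,
    descriptors: Sequence[str] = DESCRIPTOR_NAMES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Animals x descriptors table with planted group effects.

    Null columns are i.i.d. standard normal across both groups; each planted
    column (full ``structure__descriptor`` name) is shifted by its effect
    size (in within-group SD units) in the second group. Missing entries are
    inserted completely at random at ``missing_rate``. Returns (X, y) where y
    is the binary group label ('recent'/'remote'), first half / second half.
    """
    if n_animals < 4:
        raise ParameterError("need at least 4 animals")
    if not (0.0 <= missing_rate < 1.0):
        raise ParameterError("missing_rate must be in [0, 1)")
    planted = dict(planted or {})
    columns = [f"{s}__{d}" for s in structures for d in descriptors]
    unknown = set(planted) - set(columns)
    if unknown:
        raise ParameterError(f"planted columns not in table: {sorted(unknown)}")
    for eff in planted.values():
        if not math.isfinite(eff):
            raise ParameterError("effect sizes must be finite")
    rng = np.random.default_rng(rng_seed)
    animals = [f"a{i + 1:02d}" for i in range(n_animals)]
    groups = np.array(
        ["recent"] * (n_animals // 2) + ["remote"] * (n_animals - n_animals // 2)
    )
    X = pd.DataFrame(
        rng.standard_normal((n_animals, len(columns))),
        index=pd.Index(animals, name="animal_id"),
        columns=columns,
    )
    for col, eff in planted.items():
        X.loc[groups == "remote", col] += eff
    if missing_rate > 0:
        mask = rng.uniform(size=X.shape) < missing_rate
        X = X.mask(mask)
    y = pd.Series(groups, index=X.index, name="group")
    return X, y
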