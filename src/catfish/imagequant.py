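"""Nucleus and transcription-focus quantification for two-gene catFISH z-stacks.

The measurement model: every field of view is a 3-channel confocal z-stack
(DAPI nuclear counter-stain, FITC for Homer-1a foci, Cy3 for Arc foci). Each
z-layer is analysed independently in 2-D — nuclei are segmented on the DAPI
channel, intranuclear transcription foci ("dots") are detected per IEG
channel, dots are assigned to the nucleus containing them, and every nucleus
is classified into one of four activity classes (double positive, Arc-only,
Homer-only, negative) by thresholding its per-IEG dot count. Per-layer class
fractions are aggregated to a per-structure record by taking the median over
the retained z-layers, after discarding the three bottom-most and three
top-most layers so that only whole cells contribute. Both hemispheres of a
structure are pooled at the nucleus level before fractions are computed.

Coordinate convention: pixel-centred, 0-based, x = column, y = row with y
increasing downward; ellipse angles are measured from the +x axis,
counter-clockwise in image coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.draw import polygon2mask
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

from .descriptors import ActivityRecord
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

CHANNELS = ("dapi", "homer", "arc")
#: Number of z-layers trimmed at each end of the stack before aggregation,
#: so that nuclei cut by the section surfaces are not quantified.
Z_TRIM = 3

KLASSES = ("both", "arc_only", "homer_only", "negative")


# ---------------------------------------------------------------------------
# containers


@dataclass
class ZStack:
    """One imaging field: ``pixels`` has shape (channel, z, y, x)."""

    pixels: np.ndarray
    channel_names: tuple[str, ...] = CHANNELS
    pixel_size: float = 0.32  # microns per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ParameterError("ZStack pixels must be 4-D (channel, z, y, x)")
        if self.pixels.shape[0] != 3:
            raise ParameterError("ZStack must have exactly three channels")
        if np.any(self.pixels < 0):
            raise DataError("ZStack intensities must be non-negative")

    @property
    def z_layers(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[self.channel_names.index(name)]

    # -- TIFF round trip (channel-major pages: page = c * n_z + z) --
    def save(self, path: str | Path) -> None:
        c, z, y, x = self.pixels.shape
        meta = {
            "channel_names": list(self.channel_names),
            "pixel_size": self.pixel_size,
            "n_channels": c,
            "n_layers": z,
        }
        tifffile.imwrite(
            str(path),
            self.pixels.reshape(c * z, y, x).astype(np.float32),
            description=json.dumps(meta),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ZStack":
        with tifffile.TiffFile(str(path)) as tif:
            pages = tif.asarray()
            desc = tif.pages[0].description
        try:
            meta = json.loads(desc)
            n_c = int(meta["n_channels"])
            names = tuple(meta["channel_names"])
            px = float(meta.get("pixel_size", 0.32))
        except (json.JSONDecodeError, KeyError, TypeError):
            # plain 3-channel TIFF without a sidecar description
            n_c, names, px = 3, CHANNELS, 0.32
        if pages.ndim == 3:
            n_z = pages.shape[0] // n_c
            pixels = pages.reshape(n_c, n_z, *pages.shape[1:])
        else:  # single page
            pixels = pages[None, None]
        return cls(pixels=pixels, channel_names=names, pixel_size=px)


@dataclass(frozen=True)
class Ellipse:
    """Fitted nucleus outline: center (cx, cy), semi-axes a >= b, angle."""

    cx: float
    cy: float
    a: float
    b: float
    angle: float

    def normalized_value(self, x: float, y: float) -> float:
        """Ellipse-equation value: <= 1 inside, 1 on the boundary."""
        dx, dy = x - self.cx, y - self.cy
        c, s = np.cos(self.angle), np.sin(self.angle)
        u = dx * c + dy * s
        v = -dx * s + dy * c
        return (u / self.a) ** 2 + (v / self.b) ** 2

    def contains(self, x: float, y: float) -> bool:
        return self.normalized_value(x, y) <= 1.0


@dataclass(frozen=True)
class Spot:
    """One detected transcription focus."""

    x: float
    y: float
    z_layer: int
    channel: str
    intensity: float


@dataclass
class NucleusRecord:
    """One classified nucleus on one z-layer."""

    id: int
    ellipse: Ellipse
    z_layer: int
    arc_dots: int
    homer_dots: int
    klass: str


@dataclass
class ROI:
    """One brain-structure region on a slice (one hemisphere)."""

    structure: str
    hemisphere: str | None = None
    mask: np.ndarray | None = None
    polygon: np.ndarray | None = None  # (n, 2) array of (x, y) vertices

    def mask_for(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask).astype(bool)
            if m.shape != tuple(shape):
                raise DataError(
                    f"ROI mask shape {m.shape} does not match image {shape}"
                )
        else:
            if self.polygon is None:
                raise DataError("ROI needs a mask or a polygon")
            poly = np.asarray(self.polygon, dtype=float)
            # polygon2mask expects (row, col) = (y, x)
            m = polygon2mask(shape, poly[:, ::-1])
        if not m.any():
            raise DataError(f"ROI {self.structure} mask is empty")
        return m

    def contains(self, x: float, y: float, shape: tuple[int, int]) -> bool:
        m = self.mask_for(shape)
        iy, ix = int(round(y)), int(round(x))
        if 0 <= iy < shape[0] and 0 <= ix < shape[1]:
            return bool(m[iy, ix])
        return False


def load_rois(path: str | Path) -> dict[str, list[ROI]]:
    """Read a polygon-JSON ROI file: structure -> vertices, or
    structure -> {hemisphere: vertices}."""
    with open(path) as fh:
        raw = json.load(fh)
    out: dict[str, list[ROI]] = {}
    for structure, val in raw.items():
        if isinstance(val, Mapping):
            out[structure] = [
                ROI(structure=structure, hemisphere=h, polygon=np.asarray(v, float))
                for h, v in val.items()
            ]
        else:
            out[structure] = [
                ROI(structure=structure, polygon=np.asarray(val, float))
            ]
    return out


def save_rois(rois: Mapping[str, Sequence[ROI]], path: str | Path) -> None:
    raw: dict = {}
    for structure, lst in rois.items():
        if len(lst) == 1 and lst[0].hemisphere is None:
            raw[structure] = np.asarray(lst[0].polygon).tolist()
        else:
            raw[structure] = {
                r.hemisphere or f"roi{i}": np.asarray(r.polygon).tolist()
                for i, r in enumerate(lst)
            }
    with open(path, "w") as fh:
        json.dump(raw, fh)


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class SegmentationParams:
    """Watershed nucleus segmentation settings for the DAPI channel."""

    smoothing_sigma: float = 2.0
    threshold_method: str = "otsu"  # or "absolute"
    absolute_threshold: float = 0.0
    min_area: float = 30.0
    max_area: float = 5000.0
    min_solidity: float = 0.8
    marker_min_distance: int = 6

    def validate(self) -> None:
        if self.smoothing_sigma <= 0:
            raise ParameterError("smoothing_sigma must be positive")
        if self.min_area <= 0 or self.max_area <= self.min_area:
            raise ParameterError("need 0 < min_area < max_area")
        if not (0 < self.min_solidity <= 1):
            raise ParameterError("min_solidity must be in (0, 1]")
        if self.threshold_method not in ("otsu", "absolute"):
            raise ParameterError(f"unknown threshold method {self.threshold_method!r}")


@dataclass(frozen=True)
class SpotParams:
    """Laplacian-of-Gaussian focus detection settings."""

    sigma: float = 1.2
    threshold: float | None = None  # None -> robust automatic threshold
    min_separation: int = 3
    auto_nsigma: float = 8.0  # MADs above median for the automatic threshold

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ParameterError("spot sigma must be positive")
        if self.min_separation < 1:
            raise ParameterError("min_separation must be >= 1")


@dataclass(frozen=True)
class QuantParams:
    """Bundle of all per-structure quantification settings."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    spots: SpotParams = field(default_factory=SpotParams)
    positivity_threshold: int = 1  # min dots for an IEG-positive call

    def validate(self) -> None:
        self.segmentation.validate()
        self.spots.validate()
        if self.positivity_threshold < 1:
            raise ParameterError("positivity_threshold must be >= 1")


# ---------------------------------------------------------------------------
# operations


def segment_nuclei(
    dapi_layer: np.ndarray, params: SegmentationParams | None = None
) -> list[Ellipse]:
    """Fit ellipses to nuclei in a single DAPI layer.

    The smoothed layer is thresholded (Otsu by default), touching blobs are
    split by marker-controlled watershed on the distance transform, and each
    surviving region (area and solidity filters) yields one ellipse via its
    second-order image moments.
    """
    params = params or SegmentationParams()
    params.validate()
    img = np.asarray(dapi_layer, dtype=float)
    if img.ndim != 2:
        raise ParameterError("segment_nuclei expects a single 2-D layer")
    smoothed = gaussian(img, sigma=params.smoothing_sigma, preserve_range=True)
    if smoothed.max() == smoothed.min():
        return []  # empty or constant image: nothing to segment
    if params.threshold_method == "otsu":
        thr = threshold_otsu(smoothed)
    else:
        thr = params.absolute_threshold
    fg = smoothed > thr
    if not fg.any():
        return []

    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=params.marker_min_distance, labels=fg,
        exclude_border=False,
    )
    markers = np.zeros(fg.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:
        labels = label(fg)
    else:
        labels = watershed(-dist, markers=markers, mask=fg)

    ellipses: list[Ellipse] = []
    for region in regionprops(labels):
        if not (params.min_area <= region.area <= params.max_area):
            continue
        if region.solidity < params.min_solidity:
            continue
        mu = region.moments_central
        m00 = mu[0, 0]
        # image moments in (row=y, col=x) order
        mxx, myy, mxy = mu[0, 2] / m00, mu[2, 0] / m00, mu[1, 1] / m00
        common = np.sqrt(((mxx - myy) / 2.0) ** 2 + mxy**2)
        lam1 = (mxx + myy) / 2.0 + common
        lam2 = (mxx + myy) / 2.0 - common
        a = 2.0 * np.sqrt(max(lam1, 0.0))
        b = 2.0 * np.sqrt(max(lam2, 0.0))
        angle = 0.5 * np.arctan2(2.0 * mxy, mxx - myy)
        cy, cx = region.centroid
        ellipses.append(Ellipse(cx=cx, cy=cy, a=a, b=max(b, 1e-6), angle=angle))
    return ellipses


def _log_response(img: np.ndarray, sigma: float) -> np.ndarray:
    # scale-normalised negated LoG: bright blobs -> positive peaks
    return -(sigma**2) * ndi.gaussian_laplace(img.astype(float), sigma)


def detect_spots(
    channel_layer: np.ndarray,
    params: SpotParams | None = None,
    z_layer: int = 0,
    channel: str = "arc",
) -> list[Spot]:
    """Detect transcription foci as local maxima of the (negated) LoG response.

    Sub-pixel centers come from a separable quadratic fit around each peak.
    """
    params = params or SpotParams()
    params.validate()
    img = np.asarray(channel_layer, dtype=float)
    if img.ndim != 2:
        raise ParameterError("detect_spots expects a single 2-D layer")
    resp = _log_response(img, params.sigma)
    if params.threshold is None:
        med = np.median(resp)
        mad = np.median(np.abs(resp - med)) + 1e-12
        thr = med + params.auto_nsigma * 1.4826 * mad
    else:
        thr = params.threshold
    peaks = peak_local_max(
        resp,
        min_distance=params.min_separation,
        threshold_abs=thr,
        exclude_border=False,
    )
    spots: list[Spot] = []
    ny, nx = resp.shape
    for py, px in peaks:
        dx = dy = 0.0
        if 0 < px < nx - 1:
            denom = resp[py, px - 1] - 2 * resp[py, px] + resp[py, px + 1]
            if denom < 0:
                dx = 0.5 * (resp[py, px - 1] - resp[py, px + 1]) / denom
        if 0 < py < ny - 1:
            denom = resp[py - 1, px] - 2 * resp[py, px] + resp[py + 1, px]
            if denom < 0:
                dy = 0.5 * (resp[py - 1, px] - resp[py + 1, px]) / denom
        spots.append(
            Spot(
                x=px + np.clip(dx, -0.5, 0.5),
                y=py + np.clip(dy, -0.5, 0.5),
                z_layer=z_layer,
                channel=channel,
                intensity=float(resp[py, px]),
            )
        )
    return spots


def assign_and_classify(
    ellipses: Sequence[Ellipse],
    spots_by_channel: Mapping[str, Sequence[Spot]],
    positivity_threshold: int = 1,
    roi: ROI | None = None,
    shape: tuple[int, int] | None = None,
    z_layer: int = 0,
) -> list[NucleusRecord]:
    """Assign foci to nuclei and classify each nucleus.

    A spot belongs to a nucleus iff its center satisfies the ellipse
    inequality; a spot inside several overlapping ellipses goes to the one it
    is deepest inside (smallest normalised ellipse-equation value), ties to
    the lower nucleus id. A nucleus is positive for an IEG iff its dot count
    reaches ``positivity_threshold``. Nuclei whose centers fall outside the
    ROI mask are dropped.
    """
    if positivity_threshold < 1:
        raise ParameterError("positivity_threshold must be >= 1")
    roi_mask = None
    if roi is not None:
        if shape is None:
            raise ParameterError("shape is required when filtering by ROI")
        roi_mask = roi.mask_for(shape)

    counts = {ch: np.zeros(len(ellipses), dtype=int) for ch in ("homer", "arc")}
    for ch in ("homer", "arc"):
        for spot in spots_by_channel.get(ch, ()):  # assignment per spot
            best_id, best_val = -1, np.inf
            for i, e in enumerate(ellipses):
                v = e.normalized_value(spot.x, spot.y)
                if v <= 1.0 and v < best_val - 1e-12:
                    best_id, best_val = i, v
            if best_id >= 0:
                counts[ch][best_id] += 1

    records: list[NucleusRecord] = []
    for i, e in enumerate(ellipses):
        if roi_mask is not None:
            iy, ix = int(round(e.cy)), int(round(e.cx))
            if not (
                0 <= iy < roi_mask.shape[0]
                and 0 <= ix < roi_mask.shape[1]
                and roi_mask[iy, ix]
            ):
                continue
        arc_pos = counts["arc"][i] >= positivity_threshold
        homer_pos = counts["homer"][i] >= positivity_threshold
        if arc_pos and homer_pos:
            klass = "both"
        elif arc_pos:
            klass = "arc_only"
        elif homer_pos:
            klass = "homer_only"
        else:
            klass = "negative"
        records.append(
            NucleusRecord(
                id=i,
                ellipse=e,
                z_layer=z_layer,
                arc_dots=int(counts["arc"][i]),
                homer_dots=int(counts["homer"][i]),
                klass=klass,
            )
        )
    return records


def class_fractions(records: Sequence[NucleusRecord]) -> dict[str, float]:
    """Fractions of the four activity classes over a pooled nucleus list."""
    n = len(records)
    if n == 0:
        raise DataError("no nuclei to compute class fractions from")
    out = {k: 0.0 for k in KLASSES}
    for r in records:
        out[r.klass] += 1.0
    return {k: v / n for k, v in out.items()}


def quantify_layer(
    stack: ZStack,
    z: int,
    rois: Sequence[ROI],
    params: QuantParams,
) -> list[NucleusRecord]:
    """Segment, detect and classify one z-layer, pooling nuclei over ROIs."""
    dapi = stack.channel("dapi")[z]
    ellipses = segment_nuclei(dapi, params.segmentation)
    spots = {
        ch: detect_spots(stack.channel(ch)[z], params.spots, z_layer=z, channel=ch)
        for ch in ("homer", "arc")
    }
    pooled: list[NucleusRecord] = []
    for roi in rois:
        pooled.extend(
            assign_and_classify(
                ellipses,
                spots,
                positivity_threshold=params.positivity_threshold,
                roi=roi,
                shape=stack.shape,
                z_layer=z,
            )
        )
    return pooled


def quantify_roi(
    stack: ZStack,
    rois: Sequence[ROI],
    params: QuantParams | None = None,
    animal_id: str = "",
) -> ActivityRecord:
    """Quantify one structure (both hemispheres pooled) over a z-stack.

    The three bottom-most and three top-most layers are excluded; for each
    retained layer the four class fractions are computed from the pooled
    nucleus list of both hemisphere ROIs, and the final record holds the
    per-class median across retained layers. A retained layer with zero
    nuclei contributes no fractions and is logged.
    """
    params = params or QuantParams()
    params.validate()
    if not rois:
        raise ParameterError("quantify_roi needs at least one ROI")
    n_z = stack.z_layers
    if n_z < 2 * Z_TRIM + 1:
        raise ParameterError(
            f"stack has {n_z} z-layers but trimming the {Z_TRIM} bottom-most and "
            f"{Z_TRIM} top-most layers requires at least {2 * Z_TRIM + 1}"
        )
    structure = rois[0].structure
    per_layer: list[dict[str, float]] = []
    n_nuclei: list[int] = []
    for z in range(Z_TRIM, n_z - Z_TRIM):
        records = quantify_layer(stack, z, rois, params)
        if not records:
            logger.warning(
                "structure %s: retained layer %d has zero nuclei; excluded "
                "from the median", structure, z,
            )
            continue
        per_layer.append(class_fractions(records))
        n_nuclei.append(len(records))
    if not per_layer:
        logger.warning("structure %s: no retained layer had nuclei", structure)
        fr = {k: float("nan") for k in KLASSES}
    else:
        fr = {k: float(np.median([d[k] for d in per_layer])) for k in KLASSES}
    return ActivityRecord(
        animal_id=animal_id,
        structure=structure,
        f_both=fr["both"],
        f_arc_only=fr["arc_only"],
        f_homer_only=fr["homer_only"],
        f_negative=fr["negative"],
        n_layers_used=len(per_layer),
        n_nuclei=int(np.median(n_nuclei)) if n_nuclei else 0,
    )


def records_to_frame(records: Iterable[NucleusRecord], structure: str = "") -> pd.DataFrame:
    """Per-nucleus table (id,structure,z,ex,ey,a,b,angle,arc_dots,homer_dots,class)."""
    rows = [
        {
            "id": r.id,
            "structure": structure,
            "z": r.z_layer,
            "ex": r.ellipse.cx,
            "ey": r.ellipse.cy,
            "a": r.ellipse.a,
            "b": r.ellipse.b,
            "angle": r.ellipse.angle,
            "arc_dots": r.arc_dots,
            "homer_dots": r.homer_dots,
            "class": r.klass,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "id", "structure", "z", "ex", "ey", "a", "b", "angle",
            "arc_dots", "homer_dots", "class",
        ],
    )
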