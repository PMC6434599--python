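"""Area-fraction quantification of double-stained tissue images.

The measurement implemented here is the in-situ analogue of a flow-cytometry
frequency: the fraction of epithelial tissue area that stains positive for a
marker, and the fraction of marker-A-positive area that is also positive for
marker B.  The procedure is

1. rasterize the manually drawn epithelium region of interest (ROI) minus any
   exclusion regions (broken tissue, cysts, artefacts, detached epithelium)
   into a binary analysis mask;
2. suppress broad background autofluorescence with a white tophat filter
   (image minus its morphological opening with a disk structuring element);
3. threshold each marker channel, either with a fixed intensity value or with
   an image-adaptive rule (a scale factor times the upper-quartile intensity
   of the image, by default 2 x Q3);
4. count positive pixels inside the analysis mask and report single- and
   double-positive areas as percentages of the analyzed tissue area and of
   the marker-A-positive area.

All geometric conventions are explicit: image origin at the top-left, x to
the right, y down, polygons in pixel coordinates, and a pixel belongs to a
polygon iff its *center* (col + 0.5, row + 0.5) lies inside it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage.morphology import disk, white_tophat as _sk_white_tophat

__all__ = [
    "ImageBundle",
    "RegionSet",
    "ThresholdSpec",
    "QuantRecord",
    "QuantConfig",
    "rasterize_regions",
    "white_tophat",
    "compute_threshold",
    "segment_positive",
    "area_fractions",
    "quantify_image",
    "records_to_frame",
    "read_image_bundle",
    "read_regions",
    "write_image_bundle",
    "write_regions",
]

CHANNEL_MAP_SUFFIX = ".channels.json"


@dataclass
class ImageBundle:
    """Registered per-channel intensity rasters for one tissue section.

    channels
        Mapping of channel name -> 2-D float array of non-negative
        intensities.  Conventional names: ``nuclei``, ``markerA``,
        ``markerB`` (e.g. DAPI, CD4, CCR5-or-Langerin).
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    image_id
        Free-form identifier carried into the quantification record.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    image_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageBundle requires at least one channel")
        shapes = {np.asarray(ch).shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("channels must be 2-D rasters")
        for name, ch in self.channels.items():
            arr = np.asarray(ch, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} has non-finite intensities")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = arr
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class RegionSet:
    """Epithelium ROI polygons and exclusion polygons in pixel coordinates.

    Each polygon is an (n, 2) array of (x, y) vertices of a simple closed
    ring.  Exclusions are subtracted from the ROI union when rasterizing.
    """

    roi_polygons: list[np.ndarray]
    exclusion_polygons: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.roi_polygons:
            raise ValueError("RegionSet requires at least one ROI polygon")
        self.roi_polygons = [_check_ring(p, "ROI") for p in self.roi_polygons]
        self.exclusion_polygons = [
            _check_ring(p, "exclusion") for p in self.exclusion_polygons
        ]


def _check_ring(coords: Sequence, kind: str) -> np.ndarray:
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError(f"{kind} polygon must be an (n>=3, 2) coordinate array")
    poly = Polygon(arr)
    if not poly.is_valid or poly.area == 0:
        raise ValueError(f"{kind} polygon is not simple (self-intersecting or degenerate)")
    return arr


@dataclass
class ThresholdSpec:
    """Rule producing a scalar intensity threshold for one channel.

    mode ``"fixed"`` returns ``fixed_value`` regardless of the image; mode
    ``"quartile_scaled"`` returns ``scale_k`` times the ``quantile_p``
    quantile of the channel intensities (linear-interpolation convention,
    h = (n-1)p), evaluated over the analysis mask by default.

    quantile_source selects the operand of the quantile: ``"raw"`` channel
    intensities (default) or the tophat-``"filtered"`` raster.  quantile_region
    selects the evaluation support: analysis ``"mask"`` (default) or the full
    ``"frame"``.
    """

    mode: str = "fixed"
    fixed_value: float = 0.0
    scale_k: float = 2.0
    quantile_p: float = 0.75
    quantile_source: str = "raw"
    quantile_region: str = "mask"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "quartile_scaled"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "fixed" and self.fixed_value < 0:
            raise ValueError("fixed_value must be >= 0")
        if not (self.scale_k > 0):
            raise ValueError("scale_k must be > 0")
        if not (0 < self.quantile_p < 1):
            raise ValueError("quantile_p must be in (0, 1)")
        if self.quantile_source not in ("raw", "filtered"):
            raise ValueError("quantile_source must be 'raw' or 'filtered'")
        if self.quantile_region not in ("mask", "frame"):
            raise ValueError("quantile_region must be 'mask' or 'frame'")


@dataclass
class QuantRecord:
    """Per-image stained-area result.

    Pixel counts are kept alongside the um^2 areas so every derived number
    can be audited against an exhaustive pixel count.  ``pct_ab_of_a`` is NaN
    (reported as missing) when no marker-A-positive area exists.
    """

    image_id: str
    analyzed_px: int
    a_px: int
    b_px: int
    ab_px: int
    analyzed_area_um2: float
    area_a_um2: float
    area_b_um2: float
    area_ab_um2: float
    pct_a_total: float
    pct_b_total: float
    pct_ab_total: float
    pct_ab_of_a: float
    threshold_a: float = float("nan")
    threshold_b: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class QuantConfig:
    """End-to-end configuration for :func:`quantify_image`.

    ``apply_to`` chooses the raster the thresholds are compared against:
    the tophat-``"filtered"`` raster (default) or the ``"raw"`` channel.
    """

    marker_a: str = "markerA"
    marker_b: str = "markerB"
    threshold_a: ThresholdSpec = field(
        default_factory=lambda: ThresholdSpec(mode="fixed", fixed_value=500.0)
    )
    threshold_b: ThresholdSpec = field(
        default_factory=lambda: ThresholdSpec(mode="quartile_scaled")
    )
    tophat_radius_px: int = 10
    apply_to: str = "filtered"

    def __post_init__(self) -> None:
        if self.tophat_radius_px < 1:
            raise ValueError("tophat_radius_px must be >= 1")
        if self.apply_to not in ("filtered", "raw"):
            raise ValueError("apply_to must be 'filtered' or 'raw'")

    def audit(self) -> dict:
        """Conventions actually in force, for the run log."""
        return {
            "marker_a": self.marker_a,
            "marker_b": self.marker_b,
            "threshold_a": asdict(self.threshold_a),
            "threshold_b": asdict(self.threshold_b),
            "tophat_radius_px": self.tophat_radius_px,
            "apply_to": self.apply_to,
            "inequality": "strict >",
            "quantile_convention": "linear interpolation, h=(n-1)p",
            "rasterization": "pixel-center-in-polygon, origin top-left, x right, y down",
        }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def rasterize_regions(
    regions: RegionSet, shape: tuple[int, int], pixel_size_um: float | None = None
) -> np.ndarray:
    """Rasterize ROI-minus-exclusions into a boolean analysis mask.

    A pixel at (row i, col j) is analyzed iff its center (j+0.5, i+0.5) lies
    inside the union of ROI polygons and outside every exclusion polygon.

    Raises ``ValueError("empty analysis region")`` when nothing survives.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("raster shape must be positive")
    roi = unary_union([Polygon(p) for p in regions.roi_polygons])
    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    xg, yg = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(roi, xg.ravel(), yg.ravel()).reshape(h, w)
    if regions.exclusion_polygons:
        excl = unary_union([Polygon(p) for p in regions.exclusion_polygons])
        mask &= ~shapely.contains_xy(excl, xg.ravel(), yg.ravel()).reshape(h, w)
    if not mask.any():
        raise ValueError("empty analysis region")
    return mask


def white_tophat(channel: np.ndarray, radius_px: int) -> np.ndarray:
    """White tophat: channel minus its morphological opening (disk element).

    Keeps bright structures smaller than the structuring element and removes
    broad background; output satisfies 0 <= out <= channel pointwise.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    arr = np.asarray(channel, dtype=float)
    return _sk_white_tophat(arr, footprint=disk(int(radius_px)))


def compute_threshold(
    channel: np.ndarray, mask: np.ndarray | None, spec: ThresholdSpec
) -> float:
    """Evaluate a ThresholdSpec on one channel.

    ``channel`` is the operand raster the caller selected (raw or filtered,
    per ``spec.quantile_source``).  In quartile mode the quantile is taken
    over ``channel[mask]`` (or the full frame if ``spec.quantile_region`` is
    ``"frame"``) with numpy's linear-interpolation convention.
    """
    if spec.mode == "fixed":
        return float(spec.fixed_value)
    arr = np.asarray(channel, dtype=float)
    if spec.quantile_region == "frame":
        vals = arr.ravel()
    else:
        if mask is None or not np.asarray(mask).any():
            raise ValueError("empty mask in quartile mode")
        vals = arr[np.asarray(mask, dtype=bool)]
    return float(spec.scale_k * np.quantile(vals, spec.quantile_p))


def segment_positive(
    filtered: np.ndarray, threshold: float, mask: np.ndarray
) -> np.ndarray:
    """Positively stained pixels: strictly above threshold AND in the mask."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    arr = np.asarray(filtered, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if arr.shape != m.shape:
        raise ValueError(f"shape mismatch: image {arr.shape} vs mask {m.shape}")
    return (arr > threshold) & m


def area_fractions(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    analysis_mask: np.ndarray,
    pixel_size_um: float,
    image_id: str = "",
    threshold_a: float = float("nan"),
    threshold_b: float = float("nan"),
) -> QuantRecord:
    """Single/double-positive areas as percentages of tissue and of A area.

    pct_ab_of_a is the headline double-stain statistic: the percentage of
    marker-A-positive area that also stains for marker B.  When the A area is
    zero it is undefined and reported as NaN, never as 0.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    m = np.asarray(analysis_mask, dtype=bool)
    if not (a.shape == b.shape == m.shape):
        raise ValueError("masks must share one shape")
    if np.any(a & ~m):
        raise ValueError("mask_A is not a subset of the analysis mask")
    if np.any(b & ~m):
        raise ValueError("mask_B is not a subset of the analysis mask")
    n_m = int(np.count_nonzero(m))
    if n_m == 0:
        raise ValueError("empty analysis region")
    n_a = int(np.count_nonzero(a))
    n_b = int(np.count_nonzero(b))
    n_ab = int(np.count_nonzero(a & b))
    px_um2 = float(pixel_size_um) ** 2
    return QuantRecord(
        image_id=image_id,
        analyzed_px=n_m,
        a_px=n_a,
        b_px=n_b,
        ab_px=n_ab,
        analyzed_area_um2=n_m * px_um2,
        area_a_um2=n_a * px_um2,
        area_b_um2=n_b * px_um2,
        area_ab_um2=n_ab * px_um2,
        pct_a_total=100.0 * n_a / n_m,
        pct_b_total=100.0 * n_b / n_m,
        pct_ab_total=100.0 * n_ab / n_m,
        pct_ab_of_a=(100.0 * n_ab / n_a) if n_a > 0 else float("nan"),
        threshold_a=float(threshold_a),
        threshold_b=float(threshold_b),
    )


def quantify_image(
    bundle: ImageBundle, regions: RegionSet, config: QuantConfig | None = None
) -> QuantRecord:
    """Full per-image quantification: rasterize -> tophat -> threshold -> count."""
    config = config or QuantConfig()
    for name in (config.marker_a, config.marker_b):
        if name not in bundle.channels:
            raise KeyError(f"channel {name!r} missing from image {bundle.image_id!r}")
    mask = rasterize_regions(regions, bundle.shape, bundle.pixel_size_um)

    def _segment(name: str, spec: ThresholdSpec) -> tuple[np.ndarray, float]:
        raw = bundle.channels[name]
        filt = white_tophat(raw, config.tophat_radius_px)
        operand = raw if spec.quantile_source == "raw" else filt
        thr = compute_threshold(operand, mask, spec)
        target = filt if config.apply_to == "filtered" else raw
        return segment_positive(target, thr, mask), thr

    try:
        pos_a, thr_a = _segment(config.marker_a, config.threshold_a)
        pos_b, thr_b = _segment(config.marker_b, config.threshold_b)
    except ValueError as exc:
        raise ValueError(f"image {bundle.image_id!r}: {exc}") from exc
    return area_fractions(
        pos_a,
        pos_b,
        mask,
        bundle.pixel_size_um,
        image_id=bundle.image_id,
        threshold_a=thr_a,
        threshold_b=thr_b,
    )


def records_to_frame(records: Iterable[QuantRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


# ---------------------------------------------------------------------------
# I/O: multi-channel TIFF + sidecar channel map, GeoJSON regions
# ---------------------------------------------------------------------------


def write_image_bundle(bundle: ImageBundle, path: str | Path) -> Path:
    """Write channels as a (C, H, W) TIFF plus a sidecar JSON channel map."""
    path = Path(path)
    names = list(bundle.channels)
    stack = np.stack([bundle.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        metadata={"axes": "CYX", "channels": names},
    )
    sidecar = path.with_suffix(path.suffix + CHANNEL_MAP_SUFFIX)
    sidecar.write_text(
        json.dumps(
            {
                "channels": names,
                "pixel_size_um": bundle.pixel_size_um,
                "image_id": bundle.image_id,
            },
            indent=1,
        )
    )
    return path


def read_image_bundle(
    path: str | Path, channel_map: Mapping | None = None
) -> ImageBundle:
    """Read a multi-channel TIFF; channel names from the sidecar JSON unless given."""
    path = Path(path)
    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if channel_map is None:
        sidecar = path.with_suffix(path.suffix + CHANNEL_MAP_SUFFIX)
        if not sidecar.exists():
            raise FileNotFoundError(f"no channel map for {path} (expected {sidecar})")
        channel_map = json.loads(sidecar.read_text())
    names = list(channel_map["channels"])
    if len(names) != stack.shape[0]:
        raise ValueError("channel map length disagrees with TIFF page count")
    return ImageBundle(
        channels={n: stack[i] for i, n in enumerate(names)},
        pixel_size_um=float(channel_map.get("pixel_size_um", 1.0)),
        image_id=str(channel_map.get("image_id", path.stem)),
    )


def write_regions(regions: RegionSet, path: str | Path) -> Path:
    """Write a RegionSet as a GeoJSON FeatureCollection (role: roi | exclude)."""
    feats = []
    for role, polys in (
        ("roi", regions.roi_polygons),
        ("exclude", regions.exclusion_polygons),
    ):
        for p in polys:
            ring = np.vstack([p, p[:1]]).tolist()
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"role": role},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}, indent=1))
    return path


def read_regions(path: str | Path) -> RegionSet:
    doc = json.loads(Path(path).read_text())
    roi, excl = [], []
    for feat in doc.get("features", []):
        role = feat.get("properties", {}).get("role")
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        (roi if role == "roi" else excl).append(ring)
    return RegionSet(roi_polygons=roi, exclusion_polygons=excl)
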