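"""Image pipeline: from a registered multi-channel fluorescence field to a
filtered per-cell feature table.

Stages follow the high-content screening convention for rare-cell work:

1. per-channel illumination correction (division by a smooth background
   field) and denoising (median filter);
2. Otsu thresholding of the nuclear (DAPI) channel — cells are defined as
   nucleated objects, marker channels are measured but never segmented;
3. 8-connected component labeling with hole filling; touching nuclei are
   kept as one object and flagged by their nuclear-peak count (clusters are
   candidate tumor microemboli, so no watershed declumping);
4. per-object morphology and per-channel intensity features with a local
   annulus background estimate;
5. measurement-based debris filtering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import feature, measure, transform

from .schema import CHANNELS

__all__ = [
    "FluorescentField",
    "SegmentedObject",
    "DebrisFilterSpec",
    "correct_illumination",
    "denoise",
    "otsu_threshold",
    "segment_objects",
    "extract_features",
    "filter_debris",
    "read_field_tiff",
    "write_field_tiff",
]


@dataclass
class FluorescentField:
    """A registered stack of same-shape channel images plus pixel size.

    Parameters
    ----------
    channels
        Mapping from channel name (``dapi``, ``ck``, ``cd45``) to a 2-D
        float array of non-negative intensities.
    pixel_size
        Lateral pixel size in µm/pixel.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 0.5

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("field needs at least one channel")
        shapes = {ch: np.asarray(img).shape for ch, img in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for ch, img in self.channels.items():
            arr = np.asarray(img, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {ch!r} is not a 2-D image")
            if (arr < 0).any():
                raise ValueError(f"channel {ch!r} has negative intensities")
            self.channels[ch] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def preprocessed(self, *, denoise_size: int = 3) -> "FluorescentField":
        """Illumination-corrected and denoised copy of every channel."""
        out = {
            ch: denoise(correct_illumination(img), size=denoise_size)
            for ch, img in self.channels.items()
        }
        return FluorescentField(out, pixel_size=self.pixel_size)


@dataclass
class SegmentedObject:
    """One segmented nucleated object."""

    label: int
    coords: np.ndarray          # (n, 2) array of (row, col) pixel indices
    centroid: tuple[float, float]  # (x, y) in pixels
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    outline: np.ndarray         # ordered boundary vertices, (m, 2) (row, col)
    on_border: bool = False
    nuclei_count: int = 1

    @property
    def area_px(self) -> int:
        return len(self.coords)

    def __post_init__(self) -> None:
        if len(self.coords) == 0:
            raise ValueError("object has an empty pixel set")


@dataclass(frozen=True)
class DebrisFilterSpec:
    """Measurement bounds separating intact cells from debris.

    Defaults are deliberately permissive placeholders: area between that of
    a ~6 µm and a ~30 µm object, near-convex shape, and a nucleus at least
    twofold over local background.
    """

    min_area_um2: float = 30.0
    max_area_um2: float = 700.0
    min_solidity: float = 0.7
    min_dapi_fold: float = 2.0

    def __post_init__(self) -> None:
        if not self.min_area_um2 < self.max_area_um2:
            raise ValueError("min_area_um2 must be below max_area_um2")


def correct_illumination(
    image: np.ndarray,
    *,
    sigma: float | None = None,
    opening_radius: int = 25,
    downsample: int | None = None,
) -> np.ndarray:
    """Divide out a smooth multiplicative illumination field.

    The background field is a heavy Gaussian blur (``sigma`` defaults to
    1/8 of the smaller image dimension) of the morphologically opened
    image; the opening removes foreground cells so that only the slowly
    varying illumination remains.  The corrected image is rescaled to
    preserve the global median.  For large fields the background is
    estimated on a block-averaged copy and resized back, which changes the
    estimate by far less than the blur scale.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if not img.any():
        warnings.warn("all-zero image: illumination correction skipped")
        return img.copy()
    min_dim = min(img.shape)
    if sigma is None:
        sigma = min_dim / 8.0
    if downsample is None:
        downsample = max(1, min_dim // 256)
    if downsample > 1:
        small = transform.downscale_local_mean(img, (downsample, downsample))
    else:
        small = img
    radius = max(1, int(round(opening_radius / downsample)))
    opened = ndimage.grey_opening(small, size=(2 * radius + 1, 2 * radius + 1))
    bg_small = ndimage.gaussian_filter(opened, sigma=sigma / downsample)
    if downsample > 1:
        bg = transform.resize(bg_small, img.shape, order=1, mode="edge",
                              anti_aliasing=False)
    else:
        bg = bg_small
    floor = 1e-3 * float(np.median(bg)) if np.median(bg) > 0 else 1e-12
    bg = np.maximum(bg, floor)
    corrected = img / bg
    med = float(np.median(corrected))
    if med > 0:
        corrected *= float(np.median(img)) / med
    return corrected


def denoise(image: np.ndarray, *, method: str = "median", size: int = 3) -> np.ndarray:
    """Remove shot noise; the default is a 3×3 median filter.

    The output never leaves the input intensity range.
    """
    img = np.asarray(image, dtype=float)
    if method != "median":
        raise ValueError(f"unknown denoise method {method!r}")
    if size % 2 == 0:
        raise ValueError("median kernel size must be odd")
    return ndimage.median_filter(img, size=size)


def otsu_threshold(
    image: np.ndarray | None = None,
    *,
    hist: np.ndarray | None = None,
    bin_centers: np.ndarray | None = None,
    nbins: int = 256,
) -> float:
    """Otsu threshold maximizing between-class variance on a binned histogram.

    Accepts either an image (binned into ``nbins`` equal-width bins over its
    range) or a precomputed histogram with optional bin centers.  The
    returned threshold is the center of the last background bin; foreground
    is strictly greater than the threshold.  Ties in between-class variance
    are broken toward the smallest threshold.
    """
    if hist is None:
        if image is None:
            raise ValueError("provide an image or a histogram")
        img = np.asarray(image, dtype=float).ravel()
        if np.unique(img).size < 2:
            raise ValueError("degenerate histogram: fewer than 2 distinct values")
        hist, edges = np.histogram(img, bins=nbins)
        bin_centers = (edges[:-1] + edges[1:]) / 2.0
    hist = np.asarray(hist, dtype=float)
    if bin_centers is None:
        bin_centers = np.arange(hist.size, dtype=float)
    bin_centers = np.asarray(bin_centers, dtype=float)
    if hist.size != bin_centers.size:
        raise ValueError("hist and bin_centers disagree in length")
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: fewer than 2 occupied bins")

    # Between-class variance for a cut after bin i (background = bins <= i):
    # w0 * w1 * (mu0 - mu1)^2, evaluated for every cut via cumulative sums.
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    m = np.cumsum(hist * bin_centers)
    mu0 = m[:-1] / np.where(w0 > 0, w0, np.nan)
    mu1 = (m[-1] - m[:-1]) / np.where(w1 > 0, w1, np.nan)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.where(np.isfinite(between), between, -np.inf)
    idx = int(np.argmax(between))  # argmax takes the first maximum: smallest t
    return float(bin_centers[idx])


def _nuclei_peak_count(
    dapi: np.ndarray, labels: np.ndarray, n_objects: int, *, min_distance: int
) -> np.ndarray:
    """Count smoothed-DAPI local maxima per labeled object (at least 1)."""
    smoothed = ndimage.gaussian_filter(dapi, sigma=2.0)
    peaks = feature.peak_local_max(
        smoothed, min_distance=min_distance, labels=labels, exclude_border=False
    )
    counts = np.ones(n_objects + 1, dtype=int)
    if len(peaks):
        peak_labels = labels[peaks[:, 0], peaks[:, 1]]
        binc = np.bincount(peak_labels, minlength=n_objects + 1)
        counts = np.maximum(binc, 1)
    return counts


def segment_objects(
    field: FluorescentField,
    *,
    preprocess: bool = True,
    nuclei_min_distance: int | None = None,
    with_outlines: bool = True,
) -> list[SegmentedObject]:
    """Segment nucleated objects on the DAPI channel.

    The DAPI channel is (optionally) preprocessed, Otsu-thresholded, holes
    are filled, and 8-connected components are labeled.  Objects touching
    the image border are retained and flagged.  Touching nuclei stay one
    object; ``nuclei_count`` is the number of DAPI local maxima inside the
    object, so a cluster of k nuclei reports k.
    """
    dapi = field.channels["dapi"]
    if preprocess:
        dapi = denoise(correct_illumination(dapi))
    try:
        t = otsu_threshold(dapi)
    except ValueError:
        return []  # constant image: no foreground
    mask = dapi > t
    if not mask.any():
        return []
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    if nuclei_min_distance is None:
        # ~0.7 of the median equivalent radius, at least 3 px
        areas = np.bincount(labels.ravel())[1:]
        med_r = float(np.sqrt(np.median(areas) / np.pi))
        nuclei_min_distance = max(3, int(round(0.7 * med_r)))
    peak_counts = _nuclei_peak_count(dapi, labels, n, min_distance=nuclei_min_distance)

    h, w = labels.shape
    objects: list[SegmentedObject] = []
    for lbl, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        crop = labels[sl] == lbl
        offset = np.array([sl[0].start, sl[1].start])
        coords = np.argwhere(crop) + offset
        minr, minc = offset
        maxr, maxc = sl[0].stop, sl[1].stop
        on_border = minr == 0 or minc == 0 or maxr == h or maxc == w
        if with_outlines:
            contours = measure.find_contours(np.pad(crop, 1).astype(float), 0.5)
            outline = (max(contours, key=len) + (offset - 1) if contours
                       else coords.astype(float))
        else:
            outline = np.empty((0, 2))
        cy, cx = coords.mean(axis=0)
        objects.append(
            SegmentedObject(
                label=lbl,
                coords=coords,
                centroid=(float(cx), float(cy)),
                bbox=(int(minr), int(minc), int(maxr), int(maxc)),
                outline=outline,
                on_border=bool(on_border),
                nuclei_count=int(peak_counts[lbl]),
            )
        )
    return objects


def _segment_stats(values: np.ndarray, seg_ids: np.ndarray,
                   n_labels: int) -> dict[str, np.ndarray]:
    """Mean/median/max/sum of ``values`` grouped by contiguous ``seg_ids``
    (sorted ascending, 1-based labels); labels with no pixels get NaN."""
    order = np.lexsort((values, seg_ids))
    v = values[order]
    ids = seg_ids[order]
    starts = np.searchsorted(ids, np.arange(1, n_labels + 2))
    out = {k: np.full(n_labels, np.nan) for k in ("mean", "median", "max", "sum")}
    for i in range(n_labels):
        a, b = starts[i], starts[i + 1]
        if a == b:
            continue
        seg = v[a:b]
        out["sum"][i] = seg.sum()
        out["mean"][i] = out["sum"][i] / (b - a)
        out["max"][i] = seg[-1]
        out["median"][i] = (seg[(a + b) // 2 - a] if (b - a) % 2
                            else 0.5 * (seg[(b - a) // 2 - 1] + seg[(b - a) // 2]))
    return out


def extract_features(
    field: FluorescentField,
    objects: list[SegmentedObject],
    *,
    annulus_inner: int = 2,
    annulus_outer: int = 5,
) -> pd.DataFrame:
    """One feature vector per segmented object.

    Morphology is reported in physical units via the field's pixel size;
    each channel contributes mean, median, max, integrated, a
    background-corrected mean (mean − annulus median) and a fold over the
    annulus median.  The local background ring is the ``annulus_inner``–
    ``annulus_outer`` px dilation band around each object, excluding
    pixels of any object; ring pixels shared between nearby objects go to
    the higher label, which leaves the median essentially unchanged on the
    smooth background the ring samples.
    """
    if not objects:
        return pd.DataFrame()
    for obj in objects:
        if len(obj.coords) == 0:
            raise ValueError(f"object {obj.label} has an empty pixel set")
    px = field.pixel_size
    shape = field.shape
    labels = np.zeros(shape, dtype=np.int32)
    for obj in objects:
        labels[obj.coords[:, 0], obj.coords[:, 1]] = obj.label
    n = max(obj.label for obj in objects)
    mask = labels > 0

    # background ring: between inner and outer Chebyshev dilation bands,
    # owned by the (max-filter) nearest label, excluding object pixels
    inner_band = ndimage.maximum_filter(mask, size=2 * annulus_inner + 1)
    outer_band = ndimage.maximum_filter(mask, size=2 * annulus_outer + 1)
    ring = outer_band & ~inner_band
    owner = ndimage.maximum_filter(labels, size=2 * annulus_outer + 1)

    fg_idx = np.flatnonzero(labels.ravel())
    fg_ids = labels.ravel()[fg_idx]
    ring_idx = np.flatnonzero(ring.ravel())
    ring_ids = owner.ravel()[ring_idx]

    # area, centroid and eccentricity from vectorized image moments;
    # perimeter and solidity (convex hull) from skimage
    w_img = shape[1]
    fg_rows = (fg_idx // w_img).astype(float)
    fg_cols = (fg_idx % w_img).astype(float)
    area_all = np.bincount(fg_ids, minlength=n + 1)[1:].astype(float)
    sr = np.bincount(fg_ids, weights=fg_rows, minlength=n + 1)[1:]
    sc = np.bincount(fg_ids, weights=fg_cols, minlength=n + 1)[1:]
    cr, cc = sr / area_all, sc / area_all
    srr = np.bincount(fg_ids, weights=fg_rows**2, minlength=n + 1)[1:]
    scc = np.bincount(fg_ids, weights=fg_cols**2, minlength=n + 1)[1:]
    src = np.bincount(fg_ids, weights=fg_rows * fg_cols, minlength=n + 1)[1:]
    mu20 = srr / area_all - cr**2
    mu02 = scc / area_all - cc**2
    mu11 = src / area_all - cr * cc
    half = (mu20 + mu02) / 2.0
    delta = np.sqrt(((mu20 - mu02) / 2.0) ** 2 + mu11**2)
    lam1, lam2 = half + delta, np.maximum(half - delta, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ecc_all = np.where(lam1 > 0, np.sqrt(1.0 - lam2 / np.maximum(lam1, 1e-30)),
                           0.0)

    morph = measure.regionprops_table(labels, properties=("label", "perimeter",
                                                          "solidity"))
    by_label = {int(l): i for i, l in enumerate(morph["label"])}

    table: dict[str, np.ndarray] = {}
    obj_order = [by_label[obj.label] for obj in objects]
    label_arr = np.array([obj.label for obj in objects])
    area_px = area_all[label_arr - 1]
    perimeter_px = morph["perimeter"][obj_order].astype(float)
    table["label"] = label_arr
    table["centroid_x"] = np.array([obj.centroid[0] for obj in objects])
    table["centroid_y"] = np.array([obj.centroid[1] for obj in objects])
    table["centroid_x_um"] = table["centroid_x"] * px
    table["centroid_y_um"] = table["centroid_y"] * px
    table["on_border"] = np.array([obj.on_border for obj in objects])
    table["nuclei_count"] = np.array([obj.nuclei_count for obj in objects])
    table["area_um2"] = area_px * px * px
    table["perimeter_um"] = perimeter_px * px
    table["equiv_diameter_um"] = 2.0 * np.sqrt(area_px / np.pi) * px
    table["eccentricity"] = ecc_all[label_arr - 1]
    table["solidity"] = morph["solidity"][obj_order].astype(float)
    with np.errstate(divide="ignore"):
        ff = np.where(perimeter_px > 0,
                      4.0 * np.pi * area_px / perimeter_px**2, 1.0)
    table["form_factor"] = ff

    label_index = label_arr
    for ch in CHANNELS:
        values = field.channels[ch].ravel()
        stats = _segment_stats(values[fg_idx], fg_ids, n)
        ring_stats = _segment_stats(values[ring_idx], ring_ids, n)
        bg = ring_stats["median"]
        bg = np.where(np.isnan(bg), np.median(values), bg)
        mean = stats["mean"][label_index - 1]
        bg = bg[label_index - 1]
        table[f"{ch}_mean"] = mean
        table[f"{ch}_median"] = stats["median"][label_index - 1]
        table[f"{ch}_max"] = stats["max"][label_index - 1]
        table[f"{ch}_integrated"] = stats["sum"][label_index - 1]
        table[f"{ch}_corr_mean"] = np.maximum(mean - bg, 0.0)
        table[f"{ch}_fold"] = mean / np.maximum(bg, 1e-9)
    return pd.DataFrame(table)


def filter_debris(
    table: pd.DataFrame, spec: DebrisFilterSpec = DebrisFilterSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a feature table into (kept cells, removed debris).

    A row is kept iff all bounds hold; rows with missing values in any
    gated measurement are removed.  The two outputs partition the input.
    """
    if table.empty:
        return table.copy(), table.copy()
    gated = table[["area_um2", "solidity", "dapi_fold"]]
    keep = (
        (table["area_um2"] >= spec.min_area_um2)
        & (table["area_um2"] <= spec.max_area_um2)
        & (table["solidity"] >= spec.min_solidity)
        & (table["dapi_fold"] >= spec.min_dapi_fold)
        & gated.notna().all(axis=1)
    )
    return table[keep].copy(), table[~keep].copy()


def write_field_tiff(field: FluorescentField, path: str | Path,
                     metadata: dict | None = None) -> None:
    """Write a field as a multi-page TIFF (page order: DAPI, CK, CD45) with
    a JSON sidecar recording pixel size and optional provenance metadata."""
    path = Path(path)
    stack = np.stack([field.channels[ch] for ch in CHANNELS])
    tifffile.imwrite(path, stack.astype(np.float32), photometric="minisblack")
    sidecar = {"pixel_size_um": field.pixel_size, "channel_order": list(CHANNELS)}
    if metadata:
        sidecar["metadata"] = metadata
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_field_tiff(path: str | Path) -> FluorescentField:
    """Read a field written by :func:`write_field_tiff`."""
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar_path = path.with_suffix(".json")
    pixel_size = 0.5
    order = list(CHANNELS)
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        pixel_size = float(sidecar.get("pixel_size_um", pixel_size))
        order = list(sidecar.get("channel_order", order))
    channels = {ch: np.asarray(stack[i], dtype=float) for i, ch in enumerate(order)}
    return FluorescentField(channels, pixel_size=pixel_size)
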