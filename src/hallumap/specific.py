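"""Specific hallucination maps: localizing structured regions in a map.

The transform ``T`` turns a (null-space or error) map into a binary map of
coherent, task-relevant regions: restrict to the object support, histogram-
equalize, smooth with a small Gaussian, keep the top intensity percentile,
and drop tiny connected components.  The pipeline is deterministic and
scale-free (invariant to multiplying the input map by any positive factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.exposure import equalize_hist
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .maps import HallucinationMap


@dataclass
class TransformConfig:
    """Parameters of the localization transform ``T``.

    ``gaussian_width`` is the (odd) kernel width in pixels of the smoothing
    filter, realized as a truncated Gaussian of standard deviation
    ``gaussian_width / 4``.  The intensity threshold is the ``percentile``-th
    percentile of the processed values over in-support pixels (strictly
    exceeded); connected components smaller than ``min_component_px`` are
    discarded.
    """

    gaussian_width: int = 7
    gaussian_sigma: Optional[float] = None  # defaults to gaussian_width / 4
    percentile: float = 95.0
    min_component_px: int = 100
    connectivity: int = 8  # {4, 8}-neighbor

    def __post_init__(self):
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must be in (0, 100)")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.gaussian_sigma is None:
            self.gaussian_sigma = self.gaussian_width / 4.0


@dataclass
class SpecificMap:
    """Binary localization map plus connected-region descriptors."""

    binary: np.ndarray
    regions: List[Tuple[float, float, int]]  # (centroid_row, centroid_col, area)
    source_space: str = ""
    config: Optional[TransformConfig] = None

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def otsu_support(obj: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Binary object-support mask by Otsu's between-class-variance threshold."""
    obj = np.asarray(obj, dtype=float)
    if np.ptp(obj) == 0:
        raise ValueError("cannot compute an Otsu threshold for a constant image")
    thresh = threshold_otsu(obj, nbins=nbins)
    return obj > thresh


def transform_T(
    hmap: Union[HallucinationMap, np.ndarray],
    support_mask: np.ndarray,
    config: Optional[TransformConfig] = None,
) -> SpecificMap:
    """Apply the localization transform ``T`` to a hallucination or error map.

    Steps: absolute value; zero outside support; histogram equalization over
    in-support pixels (256 bins); Gaussian smoothing; binarization strictly
    above the configured percentile of in-support processed values; removal
    of connected components below ``min_component_px``.

    A map that is constant (e.g. identically zero) within the support carries
    no structure and yields an empty map.
    """
    config = config or TransformConfig()
    values = hmap.values if isinstance(hmap, HallucinationMap) else np.asarray(hmap)
    source_space = hmap.space if isinstance(hmap, HallucinationMap) else ""
    support = np.asarray(support_mask).astype(bool)
    if values.shape != support.shape:
        raise ValueError(f"map shape {values.shape} != support shape {support.shape}")
    if not support.any():
        raise ValueError("support mask is empty")

    amag = np.abs(values) * support
    if np.ptp(amag[support]) == 0:
        binary = np.zeros(support.shape, dtype=bool)
        return SpecificMap(binary=binary, regions=[], source_space=source_space, config=config)

    equalized = equalize_hist(amag, nbins=256, mask=support) * support
    radius = max(int(config.gaussian_width) // 2, 1)
    smoothed = gaussian_filter(equalized, sigma=config.gaussian_sigma, radius=radius)
    cutoff = np.percentile(smoothed[support], config.percentile)
    binary = (smoothed > cutoff) & support

    labeled = label(binary, connectivity=1 if config.connectivity == 4 else 2)
    regions: List[Tuple[float, float, int]] = []
    keep = np.zeros(support.shape, dtype=bool)
    for props in regionprops(labeled):
        if props.area >= config.min_component_px:
            keep |= labeled == props.label
            regions.append((float(props.centroid[0]), float(props.centroid[1]), int(props.area)))
    return SpecificMap(binary=keep, regions=regions, source_space=source_space, config=config)


def region_centroids(
    maps: Sequence[SpecificMap], image_ids: Optional[Sequence] = None
) -> List[Dict]:
    """Flatten region descriptors into rows of (image_id, space, row, col, area)."""
    if image_ids is None:
        image_ids = list(range(len(maps)))
    rows = []
    for image_id, smap in zip(image_ids, maps):
        for cy, cx, area in smap.regions:
            rows.append(
                dict(image_id=image_id, space=smap.source_space, row=cy, col=cx, area=area)
            )
    return rows


def centroid_scatter(table: Sequence[Dict]) -> Dict[str, float]:
    """Per-space scatter of region centroids: trace of the centroid covariance.

    Quantifies how spread out detected regions are across an ensemble; random
    error-driven regions scatter more widely than prior-driven ones.
    """
    out: Dict[str, float] = {}
    spaces = sorted({row["space"] for row in table})
    for space in spaces:
        pts = np.array([(r["row"], r["col"]) for r in table if r["space"] == space])
        if len(pts) < 2:
            out[space] = 0.0
        else:
            out[space] = float(np.trace(np.cov(pts.T)))
    return out
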