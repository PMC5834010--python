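"""Nucleus detection in H&E-like RGB images.

The chain is deliberately classical: colour deconvolution into
haematoxylin/eosin channels (fixed Ruifrok-Johnston stain matrix), Gaussian
smoothing, Otsu (or fixed) thresholding, hole filling, and a
distance-transform watershed to split touching nuclei, followed by an area
filter.  Every stage is parameterised; the downstream density statistic
needs only centroids, so no attempt is made at pixel-perfect boundaries.

All geometry is reported in microns; the mandatory ``microns_per_pixel``
calibration has no default on purpose.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb2hed
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .errors import ConfigurationError, FormatError


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable stages of the nucleus detector.

    microns_per_pixel has no default: the pixel size must come from the
    scanner/renderer calibration.  Areas are in square microns; the default
    bounds (8-250 um^2) bracket lymphocyte through cancer nuclei generously.
    """

    microns_per_pixel: float
    smoothing_sigma_um: float = 1.0
    threshold: Union[str, float] = "otsu"  # "otsu" or an absolute OD value
    min_area_um2: float = 8.0
    max_area_um2: float = 250.0
    min_peak_distance_um: float = 4.0

    def validate(self) -> "SegmentationParams":
        if not (self.microns_per_pixel > 0):
            raise ConfigurationError("microns_per_pixel must be > 0")
        if self.min_area_um2 >= self.max_area_um2:
            raise ConfigurationError("min_area_um2 must be < max_area_um2")
        if self.smoothing_sigma_um < 0 or self.min_peak_distance_um <= 0:
            raise ConfigurationError("smoothing/peak-distance scales must be positive")
        if not (self.threshold == "otsu" or isinstance(self.threshold, (int, float))):
            raise ConfigurationError(f"unknown threshold mode {self.threshold!r}")
        return self


@dataclass
class NucleusObject:
    """One segmented nucleus: centroid in microns plus its pixel mask."""

    centroid_um: tuple[float, float]  # (x, y)
    coords: np.ndarray  # (n, 2) array of (row, col) pixel indices
    area_um2: float
    image_id: Optional[str] = None

    @property
    def n_pixels(self) -> int:
        return len(self.coords)


def separate_stains(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Colour-deconvolve an 8-bit RGB image into (haematoxylin, eosin) OD.

    Uses the standard H&E stain vectors; channels are clipped at zero so
    they are non-negative optical densities.  An all-black input saturates
    the optical density but remains finite (the transform works on
    intensities clipped away from zero).
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError(f"expected an RGB image (H, W, 3), got shape {img.shape}")
    if img.dtype != np.uint8:
        raise FormatError(f"expected 8-bit RGB, got dtype {img.dtype}")
    hed = rgb2hed(img)
    h = np.clip(hed[..., 0], 0.0, None)
    e = np.clip(hed[..., 1], 0.0, None)
    return h, e


def detect_nuclei(
    channel: np.ndarray,
    params: SegmentationParams,
    image_id: Optional[str] = None,
) -> list[NucleusObject]:
    """Detect nuclei in a single (haematoxylin) channel.

    Pipeline: Gaussian smoothing -> threshold (Otsu by default) -> hole
    filling -> distance-transform watershed -> area filter.  Returns objects
    sorted row-major by centroid so the output order is deterministic.
    An image without foreground yields an empty list, not an error.
    """
    params.validate()
    chan = np.asarray(channel, dtype=float)
    if chan.ndim != 2:
        raise FormatError(f"expected a single-channel image, got shape {chan.shape}")
    if chan.size == 0:
        return []

    mpp = params.microns_per_pixel
    sigma_px = params.smoothing_sigma_um / mpp
    smoothed = gaussian(chan, sigma=sigma_px, preserve_range=True) if sigma_px > 0 else chan

    if params.threshold == "otsu":
        if np.ptp(smoothed) == 0:  # constant image: nothing to segment
            return []
        thr = threshold_otsu(smoothed)
    else:
        thr = float(params.threshold)
    mask = smoothed > thr
    if not mask.any():
        return []
    mask = ndi.binary_fill_holes(mask)

    distance = ndi.distance_transform_edt(mask)
    min_dist_px = max(1, int(round(params.min_peak_distance_um / mpp)))
    peaks = peak_local_max(distance, min_distance=min_dist_px, labels=mask)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if len(peaks) == 0:
        labels, _ = ndi.label(mask)
    else:
        labels = watershed(-distance, markers, mask=mask)

    px_area = mpp * mpp
    objects: list[NucleusObject] = []
    for region in regionprops(labels):
        area_um2 = region.area * px_area
        if area_um2 < params.min_area_um2 or area_um2 > params.max_area_um2:
            continue
        cy, cx = region.centroid  # (row, col)
        objects.append(
            NucleusObject(
                centroid_um=(cx * mpp, cy * mpp),
                coords=region.coords.copy(),
                area_um2=area_um2,
                image_id=image_id,
            )
        )
    objects.sort(key=lambda o: (o.centroid_um[1], o.centroid_um[0]))
    return objects


def segment_image(
    image: np.ndarray,
    params: SegmentationParams,
    image_id: Optional[str] = None,
) -> tuple[list[NucleusObject], np.ndarray]:
    """Full stage: stain separation then detection.

    Returns the nucleus list together with the haematoxylin channel (which
    feature extraction reuses for intensity statistics).
    """
    h, _ = separate_stains(image)
    return detect_nuclei(h, params, image_id=image_id), h


def nuclei_to_frame(objects: list[NucleusObject]) -> pd.DataFrame:
    """Tabulate detections as nucleus_id, x_um, y_um, area_um2."""
    return pd.DataFrame(
        {
            "nucleus_id": np.arange(len(objects)),
            "x_um": [o.centroid_um[0] for o in objects],
            "y_um": [o.centroid_um[1] for o in objects],
            "area_um2": [o.area_um2 for o in objects],
        }
    )


def match_to_ground_truth(
    objects: list[NucleusObject],
    truth_xy: np.ndarray,
    truth_radius: np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """Greedy one-to-one match of detections to true nuclei.

    A detection matches a truth point when their centroid distance is below
    that nucleus' radius.  Returns (truth index per detection, -1 if
    unmatched; recall; precision).  Used by validation tests and reported
    in pipeline logs; not part of the measurement path.
    """
    truth_xy = np.asarray(truth_xy, dtype=float)
    n_truth = len(truth_xy)
    assigned = np.full(len(objects), -1, dtype=int)
    if n_truth == 0 or len(objects) == 0:
        return assigned, 0.0, 0.0
    det_xy = np.array([o.centroid_um for o in objects])
    d2 = ((det_xy[:, None, :] - truth_xy[None, :, :]) ** 2).sum(axis=2)
    taken = np.zeros(n_truth, dtype=bool)
    order = np.argsort(d2.min(axis=1))
    for i in order:
        j = int(np.argmin(np.where(taken, np.inf, d2[i])))
        if not taken[j] and d2[i, j] <= truth_radius[j] ** 2:
            assigned[i] = j
            taken[j] = True
    n_match = int((assigned >= 0).sum())
    recall = n_match / n_truth
    precision = n_match / len(objects)
    return assigned, recall, precision
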