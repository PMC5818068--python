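"""Lung segmentation and multi-gray-level candidate detection.

Candidates are detected and segmented simultaneously: the lung field is
thresholded at a ladder of HU levels, each threshold is paired with a
morphological opening whose ball radius shrinks as the threshold rises
(low thresholds catch faint extended structure and need aggressive
opening; high thresholds isolate bright cores and need almost none), a
size/compactness expert filter prunes each intermediate mask, and the
survivors are OR-fused into a final candidate mask whose 26-connected
components become the candidates.

The exact ladder is configurable; the default is 15 levels uniformly
spaced over [-700, 0] HU with opening radii falling linearly from 3.0 mm
to 0.5 mm.  Openings use Euclidean balls specified in mm and realized per
volume spacing via two distance-transform passes (erode-then-dilate),
which is exact for balls and fast at clinical radii.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, voxel_to_world

__all__ = [
    "DetectorParams",
    "Candidate",
    "segment_lungs",
    "detect_candidates",
    "expert_filter",
    "ball_opening",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _default_thresholds() -> tuple[float, ...]:
    return tuple(np.linspace(-700.0, 0.0, 15))


def _default_radii() -> tuple[float, ...]:
    # Paired radii fall linearly as the threshold rises.  The start radius is
    # set just below the smallest nodule core the ladder should keep: a 4-mm
    # sphere thresholded near its base level retains a ~2.3-mm core after
    # boundary smoothing, so 2.0 mm keeps >3-mm nodules detectable while
    # still erasing sub-candidate speckle.
    return tuple(np.linspace(2.0, 0.25, 15))


@dataclass(frozen=True)
class DetectorParams:
    """Detector configuration; every constant of the ladder is overridable."""

    thresholds_hu: tuple[float, ...] = field(default_factory=_default_thresholds)
    opening_radii_mm: tuple[float, ...] = field(default_factory=_default_radii)
    volume_bounds_mm3: tuple[float, float] = (4.0, 50000.0)
    min_compactness: float = 0.15
    lung_threshold_hu: float = -300.0
    lung_closing_radius_mm: float = 3.0

    def __post_init__(self) -> None:
        t = self.thresholds_hu
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.opening_radii_mm) != len(t):
            raise ValueError("need exactly one opening radius per threshold")
        lo, hi = self.volume_bounds_mm3
        if not (0 < lo < hi):
            raise ValueError("volume bounds must be positive and ordered")


@dataclass
class Candidate:
    """A detected-and-segmented connected component."""

    case_id: str
    indices: np.ndarray  # (n, 3) voxel indices into the source volume
    centroid_mm: tuple[float, float, float]
    volume_mm3: float
    features: object | None = None
    score: float | None = None
    target_id: int | None = None

    @property
    def n_voxels(self) -> int:
        return self.indices.shape[0]


def ball_opening(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Binary opening by a Euclidean ball of ``radius_mm``.

    Implemented as two anisotropic-sampling distance transforms: erosion
    keeps voxels whose distance to background is >= radius, dilation then
    recovers voxels within radius of the eroded core.  Radii below the
    finest spacing degenerate to the identity, matching a single-voxel
    structuring element.
    """
    if radius_mm < min(spacing):
        return mask.copy()
    if not mask.any():
        return mask.copy()
    # pad with one background layer so the volume border erodes like
    # structuring-element morphology (outside counts as background)
    padded = np.pad(mask, 1)
    dist_in = ndimage.distance_transform_edt(padded, sampling=spacing)
    crop = tuple(slice(1, -1) for _ in range(3))
    eroded = (dist_in > radius_mm)[crop]
    if not eroded.any():
        return np.zeros_like(mask)
    dist_out = ndimage.distance_transform_edt(~eroded, sampling=spacing)
    return dist_out <= radius_mm


def segment_lungs(vol: CTVolume, params: DetectorParams | None = None) -> np.ndarray:
    """Segment the lung fields of a thoracic HU volume.

    Air-range voxels (HU below -300 by default) are labeled; components
    touching the lateral volume border are discarded as outside-body air,
    the two largest remaining cavities are kept as the lungs, and internal
    holes (vessels) are closed with a 3-mm ball.
    """
    params = params or DetectorParams()
    air = vol.data < params.lung_threshold_hu
    if not air.any():
        return np.zeros(vol.shape, dtype=bool)
    labels, n = ndimage.label(air, structure=_CONN26)
    if n == 0:
        return np.zeros(vol.shape, dtype=bool)
    border_labels = np.unique(
        np.concatenate(
            [
                labels[0, :, :].ravel(),
                labels[-1, :, :].ravel(),
                labels[:, 0, :].ravel(),
                labels[:, -1, :].ravel(),
            ]
        )
    )
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    for lab in border_labels:
        counts[lab] = 0
    keep = np.argsort(counts)[::-1][:2]
    keep = [int(k) for k in keep if counts[k] > 0]
    if not keep:
        warnings.warn("no interior air cavity found; empty lung mask", stacklevel=2)
        return np.zeros(vol.shape, dtype=bool)
    mask = np.isin(labels, keep)
    # close vessel holes: dilate-then-erode with a Euclidean ball
    r = params.lung_closing_radius_mm
    dist = ndimage.distance_transform_edt(~mask, sampling=vol.spacing)
    dilated = dist <= r
    dist2 = ndimage.distance_transform_edt(dilated, sampling=vol.spacing)
    return dist2 > r


def expert_filter(components, spacing, params: DetectorParams | None = None):
    """Keep components with plausible nodule size and compactness.

    ``components`` is a list of (n, 3) voxel-index arrays.  A component
    survives iff its volume in mm^3 lies inside ``volume_bounds_mm3`` and
    its compactness — volume over axis-aligned bounding-box volume — is at
    least ``min_compactness``.
    """
    params = params or DetectorParams()
    voxel_mm3 = float(np.prod(spacing))
    lo, hi = params.volume_bounds_mm3
    kept = []
    for idx in components:
        vol_mm3 = idx.shape[0] * voxel_mm3
        if not (lo <= vol_mm3 <= hi):
            continue
        extent = idx.max(axis=0) - idx.min(axis=0) + 1
        compactness = idx.shape[0] / float(np.prod(extent))
        if compactness >= params.min_compactness:
            kept.append(idx)
    return kept


def _components(mask: np.ndarray, offset=(0, 0, 0)) -> list[np.ndarray]:
    labels, n = ndimage.label(mask, structure=_CONN26)
    out = []
    for sl_idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        local = np.argwhere(labels[sl] == sl_idx)
        base = np.array([s.start for s in sl]) + np.asarray(offset)
        out.append(local + base)
    return out


def detect_candidates(
    vol: CTVolume, lung_mask: np.ndarray, params: DetectorParams | None = None
) -> list[Candidate]:
    """Run the full multi-threshold detect-and-segment chain on one case.

    Returns the 26-connected components of the OR-fused final mask as
    :class:`Candidate` objects with world-mm centroids; an empty list is a
    valid outcome.
    """
    params = params or DetectorParams()
    if not lung_mask.any():
        return []
    # work on the lung bounding box only; morphology cost drops sharply
    bbox = ndimage.find_objects(lung_mask.astype(np.int8), max_label=1)[0]
    pad = 2
    sl = tuple(
        slice(max(s.start - pad, 0), min(s.stop + pad, dim))
        for s, dim in zip(bbox, vol.shape)
    )
    data = vol.data[sl]
    lung = lung_mask[sl]
    offset = np.array([s.start for s in sl])

    final = np.zeros(data.shape, dtype=bool)
    for threshold, radius in zip(params.thresholds_hu, params.opening_radii_mm):
        intermediate = (data >= threshold) & lung
        if not intermediate.any():
            continue
        opened = ball_opening(intermediate, radius, vol.spacing)
        survivors = expert_filter(_components(opened), vol.spacing, params)
        for idx in survivors:
            final[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    candidates = []
    for idx in _components(final, offset=offset):
        centroid_idx = idx.mean(axis=0)
        centroid = voxel_to_world(vol.geometry, centroid_idx)
        candidates.append(
            Candidate(
                case_id="",
                indices=idx,
                centroid_mm=tuple(float(c) for c in centroid),
                volume_mm3=idx.shape[0] * float(np.prod(vol.spacing)),
            )
        )
    return candidates
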