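"""Per-pillar centreline extraction from 3D fluorescence z-stacks.

The measurement protocol mirrors slice-wise confocal analysis of deflected
micropillars: each z slice is binarized, adjacent pillar footprints are
separated by a distance-transform-seeded watershed, and the intensity
weighted centre of mass of every footprint is computed.  Footprints are then
linked across slices by nearest-centroid matching to form one centreline per
pillar, and before/after centreline pairs are differenced and projected onto
the inward (toward ring centre) direction to yield deflection profiles that
feed the Euler-beam force fit.

Coordinates are physical (µm): the centre of voxel ``(0, 0, 0)`` sits at the
physical origin and axis order is ``(z, y, x)``; ``z`` increases away from
the substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .beam import DeflectionProfile
from .errors import SegmentationError, ValidationError

__all__ = [
    "VoxelStack",
    "Centerline",
    "segment_stack",
    "extract_centerlines",
    "profiles_from_centerlines",
]


@dataclass
class VoxelStack:
    """A 3D intensity stack with physical voxel size.

    Attributes
    ----------
    intensities : ndarray, shape (nz, ny, nx)
        Non-negative intensities, axis order (slice z, row y, column x).
    voxel_size : (dz, dy, dx)
        Voxel edge lengths in µm.
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise ValidationError("intensities must be a non-empty 3D array")
        if np.any(np.asarray(self.intensities.min()) < 0):
            raise ValidationError("intensities must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size must be three positive lengths (µm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def z_of_slice(self, k: int) -> float:
        """Physical height (µm) of slice ``k``."""
        return k * self.voxel_size[0]


@dataclass
class Centerline:
    """Per-slice centre-of-mass track of one pillar.

    ``z`` is strictly increasing; slices where the pillar was not detected
    are simply absent.
    """

    pillar_id: int
    z: np.ndarray
    cx: np.ndarray
    cy: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.cx = np.asarray(self.cx, dtype=float)
        self.cy = np.asarray(self.cy, dtype=float)
        if not (self.z.shape == self.cx.shape == self.cy.shape):
            raise ValidationError("z, cx, cy must have equal lengths")
        if np.any(np.diff(self.z) <= 0):
            raise ValidationError("centerline z must be strictly increasing")

    @property
    def base_xy(self) -> tuple[float, float]:
        """(cx, cy) of the lowest detected slice."""
        return float(self.cx[0]), float(self.cy[0])

    def __len__(self) -> int:
        return len(self.z)


def _binarize(img: np.ndarray, threshold_method) -> np.ndarray:
    if isinstance(threshold_method, (int, float)):
        return img > threshold_method
    if threshold_method == "otsu":
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=bool)
        return img > threshold_otsu(img)
    if (isinstance(threshold_method, tuple) and len(threshold_method) == 2
            and threshold_method[0] == "percentile"):
        return img > np.percentile(img, threshold_method[1])
    raise ValidationError(
        f"unknown threshold_method {threshold_method!r}; use 'otsu', a fixed "
        f"value, or ('percentile', p)")


def _split_watershed(mask: np.ndarray, min_separation_px: int) -> np.ndarray:
    """Label a binary slice, splitting touching objects by watershed."""
    distance = ndi.distance_transform_edt(mask)
    base_labels, _ = ndi.label(mask)
    coords = peak_local_max(distance, min_distance=max(min_separation_px, 1),
                            labels=base_labels, exclude_border=False)
    if len(coords) == 0:
        return base_labels
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    return watershed(-distance, markers, mask=mask)


def segment_stack(stack: VoxelStack,
                  threshold_method="otsu",
                  min_area_voxels: int = 20,
                  min_seed_separation_um: float = 1.0,
                  max_link_um: float = 2.0) -> np.ndarray:
    """Segment pillar footprints slice by slice with consistent labels.

    Each slice is binarized (Otsu by default), touching footprints are split
    by a watershed seeded from local maxima of the Euclidean distance
    transform (minimum seed separation of about one pillar radius), and
    components smaller than ``min_area_voxels`` are discarded.  Components
    are then linked across slices by nearest-centroid matching within
    ``max_link_um`` so that a pillar keeps one label along the whole stack.

    Returns
    -------
    ndarray of int, same shape as the stack
        0 for background; positive consistent labels per pillar.

    Raises
    ------
    SegmentationError
        If no component is found in any slice.
    """
    dz, dy, dx = stack.voxel_size
    sep_px = int(round(min_seed_separation_um / max(dy, dx)))
    labels_out = np.zeros(stack.shape, dtype=np.int32)
    # id -> most recent centroid (in px) for cross-slice linking
    last_seen: dict[int, np.ndarray] = {}
    next_id = 1
    found_any = False

    for k in range(stack.shape[0]):
        img = np.asarray(stack.intensities[k], dtype=float)
        mask = _binarize(img, threshold_method)
        if not mask.any():
            continue
        slice_labels = _split_watershed(mask, sep_px)
        props = []
        for lab in np.unique(slice_labels):
            if lab == 0:
                continue
            region = slice_labels == lab
            area = int(region.sum())
            if area < min_area_voxels:
                slice_labels[region] = 0
                continue
            cy_px, cx_px = ndi.center_of_mass(img, labels=slice_labels, index=lab)
            props.append((lab, np.array([cy_px, cx_px])))
        if not props:
            continue
        found_any = True
        # link to existing pillars: globally optimal assignment, ties and
        # conflicts resolved by total displacement
        ids = sorted(last_seen)
        assigned: dict[int, int] = {}
        if ids:
            cost = np.full((len(props), len(ids)), np.inf)
            for i, (_, c) in enumerate(props):
                for j, gid in enumerate(ids):
                    disp = (c - last_seen[gid]) * np.array([dy, dx])
                    dist = float(np.hypot(*disp))
                    if dist <= max_link_um:
                        cost[i, j] = dist
            finite = np.isfinite(cost)
            if finite.any():
                big = 1e6
                rows, cols = linear_sum_assignment(np.where(finite, cost, big))
                for i, j in zip(rows, cols):
                    if finite[i, j]:
                        assigned[i] = ids[j]
        for i, (lab, c) in enumerate(props):
            gid = assigned.get(i)
            if gid is None:
                gid = next_id
                next_id += 1
            last_seen[gid] = c
            labels_out[k][slice_labels == lab] = gid

    if not found_any:
        raise SegmentationError("no objects found in any slice of the stack")
    return labels_out


def extract_centerlines(labels: np.ndarray, stack: VoxelStack
                        ) -> list[Centerline]:
    """Intensity-weighted per-slice centroids for every labelled pillar.

    Returns one :class:`Centerline` per label, in physical µm coordinates,
    ordered by label id.
    """
    if labels.shape != stack.shape:
        raise ValidationError("labels and stack shapes differ")
    dz, dy, dx = stack.voxel_size
    tracks: dict[int, list[tuple[float, float, float]]] = {}
    for k in range(stack.shape[0]):
        slab = labels[k]
        present = np.unique(slab)
        present = present[present > 0]
        if len(present) == 0:
            continue
        img = np.asarray(stack.intensities[k], dtype=float)
        coms = ndi.center_of_mass(img, labels=slab, index=present)
        for gid, (cy_px, cx_px) in zip(present, np.atleast_2d(coms)):
            tracks.setdefault(int(gid), []).append(
                (stack.z_of_slice(k), cx_px * dx, cy_px * dy))
    out = []
    for gid in sorted(tracks):
        arr = np.array(tracks[gid])
        out.append(Centerline(pillar_id=gid, z=arr[:, 0], cx=arr[:, 1],
                              cy=arr[:, 2]))
    return out


def _match_by_base(before: Sequence[Centerline], after: Sequence[Centerline]
                   ) -> list[tuple[Centerline, Centerline]]:
    if len(before) != len(after):
        b_ids = [c.pillar_id for c in before]
        a_ids = [c.pillar_id for c in after]
        raise ValidationError(
            f"unmatched pillar counts: before has {len(before)} ({b_ids}), "
            f"after has {len(after)} ({a_ids})")
    cost = np.zeros((len(before), len(after)))
    for i, cb in enumerate(before):
        for j, ca in enumerate(after):
            cost[i, j] = np.hypot(cb.base_xy[0] - ca.base_xy[0],
                                  cb.base_xy[1] - ca.base_xy[1])
    rows, cols = linear_sum_assignment(cost)
    return [(before[i], after[j]) for i, j in zip(rows, cols)]


def profiles_from_centerlines(before: Sequence[Centerline],
                              after: Sequence[Centerline],
                              ring_centre: tuple[float, float]
                              ) -> list[tuple[int, DeflectionProfile]]:
    """Signed deflection profiles from before/after centreline pairs.

    Pillars are matched by nearest base centroid.  For every height present
    in both centrelines, the displacement of the after-centroid relative to
    the before-centroid is projected onto the unit vector from the pillar
    base toward ``ring_centre``; positive deflection therefore points inward.

    Returns ``[(pillar_id, DeflectionProfile), ...]`` using the before ids.
    """
    pairs = _match_by_base(before, after)
    out = []
    for cb, ca in pairs:
        bx, by = cb.base_xy
        ux, uy = ring_centre[0] - bx, ring_centre[1] - by
        norm = np.hypot(ux, uy)
        if norm == 0:
            raise ValidationError(
                f"pillar {cb.pillar_id} base coincides with the ring centre")
        ux, uy = ux / norm, uy / norm
        common, ib, ia = np.intersect1d(np.round(cb.z, 9), np.round(ca.z, 9),
                                        return_indices=True)
        if len(common) == 0:
            raise ValidationError(
                f"pillar {cb.pillar_id}: no common heights between before "
                f"and after centrelines")
        w = ((ca.cx[ia] - cb.cx[ib]) * ux + (ca.cy[ia] - cb.cy[ib]) * uy)
        out.append((cb.pillar_id, DeflectionProfile(z=common, w=w)))
    return out
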