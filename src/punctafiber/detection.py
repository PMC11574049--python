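"""Spot detection: local intensity maxima above a threshold inside a fiber mask.

A punctum is a pixel strictly greater than all of its neighbors, or a
connected plateau of equal values strictly greater than every pixel adjacent
to the plateau, reported once at the plateau centroid. A detection is kept
iff its intensity is strictly above the threshold AND the reported pixel
lies inside the mask. Border pixels compare only against existing neighbors.

Edge conventions (shared by both implementations):

* a plateau spanning the whole image is not a maximum, except for a
  degenerate 1x1 image whose single pixel has no neighbors at all;
* plateau centroids are rounded half-up; if the rounded centroid falls off
  the plateau, the plateau member smallest in (y, x) row-major order is
  reported instead.

``detect_maxima`` is the vectorized production path; ``brute_force_maxima``
is a deliberately naive exhaustive reference with the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging_io import BinaryMask, ChannelImage

__all__ = ["Spot", "SpotList", "detect_maxima", "brute_force_maxima", "spot_filter"]

DEFAULT_THRESHOLD = 200.0


@dataclass(frozen=True)
class Spot:
    y: int
    x: int
    intensity: float
    in_mask: bool = True


@dataclass
class SpotList:
    """Detected spots in deterministic row-major (y, x) order."""

    spots: list[Spot] = field(default_factory=list)
    image_id: str = ""
    threshold: float = DEFAULT_THRESHOLD
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spots = sorted(self.spots, key=lambda s: (s.y, s.x))
        coords = [(s.y, s.x) for s in self.spots]
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate spot coordinates")

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)

    def coords(self) -> list[tuple[int, int]]:
        return [(s.y, s.x) for s in self.spots]


def _footprint(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    raise ValueError("connectivity must be 4 or 8")


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def _report_pixel(members: np.ndarray) -> tuple[int, int]:
    """Centroid of plateau members, rounded half-up; fall back to the
    row-major smallest member if the rounded centroid is off-plateau."""
    cy = _round_half_up(float(members[:, 0].mean()))
    cx = _round_half_up(float(members[:, 1].mean()))
    member_set = {(int(y), int(x)) for y, x in members}
    if (cy, cx) in member_set:
        return cy, cx
    return min(member_set)


def detect_maxima(
    channel: ChannelImage,
    mask: BinaryMask,
    threshold: float = DEFAULT_THRESHOLD,
    connectivity: int = 8,
    image_id: str = "",
) -> SpotList:
    """Vectorized maxima detection restricted to ``mask``.

    Candidate pixels (no strictly greater neighbor) are found with a
    maximum filter; connected candidate components are equal-valued
    plateaus, kept when no adjacent pixel matches the plateau value.
    """
    img = np.asarray(channel.pixels)
    if img.shape != mask.pixels.shape:
        raise ValueError(f"channel shape {img.shape} != mask shape {mask.pixels.shape}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    fp = _footprint(connectivity)
    ring = fp.copy()
    ring[1, 1] = False

    work = img.astype(np.float64)
    neighbor_max = ndimage.maximum_filter(work, footprint=ring, mode="constant", cval=-np.inf)
    candidates = work >= neighbor_max  # no strictly greater neighbor

    structure = fp  # same adjacency for plateau labeling
    labels, n_labels = ndimage.label(candidates, structure=structure)

    spots: list[Spot] = []
    whole_image_px = img.size
    for lab in range(1, n_labels + 1):
        members = np.argwhere(labels == lab)
        value = work[members[0, 0], members[0, 1]]
        if len(members) == whole_image_px:
            if whole_image_px > 1:
                continue  # constant multi-pixel image: no maxima
        else:
            # reject plateaus with an equal-valued neighbor (partial plateaus)
            comp_mask = labels == lab
            boundary = ndimage.binary_dilation(comp_mask, structure=structure) & ~comp_mask
            if boundary.any() and work[boundary].max() >= value:
                continue
        if value <= threshold:
            continue
        ry, rx = _report_pixel(members)
        if not mask.pixels[ry, rx]:
            continue
        spots.append(Spot(y=ry, x=rx, intensity=float(img[ry, rx]), in_mask=True))

    return SpotList(
        spots=spots,
        image_id=image_id,
        threshold=threshold,
        params={"connectivity": connectivity, "impl": "detect_maxima"},
    )


def brute_force_maxima(
    channel: ChannelImage,
    mask: BinaryMask,
    threshold: float = DEFAULT_THRESHOLD,
    connectivity: int = 8,
    image_id: str = "",
) -> SpotList:
    """Exhaustive reference implementation of the detect_maxima contract.

    Per-pixel flood fill of equal-valued plateaus with explicit neighbor
    comparisons; intentionally unoptimized.
    """
    img = np.asarray(channel.pixels)
    if img.shape != mask.pixels.shape:
        raise ValueError(f"channel shape {img.shape} != mask shape {mask.pixels.shape}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    h, w = img.shape
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        offsets = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        raise ValueError("connectivity must be 4 or 8")

    visited = np.zeros((h, w), dtype=bool)
    spots: list[Spot] = []
    for sy in range(h):
        for sx in range(w):
            if visited[sy, sx]:
                continue
            value = img[sy, sx]
            # flood the equal-value plateau containing (sy, sx)
            plateau = [(sy, sx)]
            visited[sy, sx] = True
            queue = [(sy, sx)]
            is_max = True
            has_neighbor = False
            while queue:
                y, x = queue.pop()
                for dy, dx in offsets:
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < h and 0 <= nx < w):
                        continue
                    nv = img[ny, nx]
                    if nv == value:
                        if not visited[ny, nx]:
                            visited[ny, nx] = True
                            plateau.append((ny, nx))
                            queue.append((ny, nx))
                    else:
                        has_neighbor = True
                        if nv > value:
                            is_max = False
            if not is_max:
                continue
            if not has_neighbor and h * w > 1:
                continue  # plateau covers the whole image
            if not (value > threshold):
                continue
            members = np.array(sorted(plateau))
            ry, rx = _report_pixel(members)
            if not mask.pixels[ry, rx]:
                continue
            spots.append(Spot(y=ry, x=rx, intensity=float(img[ry, rx]), in_mask=True))

    return SpotList(
        spots=spots,
        image_id=image_id,
        threshold=threshold,
        params={"connectivity": connectivity, "impl": "brute_force_maxima"},
    )


def spot_filter(spots: SpotList, min_separation_px: float) -> SpotList:
    """Greedy de-duplication: keep brighter spots first, drop any spot closer
    than ``min_separation_px`` to an already-kept spot. Ties break by
    (intensity desc, y, x)."""
    if min_separation_px < 0:
        raise ValueError("min_separation_px must be >= 0")
    if min_separation_px == 0:
        return SpotList(
            spots=list(spots.spots),
            image_id=spots.image_id,
            threshold=spots.threshold,
            params=dict(spots.params),
        )
    ordered = sorted(spots.spots, key=lambda s: (-s.intensity, s.y, s.x))
    kept: list[Spot] = []
    sep2 = min_separation_px**2
    for s in ordered:
        if all((s.y - k.y) ** 2 + (s.x - k.x) ** 2 >= sep2 for k in kept):
            kept.append(s)
    params = dict(spots.params)
    params["min_separation_px"] = min_separation_px
    return SpotList(spots=kept, image_id=spots.image_id, threshold=spots.threshold, params=params)
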