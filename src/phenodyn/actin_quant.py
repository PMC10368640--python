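"""Actin stress-fiber detection and 4-class scoring.

Cables are detected by a multi-scale ridge (Hessian line) filter, thresholded,
skeletonised and split at branch points into polylines; width along each
skeleton comes from the distance transform of the bright-pixel mask.  Cells
are then scored with explicit quantifiers standing in for visual criteria:

* class 1 — heavy cables cover > 90% of the central area (a central pixel
  is covered when it lies within ``cover_radius`` of a heavy skeleton);
* class 2 — at least two heavy cables enter the central region and fine
  cables fill the rest;
* class 3 — only fine cables (at least one reaching the central region);
* class 4 — nothing detectable in the central area.

The central region is the cell mask shrunk about its centroid to half the
area; the same construction serves the mitochondrial peripheral fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import sato, threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "Cable",
    "ActinResult",
    "detect_cables",
    "central_region",
    "classify_actin",
    "skeleton_polylines",
]


@dataclass
class Cable:
    polyline: np.ndarray  # (K, 2) row/col skeleton path
    width: float  # px
    ridge_intensity: float
    tier: str  # "heavy" | "fine"
    intersects_central: bool = False

    def __post_init__(self) -> None:
        if self.polyline.shape[0] < 2:
            raise ValueError("cable polyline needs >= 2 points")
        if self.width <= 0:
            raise ValueError("cable width must be positive")


@dataclass
class ActinResult:
    cell_id: str
    cables: list[Cable]
    central_coverage: float
    n_heavy_central: int
    actin_class: int

    @property
    def n_heavy(self) -> int:
        return sum(1 for c in self.cables if c.tier == "heavy")

    @property
    def n_fine(self) -> int:
        return sum(1 for c in self.cables if c.tier == "fine")


# --- skeleton tracing ------------------------------------------------------

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbour_count(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def skeleton_polylines(skel: np.ndarray, min_length: int = 2) -> list[np.ndarray]:
    """Split a skeleton at branch points and trace each branch as an
    ordered polyline (row/col points)."""
    nb = _neighbour_count(skel)
    branches = skel & (nb >= 3)
    segments = skel & ~branches
    labels, n = ndimage.label(segments, structure=np.ones((3, 3), dtype=int))
    polylines = []
    for lab in range(1, n + 1):
        pts = np.argwhere(labels == lab)
        if len(pts) < min_length:
            continue
        polylines.append(_order_segment(pts, labels, lab))
    return polylines


def _order_segment(pts: np.ndarray, labels: np.ndarray, lab: int) -> np.ndarray:
    """Order the pixels of a (near-)linear segment by walking from an end."""
    ptset = {tuple(p) for p in map(tuple, pts)}
    deg = {}
    for p in ptset:
        deg[p] = sum(((p[0] + dr, p[1] + dc) in ptset) for dr, dc in _NEIGHBOURS)
    ends = [p for p, d in deg.items() if d <= 1]
    start = min(ends) if ends else min(ptset)
    ordered = [start]
    seen = {start}
    cur = start
    while True:
        nxt = None
        for dr, dc in _NEIGHBOURS:
            q = (cur[0] + dr, cur[1] + dc)
            if q in ptset and q not in seen:
                nxt = q
                break
        if nxt is None:
            break
        ordered.append(nxt)
        seen.add(nxt)
        cur = nxt
    return np.array(ordered)


# --- operations ------------------------------------------------------------

def detect_cables(
    channel: np.ndarray,
    cell_mask: np.ndarray,
    scales: tuple[float, ...] = (1.0, 2.0, 3.0),
    ridge_thr: float = 0.08,
    width_split: float = 3.5,
    min_length_px: int = 10,
    psf_sigma: float = 0.0,
) -> list[Cable]:
    """Detect actin cables in one channel.

    ``ridge_thr`` is relative to the maximum ridge response inside the
    mask.  Width per cable is ``2 * median(EDT) - 1`` along the skeleton
    of the thresholded ridge support (median resists crossing artefacts);
    when the optical PSF sigma is known it is removed from the apparent
    width in quadrature (a Gaussian PSF widens a bar by ~2.355 sigma at
    half maximum).  Tier is heavy when the corrected width reaches
    ``width_split`` px.  Cables shorter than ``min_length_px`` along the
    skeleton are discarded as clutter.
    """
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    img = channel.astype(float)
    if img.max() > 0:
        img = img / img.max()

    response = sato(img, sigmas=scales, black_ridges=False)
    response[~cell_mask] = 0.0
    if response.max() <= 0:
        return []
    ridge_mask = response > ridge_thr * response.max()

    # Background level and noise scale come from outside the cell, where
    # there is no signal by construction — inside, dense cable coverage can
    # leave no clean background to estimate from.
    outside = img[~cell_mask]
    ref = outside if outside.size >= 100 else img[cell_mask]
    bg = float(np.median(ref))
    noise_scale = 1.4826 * float(np.median(np.abs(ref - bg))) + 1e-12
    amp = float(np.quantile(img[cell_mask], 0.995)) - bg
    if amp < 8.0 * noise_scale:
        return []
    bright = (img > bg + max(0.15 * amp, 4.0 * noise_scale)) & cell_mask
    support = ridge_mask & bright
    if not support.any():
        return []

    skel = skeletonize(support)
    cables = []
    for poly in skeleton_polylines(skel):
        arclen = np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)) if len(poly) > 1 else 0
        if arclen < min_length_px:
            continue
        rr, cc = poly[:, 0], poly[:, 1]
        width = _cable_width(img, bg, poly, psf_sigma)
        cables.append(
            Cable(
                polyline=poly,
                width=width,
                ridge_intensity=float(response[rr, cc].mean()),
                tier="heavy" if width >= width_split else "fine",
            )
        )
    return cables


def _cable_width(img: np.ndarray, bg: float, poly: np.ndarray, psf_sigma: float) -> float:
    """Width of one cable as its median full width at half maximum.

    At every few skeleton points the intensity is sampled along the local
    perpendicular at quarter-pixel resolution and the run above half the
    cable's own peak is measured — orientation-independent, unlike a
    distance transform on the pixel lattice.  Known PSF broadening is
    removed in quadrature (a Gaussian PSF widens a bar by ~2.355 sigma at
    half maximum).
    """
    peak = float(np.median(img[poly[:, 0], poly[:, 1]]))
    if peak <= bg:
        return 1.0
    half = bg + 0.5 * (peak - bg)

    stride = max(len(poly) // 15, 1)
    step = 0.25
    offsets = np.arange(-8.0, 8.0 + step, step)
    widths = []
    k = 3  # tangent from neighbours k apart
    for j in range(0, len(poly), stride):
        j0, j1 = max(j - k, 0), min(j + k, len(poly) - 1)
        tan = poly[j1].astype(float) - poly[j0].astype(float)
        norm = np.linalg.norm(tan)
        if norm == 0:
            continue
        tan /= norm
        perp = np.array([-tan[1], tan[0]])
        samples = ndimage.map_coordinates(
            img,
            [poly[j][0] + offsets * perp[0], poly[j][1] + offsets * perp[1]],
            order=1,
            mode="nearest",
        )
        above = samples > half
        if not above[len(offsets) // 2]:
            continue
        # contiguous run through the centre
        lo = len(offsets) // 2
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = len(offsets) // 2
        while hi < len(offsets) - 1 and above[hi + 1]:
            hi += 1
        widths.append((hi - lo + 1) * step)
    if not widths:
        return 1.0
    width_raw = float(np.median(widths))
    return float(np.sqrt(max(width_raw**2 - (2.355 * psf_sigma) ** 2, 1.0)))


def central_region(cell_mask: np.ndarray, area_fraction: float = 0.5) -> np.ndarray:
    """Shrink the cell mask about its centroid to ``area_fraction`` of its
    area (within 1%), by uniform scaling of the pixel lattice."""
    if not 0.0 < area_fraction < 1.0:
        if area_fraction == 1.0:
            return cell_mask.copy()
        raise ValueError("area fraction must lie in (0, 1]")
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    target = area_fraction * cell_mask.sum()
    centroid = np.array(ndimage.center_of_mass(cell_mask))
    rr, cc = np.mgrid[0 : cell_mask.shape[0], 0 : cell_mask.shape[1]]
    coords = np.stack([rr, cc]).astype(float)

    def region(s: float) -> np.ndarray:
        # pixel p is in the region iff centroid + (p - centroid)/s is in the mask
        mapped = centroid[:, None, None] + (coords - centroid[:, None, None]) / s
        sampled = ndimage.map_coordinates(
            cell_mask.astype(np.uint8), mapped.reshape(2, -1), order=0, cval=0
        ).reshape(cell_mask.shape)
        return sampled.astype(bool) & cell_mask

    lo, hi = 0.05, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        area = region(mid).sum()
        if abs(area - target) <= 0.01 * target:
            return region(mid)
        if area > target:
            hi = mid
        else:
            lo = mid
    return region(0.5 * (lo + hi))


def classify_actin(
    cables: list[Cable],
    cell_mask: np.ndarray,
    cover_radius: float = 15.0,
    cell_id: str = "",
    central: np.ndarray | None = None,
) -> ActinResult:
    """Apply the 4-class decision rules in order (class 1 tested first,
    since blanket coverage subsumes the class-2 condition)."""
    central_mask = central_region(cell_mask) if central is None else central

    heavy_skel = np.zeros(cell_mask.shape, dtype=bool)
    for c in cables:
        hit = central_mask[c.polyline[:, 0], c.polyline[:, 1]].any()
        c.intersects_central = bool(hit)
        if c.tier == "heavy":
            heavy_skel[c.polyline[:, 0], c.polyline[:, 1]] = True

    if heavy_skel.any():
        dist = ndimage.distance_transform_edt(~heavy_skel)
        coverage = float((dist[central_mask] <= cover_radius).mean())
    else:
        coverage = 0.0

    n_heavy_central = sum(1 for c in cables if c.tier == "heavy" and c.intersects_central)
    n_fine = sum(1 for c in cables if c.tier == "fine")
    any_central = any(c.intersects_central for c in cables)
    any_heavy = any(c.tier == "heavy" for c in cables)

    if coverage > 0.90:
        klass = 1
    elif n_heavy_central >= 2 and n_fine >= 1:
        klass = 2
    elif any_central and not any_heavy:
        klass = 3
    else:
        klass = 4

    return ActinResult(
        cell_id=cell_id,
        cables=cables,
        central_coverage=coverage,
        n_heavy_central=n_heavy_central,
        actin_class=klass,
    )
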