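"""Synthetic single-cell fluorescence scenes with ground truth.

Renders one cell per image with four channels — transfection marker, actin,
mitochondria, microtubules — from parametric content specs:

* actin cables in the four stress-fiber classes (1: heavy cables covering
  the central area; 2: a few heavy cables entering the centre plus fine
  cables; 3: fine cables only; 4: nothing detectable centrally),
* mitochondria as curved tubules with log-normal lengths and a radial
  placement law (Beta-distributed centroid radius whose mode is the
  placement parameter rho: 0 = perinuclear, 1 = peripheral),
* microtubule arrays that are radial (from a centrosome), parallel
  (bundles along one axis) or mixed (half the cell each).

The ideal fluorophore density is degraded in the standard order: Gaussian
PSF blur, intensity scaling plus background, Poisson photon noise, Gaussian
read noise, quantisation.  Ground truth (centreline polylines, true lengths
in µm, class labels, counts, pre-degradation masks) is captured before any
degradation, so recovery tests compare against exact commanded values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import dilation, disk

__all__ = [
    "CellGeometry",
    "ActinSpec",
    "MitoSpec",
    "MTSpec",
    "ImagingSpec",
    "SceneGroundTruth",
    "render_scene",
    "generate_population",
    "default_geometry",
    "mito_spec_for_label",
    "PlacementError",
]

CHANNEL_MARKER, CHANNEL_ACTIN, CHANNEL_MITO, CHANNEL_MT = 0, 1, 2, 3

# Radial placement: centroid radius fraction ~ Beta(1 + K*rho, 1 + K*(1-rho)),
# whose mode is exactly rho.
_BETA_CONCENTRATION = 6.0


class PlacementError(RuntimeError):
    """An object could not be placed inside the cell after bounded retries."""


# --- geometry --------------------------------------------------------------

@dataclass
class CellGeometry:
    shape: tuple[int, int] = (256, 256)
    cell_center: tuple[float, float] = (128.0, 128.0)  # (row, col)
    cell_axes: tuple[float, float] = (110.0, 86.0)  # semi-axes, px
    cell_angle: float = 0.0  # radians, CCW from the column axis
    nucleus_center: tuple[float, float] = (120.0, 120.0)
    nucleus_axes: tuple[float, float] = (36.0, 28.0)
    centrosome: tuple[float, float] = (120.0, 152.0)
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if not self._inside_cell(np.array([self.centrosome]))[0]:
            raise ValueError("centrosome must lie inside the cell")
        if not np.all(self._inside_cell(self._nucleus_boundary())):
            raise ValueError("nucleus must lie inside the cell")

    def _ellipse_frac(self, pts: np.ndarray, center, axes, angle) -> np.ndarray:
        d = pts - np.asarray(center)
        c, s = np.cos(angle), np.sin(angle)
        u = d[:, 1] * c + d[:, 0] * s
        v = -d[:, 1] * s + d[:, 0] * c
        return (u / axes[1]) ** 2 + (v / axes[0]) ** 2

    def _inside_cell(self, pts: np.ndarray) -> np.ndarray:
        return self._ellipse_frac(pts, self.cell_center, self.cell_axes, self.cell_angle) <= 1.0

    def _nucleus_boundary(self, n: int = 64) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r0, c0 = self.nucleus_center
        return np.column_stack(
            [r0 + self.nucleus_axes[0] * np.sin(t), c0 + self.nucleus_axes[1] * np.cos(t)]
        )

    def _mask_from_ellipse(self, center, axes, angle) -> np.ndarray:
        rr, cc = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        return (self._ellipse_frac(pts, center, axes, angle) <= 1.0).reshape(self.shape)

    def cell_mask(self) -> np.ndarray:
        return self._mask_from_ellipse(self.cell_center, self.cell_axes, self.cell_angle)

    def nucleus_mask(self) -> np.ndarray:
        return self._mask_from_ellipse(self.nucleus_center, self.nucleus_axes, 0.0)

    def boundary_radius(self, angle: float) -> float:
        """Distance from the cell centroid to the boundary along ``angle``
        (row/col plane, angle measured from the column axis)."""
        d = np.array([np.sin(angle), np.cos(angle)])  # (row, col)
        c, s = np.cos(self.cell_angle), np.sin(self.cell_angle)
        u = d[1] * c + d[0] * s
        v = -d[1] * s + d[0] * c
        return 1.0 / np.sqrt((u / self.cell_axes[1]) ** 2 + (v / self.cell_axes[0]) ** 2)


def default_geometry(seed: int | None = None) -> CellGeometry:
    """The standard 25.6 µm HeLa-like cell; jittered slightly under a seed."""
    if seed is None:
        return CellGeometry()
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-6, 6, size=2)
    axes = (rng.uniform(96, 112), rng.uniform(82, 94))
    return CellGeometry(
        cell_center=(128.0 + jitter[0], 128.0 + jitter[1]),
        cell_axes=axes,
        cell_angle=rng.uniform(0, np.pi),
        nucleus_center=(128.0 + jitter[0] - 8, 128.0 + jitter[1] - 8),
        centrosome=(128.0 + jitter[0] - 8, 128.0 + jitter[1] + 18),
    )


# --- content specs ---------------------------------------------------------

@dataclass
class ActinSpec:
    """Stress-fiber content.  Heavy cables are edge-to-edge chords; fine
    cables are shorter and thinner.  Defaults per class are encoded in
    :meth:`for_class`."""

    target_class: int
    n_heavy: int = 0
    n_fine: int = 0
    heavy_width: int = 5
    fine_width: int = 2
    heavy_intensity: float = 1.0
    fine_intensity: float = 0.45

    def __post_init__(self) -> None:
        if self.target_class not in (1, 2, 3, 4):
            raise ValueError("actin class must be 1-4")

    @classmethod
    def for_class(cls, target_class: int) -> "ActinSpec":
        presets = {
            1: dict(n_heavy=12, n_fine=4),
            2: dict(n_heavy=2, n_fine=10),
            3: dict(n_heavy=0, n_fine=12),
            4: dict(n_heavy=0, n_fine=3),
        }
        return cls(target_class=target_class, **presets[target_class])


@dataclass
class MitoSpec:
    """Mitochondria population: log-normal lengths, Beta radial placement."""

    n_objects: int = 30
    median_length_um: float = 2.0
    log_sd: float = 0.3
    width_px: int = 3
    curvature: float = 0.15  # stdev of per-step heading change, radians
    rho: float = 0.25  # radial placement parameter, 0 perinuclear .. 1 peripheral
    morphology: str = "tubular"  # tubular | mixed | fragmented
    intensity: float = 1.0
    min_separation_px: int = 2

    def __post_init__(self) -> None:
        if self.median_length_um <= 0:
            raise ValueError("median length must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.morphology not in ("tubular", "mixed", "fragmented"):
            raise ValueError(f"unknown morphology {self.morphology!r}")


def mito_spec_for_label(label: str, rho: float | None = None) -> MitoSpec:
    """Morphology label -> generator parameters.

    Tubular cells carry fewer, longer mitochondria; fragmented cells carry
    many short ones (the fragmentation phenotype observed on pathogenic
    variants); mixed is an even mixture rendered as an intermediate
    median.  Pathogenic-like cells also mislocalise outward (higher rho).
    """
    table = {
        "tubular": MitoSpec(n_objects=22, median_length_um=2.2, rho=0.25, morphology="tubular"),
        "mixed": MitoSpec(n_objects=30, median_length_um=1.5, log_sd=0.55, rho=0.45,
                          morphology="mixed"),
        "fragmented": MitoSpec(n_objects=40, median_length_um=0.7, rho=0.6,
                               morphology="fragmented"),
    }
    spec = table[label]
    if rho is not None:
        spec = replace(spec, rho=rho)
    return spec


@dataclass
class MTSpec:
    """Microtubule array: radial, parallel, or regionally mixed."""

    field_type: str = "radial"  # radial | mixed | parallel
    parallel_axis_angle: float = 0.3  # radians
    # target share of orientation energy carried by bundles in a mixed
    # cell; bundle chords are about twice as long as centrosome rays, so
    # the bundle count is half of what a naive count fraction would give
    mixed_fraction: float = 0.4
    filament_count: int = 60
    bundle_width: int = 2
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.field_type not in ("radial", "mixed", "parallel"):
            raise ValueError(f"unknown MT field type {self.field_type!r}")
        if self.field_type == "mixed" and not 0.0 < self.mixed_fraction < 1.0:
            raise ValueError("mixed fraction must be in (0, 1) for mixed fields")

    @property
    def target_class(self) -> int:
        return {"radial": 1, "mixed": 2, "parallel": 3}[self.field_type]


@dataclass
class ImagingSpec:
    """Optical degradation: PSF blur, background, shot noise, read noise."""

    psf_sigma: float = 1.2  # px
    background: float = 8.0
    photon_scale: float = 150.0
    read_noise_sd: float = 3.0
    bit_depth: int = 16
    poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma < 0:
            raise ValueError("psf sigma must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit depth must be 8 or 16")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "ImagingSpec":
        return cls(psf_sigma=0.0, background=0.0, photon_scale=255.0,
                   read_noise_sd=0.0, bit_depth=16, poisson=False, seed=seed)


@dataclass
class SceneGroundTruth:
    actin_class: int
    mito_morphology: str
    mt_class: int
    mito_polylines: list[np.ndarray] = field(default_factory=list)
    mito_lengths_um: list[float] = field(default_factory=list)
    cable_polylines: list[np.ndarray] = field(default_factory=list)
    cable_tiers: list[str] = field(default_factory=list)
    counts: dict[int, int] = field(default_factory=dict)
    masks: dict[int, np.ndarray] = field(default_factory=dict)
    geometry: CellGeometry | None = None

    def __post_init__(self) -> None:
        if self.counts.get(CHANNEL_MITO, len(self.mito_polylines)) != len(self.mito_polylines):
            raise ValueError("mito count inconsistent with object list")


# --- drawing helpers -------------------------------------------------------

def _polyline_arclength(poly: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))


def _polyline_aa(shape: tuple[int, int], poly: np.ndarray, width: float) -> np.ndarray:
    """Anti-aliased raster of a tubule of full width ``width`` around a
    polyline: coverage ramps linearly over one pixel at the edge, so the
    rendered shape is rotation-isotropic (a dilation of a digital line is
    not) and FWHM equals the commanded width exactly."""
    r = width / 2.0
    p = np.asarray(poly, dtype=float)
    pad = int(np.ceil(width)) + 3
    r0 = max(int(np.floor(p[:, 0].min())) - pad, 0)
    r1 = min(int(np.ceil(p[:, 0].max())) + pad + 1, shape[0])
    c0 = max(int(np.floor(p[:, 1].min())) - pad, 0)
    c1 = min(int(np.ceil(p[:, 1].max())) + pad + 1, shape[1])
    out = np.zeros(shape)
    if r1 <= r0 or c1 <= c0:
        return out
    rr, cc = np.mgrid[r0:r1, c0:c1]
    pts = np.stack([rr, cc], axis=-1).astype(float)  # (h, w, 2)
    a, b = p[:-1], p[1:]
    ab = b - a  # (K, 2)
    denom = np.sum(ab**2, axis=1) + 1e-12
    ap = pts[:, :, None, :] - a[None, None, :, :]  # (h, w, K, 2)
    t = np.clip(np.einsum("hwkd,kd->hwk", ap, ab) / denom, 0.0, 1.0)
    proj = a[None, None] + t[..., None] * ab[None, None]
    d = np.sqrt(np.min(np.sum((pts[:, :, None, :] - proj) ** 2, axis=-1), axis=-1))
    out[r0:r1, c0:c1] = np.clip(r + 0.5 - d, 0.0, 1.0)
    return out


def _polyline_mask(shape: tuple[int, int], poly: np.ndarray, width: float) -> np.ndarray:
    """Binary raster (half-maximum support) of a thick polyline."""
    return _polyline_aa(shape, poly, width) >= 0.5


def _stamp_polyline(canvas: np.ndarray, poly: np.ndarray, width: float, value: float) -> np.ndarray:
    """Add an anti-aliased thick polyline; returns the half-max mask."""
    aa = _polyline_aa(canvas.shape, poly, width)
    np.maximum(canvas, value * aa, out=canvas)
    return aa >= 0.5


def _chord_through(geometry: CellGeometry, point: np.ndarray, angle: float) -> np.ndarray:
    """Edge-to-edge chord of the cell through ``point`` at ``angle``."""
    d = np.array([np.sin(angle), np.cos(angle)])
    # march out in both directions until leaving the cell
    ts = np.linspace(-2 * max(geometry.cell_axes), 2 * max(geometry.cell_axes), 800)
    pts = point[None] + ts[:, None] * d[None]
    inside = geometry._inside_cell(pts)
    if not inside.any():
        raise PlacementError("chord misses the cell")
    lo, hi = np.nonzero(inside)[0][[0, -1]]
    return np.vstack([pts[lo], pts[hi]])


# --- channel generators ----------------------------------------------------

def _central_ellipse_mask(geometry: CellGeometry, area_fraction: float = 0.5) -> np.ndarray:
    s = np.sqrt(area_fraction)
    axes = (geometry.cell_axes[0] * s, geometry.cell_axes[1] * s)
    return geometry._mask_from_ellipse(geometry.cell_center, axes, geometry.cell_angle)


def _gen_actin(
    geometry: CellGeometry, spec: ActinSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray], list[str]]:
    density = np.zeros(geometry.shape)
    polylines: list[np.ndarray] = []
    tiers: list[str] = []
    center = np.asarray(geometry.cell_center)
    minor = min(geometry.cell_axes)

    # Heavy cables: chords in up to two angle families, offsets spread so a
    # class-1 complement blankets the central area.
    if spec.n_heavy:
        base_angle = rng.uniform(0, np.pi)
        half = (spec.n_heavy + 1) // 2
        for k in range(spec.n_heavy):
            family = k // half
            ang = base_angle + family * (np.pi / 2) + rng.normal(0, 0.06)
            j = k - family * half
            n_fam = half if family == 0 else spec.n_heavy - half
            # perpendicular offsets tile the central band
            span = 0.75 * minor
            off = (-span + 2 * span * (j + 0.5) / max(n_fam, 1)) + rng.normal(0, 2.0)
            perp = np.array([np.cos(ang), -np.sin(ang)])
            poly = _chord_through(geometry, center + off * perp, ang)
            _stamp_polyline(density, poly, spec.heavy_width, spec.heavy_intensity)
            polylines.append(poly)
            tiers.append("heavy")

    central = _central_ellipse_mask(geometry)
    # fine cables must stay distinct: a candidate mostly overlapping an
    # already-drawn fine cable (near-parallel neighbour) would blur into a
    # single wide structure and contradict the commanded tier
    fine_occupied = np.zeros(geometry.shape, dtype=bool)
    for _ in range(spec.n_fine):
        for _attempt in range(60):
            ang = rng.uniform(0, np.pi)
            if spec.target_class == 4:
                # peripheral short arcs that stay out of the central area
                theta = rng.uniform(0, 2 * np.pi)
                rad = geometry.boundary_radius(theta)
                p0 = center + 0.9 * rad * np.array([np.sin(theta), np.cos(theta)])
                d = np.array([np.cos(theta), -np.sin(theta)])  # tangential
                length = rng.uniform(15, 30)
                poly = np.vstack([p0 - 0.5 * length * d, p0 + 0.5 * length * d])
                trial = _polyline_mask(geometry.shape, poly, spec.fine_width)
                if not trial.any() or (trial & central).any():
                    continue
            else:
                off = rng.uniform(-0.8, 0.8) * minor
                perp = np.array([np.cos(ang), -np.sin(ang)])
                chord = _chord_through(geometry, center + off * perp, ang)
                # fine cables span a random sub-segment of the chord
                t0, t1 = np.sort(rng.uniform(0, 1, size=2))
                if t1 - t0 < 0.3:
                    t1 = min(1.0, t0 + 0.3)
                poly = np.vstack(
                    [chord[0] + t0 * (chord[1] - chord[0]), chord[0] + t1 * (chord[1] - chord[0])]
                )
            cand = _polyline_mask(geometry.shape, poly, spec.fine_width)
            if cand.sum() == 0 or (cand & fine_occupied).sum() > 0.25 * cand.sum():
                continue
            fine_occupied |= dilation(cand, disk(3))
            _stamp_polyline(density, poly, spec.fine_width, spec.fine_intensity)
            polylines.append(poly)
            tiers.append("fine")
            break
        else:
            raise PlacementError("actin: could not place fine cable")
    return density, polylines, tiers


def _gen_mitochondria(
    geometry: CellGeometry, spec: MitoSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray], list[float]]:
    density = np.zeros(geometry.shape)
    cyto = geometry.cell_mask() & ~geometry.nucleus_mask()
    safe = ndimage.binary_erosion(cyto, iterations=spec.width_px // 2 + 1)
    occupied = np.zeros(geometry.shape, dtype=bool)
    center = np.asarray(geometry.cell_center)

    a = 1.0 + _BETA_CONCENTRATION * spec.rho
    b = 1.0 + _BETA_CONCENTRATION * (1.0 - spec.rho)

    polylines: list[np.ndarray] = []
    lengths: list[float] = []
    for i in range(spec.n_objects):
        if spec.morphology == "mixed":
            # even mixture of long tubules and short fragments
            median = 2.2 if i % 2 == 0 else 0.7
            length_um = float(np.exp(np.log(median) + 0.3 * rng.standard_normal()))
        else:
            length_um = float(
                np.exp(np.log(spec.median_length_um) + spec.log_sd * rng.standard_normal())
            )
        n_steps = max(int(round(length_um / geometry.pixel_size_um)), 3)

        placed = False
        for _attempt in range(360):
            # crowding fallbacks keep the commanded length: first allow
            # tighter (still non-touching) packing, then relax the radial law
            sep = spec.min_separation_px if _attempt < 120 else 1
            rfrac = rng.beta(a, b) if _attempt < 240 else rng.uniform(0.05, 0.95)
            theta = rng.uniform(0, 2 * np.pi)
            centroid = center + rfrac * geometry.boundary_radius(theta) * np.array(
                [np.sin(theta), np.cos(theta)]
            )
            # tangential bias: tubules wrap around the nucleus rather than
            # point into it, which is also how packing stays feasible
            heading = theta + np.pi / 2.0 + rng.normal(0, 0.5) + rng.integers(2) * np.pi
            steps = rng.normal(0, spec.curvature, size=n_steps - 1)
            headings = heading + np.concatenate([[0.0], np.cumsum(steps)])
            deltas = np.column_stack([np.sin(headings), np.cos(headings)])
            poly = np.concatenate([[np.zeros(2)], np.cumsum(deltas, axis=0)])
            poly = poly - poly.mean(axis=0) + centroid
            # self-avoidance: a tubule that loops back onto itself would
            # render as a merged blob and falsify its own truth length
            if len(poly) > 8:
                diff = poly[:, None, :] - poly[None, :, :]
                dist = np.sqrt((diff**2).sum(-1))
                ii, jj = np.triu_indices(len(poly), k=7)
                if dist[ii, jj].min() < 4.5:
                    continue
            pts = np.round(poly).astype(int)
            if (pts < 0).any() or (pts[:, 0] >= geometry.shape[0]).any() or (
                pts[:, 1] >= geometry.shape[1]
            ).any():
                continue
            if not safe[pts[:, 0], pts[:, 1]].all():
                continue
            stamp = _polyline_mask(geometry.shape, poly, spec.width_px)
            grown = dilation(stamp, disk(sep))
            if (grown & occupied).any():
                continue
            density[stamp] = np.maximum(density[stamp], spec.intensity)
            occupied |= grown
            polylines.append(poly)
            lengths.append(_polyline_arclength(poly) * geometry.pixel_size_um)
            placed = True
            break
        if not placed:
            raise PlacementError(f"mitochondria: object {i} could not be placed")
    return density, polylines, lengths


def _gen_microtubules(
    geometry: CellGeometry, spec: MTSpec, rng: np.random.Generator
) -> np.ndarray:
    density = np.zeros(geometry.shape)
    center = np.asarray(geometry.cell_center)
    centro = np.asarray(geometry.centrosome)
    minor = min(geometry.cell_axes)

    # in mixed cells the bundled region is bounded by a line running along
    # the bundle axis, so bundle chords keep their full length and the
    # bundled-area fraction stays stable across cells
    ang0 = spec.parallel_axis_angle
    split_normal = np.array([np.cos(ang0), -np.sin(ang0)])
    split_offset = 0.25 * minor

    def region_of(pts: np.ndarray) -> np.ndarray:
        return (pts - center) @ split_normal > split_offset

    n_parallel = {
        "radial": 0,
        "parallel": spec.filament_count,
        "mixed": int(round(spec.filament_count * spec.mixed_fraction / 2.0)),
    }[spec.field_type]
    n_radial = spec.filament_count - n_parallel

    mask_restrict = spec.field_type == "mixed"
    # jittered grids rather than i.i.d. draws: the per-cell energy split
    # between ray fan and bundles stays stable across cells
    ray_angles = (
        np.linspace(0, 2 * np.pi, max(n_radial, 1), endpoint=False)
        + rng.uniform(0, 2 * np.pi)
        + rng.normal(0, 0.05, max(n_radial, 1))
    )
    for k in range(n_radial):
        theta = float(ray_angles[k])
        # rays start at the centrosome and run to the cell boundary
        d = np.array([np.sin(theta), np.cos(theta)])
        ts = np.linspace(0, 2.5 * max(geometry.cell_axes), 600)
        pts = centro[None] + ts[:, None] * d[None]
        inside = geometry._inside_cell(pts)
        if mask_restrict:
            inside &= ~region_of(pts)
        if not inside.any():
            continue
        hi = np.nonzero(inside)[0][-1]
        lo = np.nonzero(inside)[0][0]
        if hi - lo < 8:
            continue
        _stamp_polyline(density, np.vstack([pts[lo], pts[hi]]), spec.bundle_width,
                        spec.intensity)
    if mask_restrict:
        offsets = np.linspace(0.38, 0.9, max(n_parallel, 1)) * minor
    else:
        offsets = np.linspace(-0.92, 0.92, max(n_parallel, 1)) * minor
    offsets = offsets + rng.normal(0, 1.5, max(n_parallel, 1))
    for k in range(n_parallel):
        ang = spec.parallel_axis_angle + rng.normal(0, 0.04)
        off = float(offsets[k])
        perp = np.array([np.cos(ang), -np.sin(ang)])
        try:
            chord = _chord_through(geometry, center + off * perp, ang)
        except PlacementError:
            continue
        if mask_restrict:
            # clip the chord to its own half of the cell
            ts = np.linspace(0, 1, 400)
            pts = chord[0][None] + ts[:, None] * (chord[1] - chord[0])[None]
            keep = region_of(pts)
            if keep.sum() < 8:
                continue
            idx = np.nonzero(keep)[0]
            chord = np.vstack([pts[idx[0]], pts[idx[-1]]])
        _stamp_polyline(density, chord, spec.bundle_width, spec.intensity)
    return density


# --- rendering -------------------------------------------------------------

def _degrade(density: np.ndarray, imaging: ImagingSpec, rng: np.random.Generator) -> np.ndarray:
    img = density
    if imaging.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, imaging.psf_sigma)
    expected = img * imaging.photon_scale + imaging.background
    if imaging.poisson:
        out = rng.poisson(np.clip(expected, 0, None)).astype(float)
    else:
        out = expected.copy()
    if imaging.read_noise_sd > 0:
        out += rng.normal(0, imaging.read_noise_sd, size=out.shape)
    maxval = 2**imaging.bit_depth - 1
    out = np.clip(np.round(out), 0, maxval)
    return out.astype(np.uint8 if imaging.bit_depth == 8 else np.uint16)


def render_scene(
    geometry: CellGeometry,
    actin: ActinSpec,
    mito: MitoSpec,
    mt: MTSpec,
    imaging: ImagingSpec,
) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render one cell.  Returns a (4, rows, cols) unsigned-int stack and
    the scene ground truth.  Identical specs and seed give identical bytes.
    """
    rng = np.random.default_rng(imaging.seed)

    marker = geometry.cell_mask().astype(float) * 0.4
    marker[geometry.nucleus_mask()] = 0.25
    actin_density, cable_polys, cable_tiers = _gen_actin(geometry, actin, rng)
    mito_density, mito_polys, mito_lengths = _gen_mitochondria(geometry, mito, rng)
    mt_density = _gen_microtubules(geometry, mt, rng)

    truth = SceneGroundTruth(
        actin_class=actin.target_class,
        mito_morphology=mito.morphology,
        mt_class=mt.target_class,
        mito_polylines=mito_polys,
        mito_lengths_um=mito_lengths,
        cable_polylines=cable_polys,
        cable_tiers=cable_tiers,
        counts={
            CHANNEL_ACTIN: len(cable_polys),
            CHANNEL_MITO: len(mito_polys),
        },
        masks={
            CHANNEL_ACTIN: actin_density > 0,
            CHANNEL_MITO: mito_density > 0,
            CHANNEL_MT: mt_density > 0,
        },
        geometry=geometry,
    )

    stack = np.stack(
        [_degrade(d, imaging, rng) for d in (marker, actin_density, mito_density, mt_density)]
    )
    return stack, truth


def generate_population(
    n_cells: int,
    actin_mixture: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    mito_mixture: tuple[float, float, float] = (1.0, 0.0, 0.0),
    mt_mixture: tuple[float, float, float] = (1.0, 0.0, 0.0),
    imaging: ImagingSpec | None = None,
    seed: int = 0,
    mito_override: MitoSpec | None = None,
) -> list[tuple[np.ndarray, SceneGroundTruth]]:
    """Sample per-cell specs from class mixtures and render the cohort.

    ``mito_mixture`` is over (tubular, mixed, fragmented); ``mt_mixture``
    over (radial, mixed, parallel).  Deterministic under ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    for mix in (actin_mixture, mito_mixture, mt_mixture):
        if abs(sum(mix) - 1.0) > 1e-9 or any(p < 0 for p in mix):
            raise ValueError("mixture proportions must be non-negative and sum to 1")
    base = ImagingSpec() if imaging is None else imaging

    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(2 * n_cells).reshape(n_cells, 2) % (2**31 - 1)
    mix_rng = np.random.default_rng(ss.spawn(1)[0])

    out = []
    mito_labels = ("tubular", "mixed", "fragmented")
    mt_types = ("radial", "mixed", "parallel")
    for i in range(n_cells):
        actin_class = int(mix_rng.choice(4, p=actin_mixture)) + 1
        mito_label = mito_labels[int(mix_rng.choice(3, p=mito_mixture))]
        mt_type = mt_types[int(mix_rng.choice(3, p=mt_mixture))]
        geometry = default_geometry(seed=int(cell_seeds[i, 0]))
        imaging_i = replace(base, seed=int(cell_seeds[i, 1]))
        mito_spec = mito_override if mito_override is not None else mito_spec_for_label(mito_label)
        stack, truth = render_scene(
            geometry,
            ActinSpec.for_class(actin_class),
            mito_spec,
            MTSpec(field_type=mt_type),
            imaging_i,
        )
        out.append((stack, truth))
    return out
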