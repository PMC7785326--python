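"""Synthetic hyper-labeled microscopy simulator.

Generates single-cell fields with the structure of a widefield
hyper-labeled dataset: a center cell (the one the ground-truth mask
covers), optional touching or nearby neighbor cells, three fluorescence
channels (cytoplasmic fill, membrane rim, interior mitochondrial speckle),
and brightfield planes at signed focal offsets whose diffraction rims
brighten (positive defocus) or darken (negative defocus) the cell
boundary.  A configurable fraction of images are cell-free negatives.

Cell shape model: an ellipse perturbed by smooth low-frequency radial
noise (a few Fourier harmonics), which captures blob-like epithelial /
beta-cell morphology with a single roughness knob.  Defocus model: a
signed Gaussian band along the contour whose amplitude grows linearly
with |offset| and whose width grows slowly with |offset| — a cheap stand-in
for diffraction that reproduces the peak/valley boundary profiles of real
out-of-focus brightfield, not a physical PSF simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .stack_io import (
    CANONICAL_CHANNELS,
    FLUORESCENCE_CHANNELS,
    FOCAL_OFFSETS_UM,
    DatasetManifest,
    HyperStack,
    MaskLabel,
    write_hyperstack,
    write_manifest,
    write_mask,
)

DEFAULT_FOCAL_OFFSETS = (-10.0, -5.0, -3.0, 0.0, 3.0, 5.0, 10.0)


class InvalidConfigError(ValueError):
    """Simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulator.

    Defaults mirror the structure of the study dataset the simulator
    emulates: 400x400 px single-cell crops, seven focal offsets, about
    26% isolated cells, fully labeled cells (all marker probabilities 1),
    and a 175/450 share of cell-free negatives.  Intensity statistics
    (noise level, rim gain, cell radii) are free parameters chosen to give
    plausible-looking images; the source data do not pin them down.
    """

    image_size: int = 400
    cell_radius_range: tuple[float, float] = (80.0, 140.0)
    boundary_roughness: float = 0.12
    isolated_fraction: float = 0.26
    marker_presence_probs: dict = field(
        default_factory=lambda: {"cyto": 1.0, "mem": 1.0, "mito": 1.0}
    )
    focal_offsets: tuple[float, ...] = DEFAULT_FOCAL_OFFSETS
    rim_gain: float = 0.03          # rim amplitude per µm of defocus
    noise_sd: float = 0.02          # additive Gaussian camera noise
    negative_fraction: float = 175.0 / 450.0
    membrane_width: float = 2.0     # px, Gaussian sd of the membrane band
    mito_margin: int = 20           # px erosion of speckle support
    bf_texture: float = 0.09        # interior brightfield texture amplitude
    bf_interior_shift: float = 0.025  # mean interior brightfield offset
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in [("isolated_fraction", self.isolated_fraction),
                        ("negative_fraction", self.negative_fraction)]:
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {p}")
        for m, p in self.marker_presence_probs.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"marker prob for {m!r} out of [0, 1]: {p}")
        if 0.0 not in self.focal_offsets:
            raise InvalidConfigError("focal_offsets must include the in-focus plane 0")
        if self.rim_gain < 0:
            raise InvalidConfigError("rim_gain must be >= 0")
        lo, hi = self.cell_radius_range
        if not 0 < lo <= hi:
            raise InvalidConfigError(f"bad cell_radius_range {self.cell_radius_range}")
        # the center cell (radius * (1 + roughness headroom)) must fit
        if hi * (1.0 + self.boundary_roughness + 0.1) * 2 >= self.image_size:
            raise InvalidConfigError(
                f"max cell diameter {2 * hi:.0f}px (+margin) exceeds frame "
                f"{self.image_size}px"
            )
        if self.mito_margin < 3:
            raise InvalidConfigError("mito_margin must be >= 3 px")


def scaled_config(image_size: int = 96, **overrides) -> SimulationConfig:
    """A config with cell radii scaled proportionally to a smaller frame.

    Convenience for desk-scale runs; same structure, smaller canvas.
    """
    scale = image_size / 400.0
    base = SimulationConfig(
        image_size=image_size,
        cell_radius_range=(80.0 * scale, 140.0 * scale),
        mito_margin=max(3, round(20 * scale)),
    )
    return replace(base, **overrides)


@dataclass
class CellGeometry:
    """Closed planar contours of the center cell and its neighbors.

    Contours are (K, 2) float arrays of (row, col) vertices; radial
    functions around a center point, hence simple (non-self-intersecting)
    by construction.
    """

    center_outline: np.ndarray
    neighbor_outlines: list
    is_isolated: bool
    image_size: tuple[int, int]


def _radial_outline(center: np.ndarray, radii: tuple[float, float],
                    roughness: float, rng: np.random.Generator,
                    n_vertices: int = 180,
                    major_radius: float | None = None) -> np.ndarray:
    """Ellipse + smooth low-frequency radial perturbation (harmonics 2-6)."""
    a = rng.uniform(*radii) if major_radius is None else major_radius
    b = a * rng.uniform(0.7, 1.0)
    phi = rng.uniform(0, 2 * math.pi)
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    # ellipse radius as a function of polar angle
    ct, st = np.cos(theta - phi), np.sin(theta - phi)
    r = (a * b) / np.sqrt((b * ct) ** 2 + (a * st) ** 2)
    if roughness > 0:
        pert = np.zeros_like(theta)
        for k in range(2, 7):
            amp = rng.normal(0.0, 1.0) / k
            ph = rng.uniform(0, 2 * math.pi)
            pert += amp * np.cos(k * theta + ph)
        pert /= max(1.0, np.abs(pert).max())      # bounded perturbation
        r = r * (1.0 + roughness * pert)
    r = np.maximum(r, 2.0)
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    return np.stack([rows, cols], axis=1)


def _outline_max_radius(outline: np.ndarray, center: np.ndarray) -> float:
    return float(np.hypot(*(outline - center).T).max())


def _min_contour_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum vertex-to-vertex distance between two dense contours."""
    d = np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])
    return float(d.min())


def generate_cell_geometry(config: SimulationConfig,
                           rng: np.random.Generator) -> CellGeometry:
    """Draw a center cell and neighbors.

    With probability ``1 - isolated_fraction`` at least one neighbor is
    adjacent (within 2 px of the center outline); isolated cells may still
    have distant neighbors in the field of view, but none adjacent.
    """
    H = W = config.image_size
    lo, hi = config.cell_radius_range
    # margin follows the sampled radius, not the global maximum, so small
    # cells roam more: a constant-position prior then carries less
    # information than the image content does
    a = float(rng.uniform(lo, hi))
    margin = a * (1.0 + config.boundary_roughness) + 2
    center = np.array([
        rng.uniform(margin, H - margin) if H > 2 * margin else H / 2.0,
        rng.uniform(margin, W - margin) if W > 2 * margin else W / 2.0,
    ])
    outline = _radial_outline(center, (lo, hi), config.boundary_roughness, rng,
                              major_radius=a)
    if outline[:, 0].min() < 0 or outline[:, 0].max() >= H \
            or outline[:, 1].min() < 0 or outline[:, 1].max() >= W:
        raise InvalidConfigError("center cell does not fit inside the frame")

    is_isolated = bool(rng.random() < config.isolated_fraction)
    r_c = _outline_max_radius(outline, center)
    neighbors: list[np.ndarray] = []
    n_extra = int(rng.integers(1, 4))  # 1-3 neighbors in the field of view
    for j in range(n_extra):
        ang = rng.uniform(0, 2 * math.pi)
        nb_center = None
        for attempt in range(30):
            if is_isolated:
                gap = rng.uniform(0.15 * hi + 6.0, 0.8 * hi + 6.0)
            else:
                gap = rng.uniform(-0.05 * hi, 0.0) if j == 0 else rng.uniform(0, 0.5 * hi)
            trial_r = rng.uniform(lo, hi)
            dist = r_c + trial_r + gap
            cand = center + dist * np.array([math.sin(ang), math.cos(ang)])
            nb = _radial_outline(cand, (trial_r * 0.95, trial_r * 1.05),
                                 config.boundary_roughness, rng)
            d = _min_contour_distance(outline, nb)
            if is_isolated and d <= 6.0:
                ang = rng.uniform(0, 2 * math.pi)
                continue
            if (not is_isolated) and j == 0 and d > 2.0:
                # first neighbor must be adjacent: pull it inward
                ang = ang if attempt < 15 else rng.uniform(0, 2 * math.pi)
                continue
            nb_center = nb
            break
        if nb_center is not None:
            neighbors.append(nb_center)
    if not is_isolated:
        # guarantee adjacency even if the stochastic search failed: slide
        # the first neighbor along its axis until it touches
        if not neighbors or _min_contour_distance(outline, neighbors[0]) > 2.0:
            ang = rng.uniform(0, 2 * math.pi)
            direction = np.array([math.sin(ang), math.cos(ang)])
            trial_r = rng.uniform(lo, hi)
            nb = _radial_outline(center + (r_c + trial_r + 20) * direction,
                                 (trial_r * 0.95, trial_r * 1.05),
                                 config.boundary_roughness, rng)
            while _min_contour_distance(outline, nb) > 2.0:
                nb = nb - 1.0 * direction
            if neighbors:
                neighbors[0] = nb
            else:
                neighbors.append(nb)
    return CellGeometry(center_outline=outline, neighbor_outlines=neighbors,
                        is_isolated=is_isolated, image_size=(H, W))


def rasterize_outline(outline: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Polygon fill of a closed contour -> uint8 mask (the mask oracle)."""
    rr, cc = draw_polygon(outline[:, 0], outline[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[rr, cc] = 1
    return mask


def geometry_mask(geometry: CellGeometry) -> MaskLabel:
    """Ground truth: the filled CENTER contour only (neighbors excluded)."""
    return MaskLabel(rasterize_outline(geometry.center_outline, geometry.image_size))


def _all_interiors(geometry: CellGeometry) -> tuple[np.ndarray, list[np.ndarray]]:
    shape = geometry.image_size
    masks = [rasterize_outline(geometry.center_outline, shape)]
    masks += [rasterize_outline(nb, shape) for nb in geometry.neighbor_outlines]
    union = np.clip(np.sum(masks, axis=0), 0, 1).astype(np.uint8)
    return union, masks


def _boundary_distance(geometry: CellGeometry) -> np.ndarray:
    """Distance (px) of every pixel to the nearest cell contour."""
    shape = geometry.image_size
    edge = np.zeros(shape, dtype=bool)
    for outline in [geometry.center_outline] + list(geometry.neighbor_outlines):
        rr = np.clip(np.round(outline[:, 0]).astype(int), 0, shape[0] - 1)
        cc = np.clip(np.round(outline[:, 1]).astype(int), 0, shape[1] - 1)
        edge[rr, cc] = True
    return ndimage.distance_transform_edt(~edge)


def _smooth_field(shape, rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Low-frequency noise field in [-1, 1]-ish range (unit max abs)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    m = np.abs(f).max()
    return f / m if m > 0 else f


def _camera_noise(shape, rng: np.random.Generator, sd: float) -> np.ndarray:
    """Bounded sensor noise: Gaussian truncated at +/-3 sd.

    Truncation keeps background strictly below 3*sd, so support
    guarantees (e.g. mitochondrial speckle confined to eroded interiors)
    are exact instead of merely statistical.
    """
    return np.clip(rng.normal(0.0, sd, size=shape), -3.0 * sd, 3.0 * sd)


def render_fluorescence(geometry: CellGeometry, marker: str,
                        rng: np.random.Generator,
                        config: SimulationConfig | None = None) -> np.ndarray:
    """Render one fluorescence channel for a geometry.

    cyto: smooth fill reaching the contour of every cell interior;
    mem:  bright Gaussian band centered on the contours;
    mito: speckle strictly inside the interiors eroded by ``mito_margin``.
    """
    config = config or scaled_config(geometry.image_size[0])
    if marker not in FLUORESCENCE_CHANNELS:
        raise ValueError(
            f"unknown marker {marker!r}; expected one of {FLUORESCENCE_CHANNELS}"
        )
    shape = geometry.image_size
    union, _ = _all_interiors(geometry)
    if marker == "cyto":
        fill = 0.55 + 0.25 * _smooth_field(shape, rng, sigma=max(2.0, shape[0] / 16))
        img = np.clip(fill, 0.2, 0.95) * union
    elif marker == "mem":
        d = _boundary_distance(geometry)
        img = 0.9 * np.exp(-0.5 * (d / config.membrane_width) ** 2)
    else:  # mito
        eroded = ndimage.binary_erosion(union, iterations=config.mito_margin)
        img = np.zeros(shape, dtype=np.float64)
        area = int(eroded.sum())
        if area > 0:
            density = 0.004  # speckles per interior pixel
            n_spots = max(3, int(rng.poisson(density * area)))
            idx = np.flatnonzero(eroded)
            pick = rng.choice(idx, size=min(n_spots, idx.size), replace=False)
            img.flat[pick] = rng.uniform(0.6, 1.0, size=pick.size)
            img = ndimage.gaussian_filter(img, 1.2)
            m = img.max()
            if m > 0:
                img *= 0.9 / m
            img *= eroded  # strict support inside the eroded interior
    if config.noise_sd > 0:
        img = img + _camera_noise(shape, rng, config.noise_sd)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def render_brightfield(geometry: CellGeometry, focal_offset_um: float,
                       rng: np.random.Generator,
                       config: SimulationConfig | None = None) -> np.ndarray:
    """Render a brightfield plane at a signed defocus offset.

    Mid-gray base with faint texture; a contour-following band is added
    with signed amplitude ``sign(offset) * rim_gain * |offset|`` so
    positive offsets give bright rims (peaks) and negative offsets dark
    rims (valleys).  At offset 0 only the faint texture remains.
    """
    config = config or scaled_config(geometry.image_size[0])
    if focal_offset_um not in config.focal_offsets:
        raise ValueError(
            f"focal offset {focal_offset_um} not in configured set "
            f"{config.focal_offsets}"
        )
    shape = geometry.image_size
    union, _ = _all_interiors(geometry)
    base = 0.5 + 0.05 * _smooth_field(shape, rng, sigma=3.0)
    # interior contrast: organelle-scale texture plus a slight mean offset,
    # the label-free signal an in-focus transmitted-light image carries
    base += (config.bf_interior_shift
             + config.bf_texture * _smooth_field(shape, rng, sigma=1.5)) * union
    if focal_offset_um != 0.0:
        d = _boundary_distance(geometry)
        width = 1.5 + 0.15 * abs(focal_offset_um)  # defocus blurs the rim
        band = np.exp(-0.5 * (d / width) ** 2)
        amplitude = math.copysign(config.rim_gain * abs(focal_offset_um),
                                  focal_offset_um)
        base = base + amplitude * band
    if config.noise_sd > 0:
        base = base + _camera_noise(shape, rng, config.noise_sd)
    return np.clip(base, 0.0, 1.0).astype(np.float32)


def _bf_name(offset: float) -> str:
    for name, off in FOCAL_OFFSETS_UM.items():
        if off == offset:
            return name
    raise ValueError(f"no canonical channel for offset {offset}")


def render_hyperstack(config: SimulationConfig, rng: np.random.Generator,
                      source_id: str = "synthetic"):
    """Render one full image: (HyperStack, MaskLabel, metadata dict).

    A negative (cell-free) draw renders empty-field channels and an
    all-background mask.  Each fluorescence marker is independently
    present with its configured probability; absent markers are blank
    (all-zero) channels.
    """
    shape = (config.image_size, config.image_size)
    is_negative = bool(rng.random() < config.negative_fraction)
    markers_present = {
        m: bool(rng.random() < config.marker_presence_probs.get(m, 1.0))
        for m in FLUORESCENCE_CHANNELS
    }
    channels: dict[str, np.ndarray] = {}
    if is_negative:
        mask = MaskLabel(np.zeros(shape, dtype=np.uint8))
        for m in FLUORESCENCE_CHANNELS:
            img = np.zeros(shape)
            if markers_present[m] and config.noise_sd > 0:
                img = img + _camera_noise(shape, rng, config.noise_sd)
            channels[m] = np.clip(img, 0, 1).astype(np.float32)
        empty = CellGeometry(
            center_outline=np.zeros((0, 2)), neighbor_outlines=[],
            is_isolated=True, image_size=shape)
        for off in config.focal_offsets:
            base = 0.5 + 0.05 * _smooth_field(shape, rng, sigma=3.0)
            if config.noise_sd > 0:
                base = base + _camera_noise(shape, rng, config.noise_sd)
            channels[_bf_name(off)] = np.clip(base, 0, 1).astype(np.float32)
        geometry = empty
    else:
        geometry = generate_cell_geometry(config, rng)
        mask = geometry_mask(geometry)
        for m in FLUORESCENCE_CHANNELS:
            if markers_present[m]:
                channels[m] = render_fluorescence(geometry, m, rng, config)
            else:
                channels[m] = np.zeros(shape, dtype=np.float32)
        for off in config.focal_offsets:
            channels[_bf_name(off)] = render_brightfield(geometry, off, rng, config)
    ordered = {n: channels[n] for n in CANONICAL_CHANNELS if n in channels}
    stack = HyperStack(channels=ordered, pixel_size_um=9.28 / config.image_size,
                       source_id=source_id)
    meta = {"is_negative": is_negative, "markers_present": markers_present,
            "is_isolated": getattr(geometry, "is_isolated", True)}
    return stack, mask, meta


def generate_dataset(config: SimulationConfig, n_images: int, out_dir,
                     rng: np.random.Generator | None = None) -> DatasetManifest:
    """Write ``n_images`` stacks + masks + a manifest CSV under ``out_dir``.

    Fully seeded: the same ``config.seed`` (or supplied generator state)
    reproduces byte-identical files.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(n_images):
        stack, mask, meta = render_hyperstack(config, rng, source_id=f"img_{i:05d}")
        img_name = f"img_{i:05d}.tiff"
        mask_name = f"mask_{i:05d}.png"
        write_hyperstack(stack, out / img_name)
        write_mask(mask, out / mask_name)
        markers = "|".join(m for m in FLUORESCENCE_CHANNELS
                           if meta["markers_present"][m])
        rows.append({"image_path": img_name, "mask_path": mask_name,
                     "is_negative": meta["is_negative"],
                     "cell_type_tag": "synthetic",
                     "markers_present": markers})
    manifest = DatasetManifest(frame=pd.DataFrame(rows), root=out)
    write_manifest(manifest, out / "manifest.csv")
    return manifest
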