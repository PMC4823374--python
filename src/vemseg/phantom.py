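"""Synthetic EM-like phantom stacks with ground-truth labels.

The phantom emulates the appearance of FIB/SEM neuropil well enough to
exercise every pipeline stage without external data: a bright, noisy
background crossed by faint membrane sheets; mitochondria as dark
ellipsoidal blobs with darker internal stripes (cristae-like texture);
synaptic junctions as thin, curved dark sheets.  Geometry is defined
continuously in nanometre space and sampled at the voxel grid, so the
anisotropy of the stack arises exactly as in acquisition: the same
object is sampled coarsely along Z and finely in-plane.

Mitochondria and synapse sheets never overlap and keep a clearance (the
adjacency-exclusion prior of the regularizer holds in the ground truth).
All randomness flows through one seeded generator: identical specs give
bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GenerationError
from .volumes import BACKGROUND, MITOCHONDRION, SYNAPSE, ImageStack, LabelVolume

_PLACEMENT_RETRIES = 200


@dataclass(frozen=True)
class IntensityModel:
    """Per-class mean intensities (bright background, dark organelles)."""

    background: float = 0.72
    membrane: float = 0.60
    mitochondrion: float = 0.40
    cristae: float = 0.33
    synapse: float = 0.20


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of a synthetic stack.

    Sizes are in-plane pixels (converted to nm through ``voxel_size``).
    Defaults model a 1.3 x 1.3 x 0.64 um block at 10 x 10 x 20 nm voxels
    (anisotropy rho = 2): mitochondria of 240-400 nm diameter, synaptic
    sheets ~40 nm thick, additive Gaussian noise.
    """

    shape: tuple[int, int, int] = (128, 128, 32)
    voxel_size: tuple[float, float, float] = (10.0, 10.0, 20.0)
    n_mitochondria: int = 4
    n_synapses: int = 3
    mito_radius_range: tuple[float, float] = (12.0, 20.0)
    sheet_radius_range: tuple[float, float] = (18.0, 28.0)
    sheet_thickness: float = 4.0
    n_membranes: int = 3
    intensity: IntensityModel = field(default_factory=IntensityModel)
    noise_sigma: float = 0.06
    edge_width: float = 0.4
    clearance: int = 2
    seed: int = 0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _grid_nm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sx, sy, sz = spec.voxel_size
    nx, ny, nz = spec.shape
    return np.meshgrid(
        np.arange(nx) * sx, np.arange(ny) * sy, np.arange(nz) * sz, indexing="ij"
    )


def _ellipsoid_distance(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: np.ndarray,
    semi_axes: np.ndarray,
    rotation: np.ndarray,
) -> np.ndarray:
    """Approximate signed distance (nm) to an ellipsoid surface."""
    rel = np.stack([c - cc for c, cc in zip(coords, center)], axis=-1)
    local = rel @ rotation
    radial = np.sqrt(np.sum((local / semi_axes) ** 2, axis=-1))
    return (radial - 1.0) * float(semi_axes.min())


def _sheet_distance(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: np.ndarray,
    rotation: np.ndarray,
    radius: float,
    thickness: float,
    curvature_radius: float,
) -> np.ndarray:
    """Signed distance (nm) to a curved disk: a paraboloid shell of the
    given thickness, cut to a disk of the given radius."""
    rel = np.stack([c - cc for c, cc in zip(coords, center)], axis=-1)
    local = rel @ rotation
    a, b, d = local[..., 0], local[..., 1], local[..., 2]
    shell = np.abs(d - (a**2 + b**2) / (2.0 * curvature_radius)) - 0.5 * thickness
    radial = np.sqrt(a**2 + b**2) - radius
    return np.maximum(shell, radial)


def _soft_mask(distance_nm: np.ndarray, edge_nm: float) -> np.ndarray:
    """1 inside, 0 outside, smooth partial-volume transition at the edge."""
    return 1.0 / (1.0 + np.exp(np.clip(distance_nm / max(edge_nm, 1e-9), -40, 40)))


def _center_lo(spec: PhantomSpec) -> np.ndarray:
    """Lower bound (nm) for object centers: protrusions past the face
    clearance are handled by rejection, not by this bound."""
    return (spec.clearance + 2) * np.asarray(spec.voxel_size, dtype=np.float64)


def generate(spec: PhantomSpec) -> tuple[ImageStack, LabelVolume]:
    """Render a phantom stack and its ground-truth label volume.

    Raises :class:`GenerationError` when objects cannot be placed without
    violating the non-overlap/clearance rule after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    sx, sy, sz = spec.voxel_size
    nx, ny, nz = spec.shape
    extent = np.array([nx * sx, ny * sy, nz * sz])
    coords = _grid_nm(spec)
    image = np.full(spec.shape, spec.intensity.background, dtype=np.float64)
    labels = np.full(spec.shape, BACKGROUND, dtype=np.int64)
    edge_nm = spec.edge_width * sx

    # Faint membrane sheets: background texture, no label of their own.
    for _ in range(spec.n_membranes):
        center = rng.uniform(0.1, 0.9, size=3) * extent
        dist = _sheet_distance(
            coords, center, _random_rotation(rng),
            radius=rng.uniform(0.5, 0.9) * float(extent.max()),
            thickness=1.2 * sx,
            curvature_radius=rng.uniform(8, 20) * float(extent.max()),
        )
        w = _soft_mask(dist, edge_nm)
        image = image * (1 - w) + spec.intensity.membrane * w

    occupied = np.zeros(spec.shape, dtype=bool)
    clearance_struct = ndimage.generate_binary_structure(3, 1)

    def _try_place(dist_nm: np.ndarray) -> np.ndarray | None:
        inside = dist_nm < 0
        if not inside.any():
            return None
        grown = ndimage.binary_dilation(
            inside, structure=clearance_struct, iterations=max(spec.clearance, 1)
        )
        if (grown & occupied).any():
            return None
        # 2-voxel clearance from the volume faces
        if (
            inside[: spec.clearance].any() or inside[-spec.clearance:].any()
            or inside[:, : spec.clearance].any() or inside[:, -spec.clearance:].any()
            or inside[:, :, : spec.clearance].any() or inside[:, :, -spec.clearance:].any()
        ):
            return None
        return inside

    # Mitochondria: dark ellipsoids with cristae-like internal stripes.
    for i in range(spec.n_mitochondria):
        for attempt in range(_PLACEMENT_RETRIES):
            r_nm = rng.uniform(*spec.mito_radius_range) * sx
            semi = r_nm * rng.uniform(0.65, 1.0, size=3)
            semi[0] = r_nm  # longest axis first
            rot = _random_rotation(rng)
            center = rng.uniform(_center_lo(spec), extent - _center_lo(spec))
            dist = _ellipsoid_distance(coords, center, semi, rot)
            inside = _try_place(dist)
            if inside is not None:
                break
        else:
            raise GenerationError(f"could not place mitochondrion {i} without overlap")
        occupied |= inside
        labels[inside] = MITOCHONDRION
        w = _soft_mask(dist, edge_nm)
        stripes_dir = _random_rotation(rng)[:, 0]
        phase = rng.uniform(0, 2 * np.pi)
        wavelength = rng.uniform(5.0, 8.0) * sx
        carrier = np.sin(
            2 * np.pi * sum(c * d for c, d in zip(coords, stripes_dir)) / wavelength + phase
        )
        body = np.where(carrier > 0.2, spec.intensity.cristae, spec.intensity.mitochondrion)
        image = image * (1 - w) + body * w

    # Synaptic junctions: thin curved dark sheets.
    for i in range(spec.n_synapses):
        for attempt in range(_PLACEMENT_RETRIES):
            radius = rng.uniform(*spec.sheet_radius_range) * sx
            thickness = spec.sheet_thickness * sx
            rot = _random_rotation(rng)
            center = rng.uniform(_center_lo(spec), extent - _center_lo(spec))
            dist = _sheet_distance(
                coords, center, rot, radius=radius, thickness=thickness,
                curvature_radius=rng.uniform(3.0, 8.0) * radius,
            )
            inside = _try_place(dist)
            if inside is not None:
                break
        else:
            raise GenerationError(f"could not place synaptic sheet {i} without overlap")
        occupied |= inside
        labels[inside] = SYNAPSE
        w = _soft_mask(dist, edge_nm)
        image = image * (1 - w) + spec.intensity.synapse * w

    image = np.clip(image + rng.normal(0.0, spec.noise_sigma, size=spec.shape), 0.0, 1.0)
    stack = ImageStack(data=image, voxel_size=spec.voxel_size)
    table = {0: "unlabeled", BACKGROUND: "background", SYNAPSE: "synapse",
             MITOCHONDRION: "mitochondrion"}
    return stack, LabelVolume(labels=labels, label_table=table)


def make_training_scribbles(labels: LabelVolume, fraction: float, seed: int = 0) -> LabelVolume:
    """Sparse training labels: keep a random per-class fraction of voxels.

    Emulates a user painting a few voxels per structure; everything not
    kept becomes unlabeled (id 0).  Deterministic under the seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    out = np.zeros(labels.shape, dtype=labels.labels.dtype)
    for lab in labels.ids():
        mask = labels.labels == lab
        keep = rng.random(int(mask.sum())) < fraction
        sel = np.zeros(labels.shape, dtype=bool)
        sel[mask] = keep
        out[sel] = lab
    table = dict(labels.label_table)
    table.setdefault(0, "unlabeled")
    return LabelVolume(labels=out, label_table=table)
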