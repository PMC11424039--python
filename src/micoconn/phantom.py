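"""Synthetic multi-shell diffusion phantoms with known streamline weights.

The phantom generator produces crossing-fiber configurations — several
streamline bundles sharing voxels, the situation that biases tractometry
and motivates streamline-level deconvolution — together with the ground
truth needed to score recovery: a per-streamline intra-axonal signal
fraction (IASF), per-voxel isotropic fractions and optional extra-axonal
(zeppelin) fractions.

Signal synthesis here is analytic and self-contained: per voxel it sums
stick, zeppelin and ball attenuations weighted by the ground-truth
fractions. It deliberately does not go through the deconvolution module's
linear operator, so recovery tests compare two independent syntheses.

Geometric conventions (package-wide): continuous mm coordinates, voxel
(i, j, k) spans the half-open box [i*vox, (i+1)*vox) x ...; a polyline is
assigned to voxels by subdividing every segment into equal pieces no
longer than voxel_size/10 and binning each piece at its midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kernels import DEFAULT_KERNEL_PARAMS, KernelParams
from .parcellation import Parcellation
from .scheme import AcquisitionScheme

__all__ = [
    "VoxelGrid",
    "Streamline",
    "Tractogram",
    "GroundTruth",
    "make_crossing_phantom",
    "simulate_signal",
    "add_noise",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular image grid: shape in voxels, isotropic voxel size in mm."""

    shape: tuple[int, int, int]
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError("grid shape must be three positive integers")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def extent_mm(self) -> np.ndarray:
        return np.array(self.shape) * self.voxel_size

    def voxel_of(self, point: np.ndarray) -> tuple[int, int, int] | None:
        """Voxel index containing a point, or None if outside the grid."""
        idx = np.floor(np.asarray(point) / self.voxel_size).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            return None
        return tuple(idx)


@dataclass
class Streamline:
    """Ordered polyline in continuous mm coordinates."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("a streamline needs >= 2 3-D points")
        seg = np.diff(pts, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0):
            raise ValueError("consecutive streamline points must be distinct")
        self.points = pts

    @property
    def length(self) -> float:
        """Arc length in mm."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class Tractogram:
    """A set of streamlines, optionally tagged with endpoint ROI pairs."""

    streamlines: list[Streamline]
    endpoint_rois: list[tuple[int, int] | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.endpoint_rois:
            self.endpoint_rois = [None] * len(self.streamlines)
        if len(self.endpoint_rois) != len(self.streamlines):
            raise ValueError("endpoint_rois must match streamlines")

    def __len__(self) -> int:
        return len(self.streamlines)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.streamlines])


@dataclass
class GroundTruth:
    """True compartment fractions of a phantom.

    ``x_true`` is the IASF per streamline (constant along it).
    ``iso_fracs`` maps each voxel to per-ball-compartment signal fractions
    (array over the grid with one trailing axis per isotropic diffusivity).
    ``zep_fracs`` lists (fraction, orientation) zeppelin compartments per
    voxel.
    """

    x_true: np.ndarray
    iso_fracs: np.ndarray
    zep_fracs: dict[tuple[int, int, int], list[tuple[float, np.ndarray]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self.x_true = np.asarray(self.x_true, dtype=float)
        self.iso_fracs = np.asarray(self.iso_fracs, dtype=float)
        if np.any(self.x_true < 0) or np.any(self.iso_fracs < 0):
            raise ValueError("compartment fractions must be non-negative")


def _subdivide(points: np.ndarray, step: float):
    """Equal pieces (<= step long) per segment: midpoints, lengths, directions.

    The binning rule every geometric routine in the package follows.
    """
    mids, lens, dirs = [], [], []
    for p0, p1 in zip(points[:-1], points[1:]):
        seg = p1 - p0
        seg_len = float(np.linalg.norm(seg))
        n_sub = max(1, math.ceil(seg_len / step))
        u = seg / seg_len
        t = (np.arange(n_sub) + 0.5) / n_sub
        mids.append(p0 + t[:, None] * seg)
        lens.append(np.full(n_sub, seg_len / n_sub))
        dirs.append(np.tile(u, (n_sub, 1)))
    return np.vstack(mids), np.concatenate(lens), np.vstack(dirs)


_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


def _bundle_streamline(
    axis: int,
    grid: VoxelGrid,
    offset: np.ndarray,
    curvature: float,
    n_points: int = 40,
) -> np.ndarray:
    """Polyline spanning the grid along ``axis``, laterally offset, with a
    sine bend of amplitude ``curvature`` voxels."""
    ext = grid.extent_mm
    t = np.linspace(0.05, 0.95, n_points)
    pts = np.tile(ext / 2.0, (n_points, 1))
    pts[:, axis] = t * ext[axis]
    bend_axis = (axis + 1) % 3
    pts[:, bend_axis] += curvature * grid.voxel_size * np.sin(np.pi * t)
    return pts + offset


def make_crossing_phantom(
    grid: VoxelGrid,
    n_bundles: int = 2,
    streamlines_per_bundle: int = 20,
    seed: int = 0,
    x_range: tuple[float, float] = (0.2, 0.7),
    ball_frac: float = 0.2,
    n_iso: int = 2,
) -> tuple[Tractogram, GroundTruth, Parcellation]:
    """Crossing-bundle phantom with ground-truth signal fractions.

    Up to three bundles run along the grid axes and cross at the grid
    centre; bundle 0 is straight, later bundles carry a gentle sine bend.
    Each bundle's endpoints fall in two dedicated ROI slabs of the
    returned parcellation. Ground-truth streamline weights are uniform on
    ``x_range``; traversed voxels receive an isotropic (ball) fraction
    ``ball_frac`` on the first isotropic compartment.
    """
    if not 1 <= n_bundles <= 3:
        raise ValueError("n_bundles must be 1..3 (one per grid axis)")
    if streamlines_per_bundle < 1:
        raise ValueError("streamlines_per_bundle must be >= 1")
    if min(grid.shape) < 4:
        raise ValueError("grid too small: need >= 4 voxels per axis")
    lo, hi = x_range
    if not (0 <= lo <= hi):
        raise ValueError("x_range must be non-negative and ordered")

    rng = np.random.default_rng(seed)
    streamlines: list[Streamline] = []
    endpoint_rois: list[tuple[int, int]] = []
    labels = np.zeros(grid.shape, dtype=np.int32)

    # geometry is deterministic: streamlines sit on a golden-angle spiral
    # across the bundle tube and each carries its own bend amplitude, so
    # every streamline has a distinct voxel footprint (identifiability)
    tube_radius = 0.22 * min(grid.extent_mm)
    for b in range(n_bundles):
        perp_axes = [a for a in range(3) if a != b]
        for m in range(streamlines_per_bundle):
            offset = np.zeros(3)
            r = tube_radius * math.sqrt((m + 0.5) / streamlines_per_bundle)
            theta = m * _GOLDEN_ANGLE + b * 2.1
            offset[perp_axes[0]] = r * math.cos(theta)
            offset[perp_axes[1]] = r * math.sin(theta)
            curvature = 0.3 * b + (0.6 * m) / max(streamlines_per_bundle, 1)
            pts = _bundle_streamline(b, grid, offset, curvature)
            np.clip(pts, 1e-3, grid.extent_mm - 1e-3, out=pts)
            sl = Streamline(pts)
            streamlines.append(sl)
            endpoint_rois.append((2 * b + 1, 2 * b + 2))
            for point, lab in ((pts[0], 2 * b + 1), (pts[-1], 2 * b + 2)):
                vox = grid.voxel_of(point)
                if vox is None:  # pragma: no cover - clipped above
                    raise ValueError("grid too small for requested bundles")
                labels[vox] = lab

    x_true = rng.uniform(lo, hi, size=len(streamlines))

    step = grid.voxel_size / 10.0
    iso = np.zeros(grid.shape + (n_iso,))
    for sl in streamlines:
        mids, _, _ = _subdivide(sl.points, step)
        for mid in mids:
            vox = grid.voxel_of(mid)
            if vox is not None:
                iso[vox][0] = ball_frac

    tractogram = Tractogram(streamlines, endpoint_rois)
    names = {}
    homolog = {}
    for b in range(n_bundles):
        names[2 * b + 1] = f"bundle{b}_start"
        names[2 * b + 2] = f"bundle{b}_end"
        homolog[2 * b + 1] = 2 * b + 2
        homolog[2 * b + 2] = 2 * b + 1
    parc = Parcellation(
        labels, voxel_size=grid.voxel_size, roi_names=names, homolog_map=homolog
    )
    return tractogram, GroundTruth(x_true, iso), parc


def simulate_signal(
    tractogram: Tractogram,
    ground_truth: GroundTruth,
    grid: VoxelGrid,
    scheme: AcquisitionScheme,
    kernel_params: KernelParams = DEFAULT_KERNEL_PARAMS,
) -> np.ndarray:
    """Analytic multi-shell signal of a phantom, per voxel and volume.

    Each streamline spreads its weight x along its path: the piece of the
    streamline inside a voxel contributes x * (in-voxel length / total
    in-grid length) * stick attenuation, so at b=0 the voxel signal equals
    the total compartment fraction present. Zeppelin and ball compartments
    add their per-voxel fractions times the corresponding attenuation.

    Returns an array of shape ``grid.shape + (len(scheme),)``.
    """
    if len(tractogram) != ground_truth.x_true.size:
        raise ValueError("ground truth does not match the tractogram")
    bvals = scheme.bvals
    bvecs = scheme.bvecs
    sig = np.zeros(grid.shape + (len(scheme),))
    step = grid.voxel_size / 10.0
    shape = np.array(grid.shape)

    for sl, x in zip(tractogram.streamlines, ground_truth.x_true):
        mids, lens, dirs = _subdivide(sl.points, step)
        vox = np.floor(mids / grid.voxel_size).astype(int)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        if not inside.any():
            continue
        vox, lens_in, dirs_in = vox[inside], lens[inside], dirs[inside]
        total_len = lens_in.sum()
        # stick attenuation per sub-segment per volume
        dots = dirs_in @ bvecs.T
        atten = np.exp(-bvals[None, :] * kernel_params.d_par * dots**2)
        contrib = (x * lens_in / total_len)[:, None] * atten
        np.add.at(sig, (vox[:, 0], vox[:, 1], vox[:, 2]), contrib)

    # isotropic (ball) compartments
    iso = ground_truth.iso_fracs
    if iso.size:
        if iso.shape[:3] != grid.shape:
            raise ValueError("iso_fracs grid does not match the voxel grid")
        for i, d_iso in enumerate(kernel_params.d_iso_list[: iso.shape[3]]):
            ball = np.exp(-bvals * d_iso)
            sig += iso[..., i, None] * ball[None, None, None, :]

    # anisotropic extra-axonal (zeppelin) compartments
    d_delta = kernel_params.d_par_zep - kernel_params.d_perp
    for vox_idx, comps in ground_truth.zep_fracs.items():
        for frac, u in comps:
            dot = bvecs @ np.asarray(u, dtype=float)
            sig[vox_idx] += frac * np.exp(
                -bvals * (kernel_params.d_perp + d_delta * dot**2)
            )
    return sig


def add_noise(
    signal: np.ndarray, sigma: float, model: str = "rician", seed: int = 0
) -> np.ndarray:
    """Add measurement noise to a signal array.

    ``gaussian`` adds N(0, sigma); ``rician`` takes the magnitude of the
    signal perturbed by complex Gaussian noise, the floor-biased noise of
    magnitude MR images. ``sigma=0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model {model!r}")
    if sigma == 0:
        return signal
    rng = np.random.default_rng(seed)
    if model == "gaussian":
        return signal + rng.normal(0.0, sigma, size=signal.shape)
    re = signal + rng.normal(0.0, sigma, size=signal.shape)
    im = rng.normal(0.0, sigma, size=signal.shape)
    return np.hypot(re, im)
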