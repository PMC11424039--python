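"""Multi-shell diffusion acquisition schemes.

An :class:`AcquisitionScheme` is the gradient table every signal model in
this package evaluates against: one b-value (s/mm^2) and one unit gradient
direction per acquired volume, with b=0 volumes carrying zero vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionScheme", "make_scheme", "uniform_sphere_directions"]


@dataclass(frozen=True)
class AcquisitionScheme:
    """Gradient table for a multi-shell diffusion acquisition.

    Parameters
    ----------
    bvals : (n,) array
        Diffusion weighting per volume in s/mm^2. Non-negative.
    bvecs : (n, 3) array
        Unit gradient directions; b=0 volumes may carry zero vectors.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    n_b0: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvals/bvecs shapes inconsistent: {bvals.shape} vs {bvecs.shape}"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals > 0
        if np.any(np.abs(norms[weighted] - 1.0) > 1e-6):
            raise ValueError("gradient directions of b>0 volumes must be unit norm")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "n_b0", int(np.sum(~weighted)))

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def shells(self) -> list[float]:
        """Distinct nonzero b-values, ascending."""
        return sorted(set(self.bvals[self.bvals > 0].tolist()))


def uniform_sphere_directions(n: int, seed: int = 0, n_iter: int = 200) -> np.ndarray:
    """Approximately uniform unit vectors via electrostatic repulsion.

    Starts from a deterministic random draw and runs projected gradient
    descent on the antipodally-symmetric Coulomb energy, the standard way
    diffusion sampling schemes spread directions over the half-sphere.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if n == 1:
        return v
    step = 0.1
    for _ in range(n_iter):
        diff = v[:, None, :] - v[None, :, :]
        diff_anti = v[:, None, :] + v[None, :, :]
        d2 = np.sum(diff**2, axis=-1) + np.eye(n)
        d2a = np.sum(diff_anti**2, axis=-1) + 1e-12
        force = np.sum(diff / d2[..., None] ** 1.5, axis=1)
        force += np.sum(diff_anti / d2a[..., None] ** 1.5, axis=1)
        v = v + step * force / n
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def make_scheme(
    shells: list[tuple[float, int]], n_b0: int = 0, seed: int = 0
) -> AcquisitionScheme:
    """Build a multi-shell scheme from (b-value, n_directions) pairs.

    b=0 volumes are prepended with zero direction vectors. Directions on
    each shell are spread by electrostatic repulsion and are reproducible
    for a given seed.

    Examples
    --------
    >>> sch = make_scheme([(500, 30), (1200, 30), (2400, 60), (4000, 60),
    ...                    (6000, 60)], n_b0=14, seed=1)
    >>> len(sch)
    254
    """
    if not shells:
        raise ValueError("shell list must be non-empty")
    if n_b0 < 0:
        raise ValueError("n_b0 must be non-negative")
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for i, (b, n_dirs) in enumerate(shells):
        if b < 0:
            raise ValueError("b-values must be non-negative")
        if n_dirs < 1:
            raise ValueError("each shell needs at least one direction")
        dirs = uniform_sphere_directions(n_dirs, seed=seed + 1000 * i)
        bvals.extend([float(b)] * n_dirs)
        bvecs.extend(dirs)
    return AcquisitionScheme(np.array(bvals), np.vstack(bvecs))
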