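"""Stick-zeppelin-ball compartment signal models.

Three Gaussian compartments describe the diffusion-weighted signal decay
in a voxel: the *stick* (fully restricted perpendicular to the axon axis,
modelling intra-axonal water), the *zeppelin* (axially symmetric tensor,
modelling hindered extra-axonal water) and the *ball* (isotropic free
water and hindered isotropic compartments). All return the signal
attenuation S/S0 in (0, 1].

Default diffusivities are those typical of developing white matter:
d_par = d_par_zep = 1.7e-3 mm^2/s, d_perp = 0.61e-3 mm^2/s, and two
isotropic compartments at 1.7e-3 (hindered) and 3.0e-3 (CSF-like) mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelParams",
    "stick_signal",
    "zeppelin_signal",
    "ball_signal",
    "DEFAULT_KERNEL_PARAMS",
]

_UNIT_TOL = 1e-4


@dataclass(frozen=True)
class KernelParams:
    """Fixed diffusivities of the stick-zeppelin-ball model (mm^2/s)."""

    d_par: float = 1.7e-3
    d_par_zep: float = 1.7e-3
    d_perp: float = 0.61e-3
    d_iso_list: tuple[float, ...] = (1.7e-3, 3.0e-3)

    def __post_init__(self) -> None:
        if min(self.d_par, self.d_par_zep, self.d_perp, *self.d_iso_list) <= 0:
            raise ValueError("diffusivities must be positive")
        if self.d_perp > self.d_par_zep:
            raise ValueError("zeppelin requires d_perp <= d_par_zep")


DEFAULT_KERNEL_PARAMS = KernelParams()


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norms = np.linalg.norm(v, axis=-1)
    if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
        raise ValueError(f"{name} must be unit-norm (tolerance {_UNIT_TOL})")
    return v


def stick_signal(b, g, u, d_par: float = 1.7e-3):
    """Signal of the stick compartment: exp(-b * d_par * (g.u)^2).

    Diffusion only along the axis u; a gradient perpendicular to the
    stick sees no attenuation.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    g = _check_unit(g, "g") if np.any(b > 0) else np.asarray(g, dtype=float)
    u = _check_unit(u, "u")
    dot = np.sum(g * u, axis=-1)
    return np.exp(-b * d_par * dot**2)


def zeppelin_signal(b, g, u, d_par_zep: float = 1.7e-3, d_perp: float = 0.61e-3):
    """Axially symmetric tensor: exp(-b*(d_perp + (d_par_zep - d_perp)(g.u)^2)).

    Reduces to the stick at d_perp=0 and to the ball at d_perp=d_par_zep.
    """
    if d_perp > d_par_zep:
        raise ValueError("zeppelin requires d_perp <= d_par_zep")
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    g = _check_unit(g, "g") if np.any(b > 0) else np.asarray(g, dtype=float)
    u = _check_unit(u, "u")
    dot = np.sum(g * u, axis=-1)
    return np.exp(-b * (d_perp + (d_par_zep - d_perp) * dot**2))


def ball_signal(b, d_iso: float):
    """Isotropic Gaussian compartment: exp(-b * d_iso), direction-free."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    if d_iso <= 0:
        raise ValueError("d_iso must be positive")
    return np.exp(-b * d_iso)
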