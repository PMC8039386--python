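"""Speckle-reducing anisotropic diffusion (SRAD).

SRAD evolves an image under the PDE

    dI/dt = div[ c(q) grad I ],    I(x,y;0) = I0(x,y),

with zero-flux boundaries, where the diffusion coefficient c depends on
the instantaneous coefficient of variation (ICOV)

    q^2 = [ 1/2 (|grad I|/I)^2 - 1/16 (lap I / I)^2 ] / [1 + 1/4 (lap I / I)]^2 .

q is large at edges and fluctuates around the speckle scale q0 in
homogeneous regions, so c(q) ~ 1 inside uniform speckle (isotropic
smoothing) and c(q) -> 0 across edges (edge preservation).  q0 is the
coefficient of variation measured in a user-chosen homogeneous window,
recomputed every iteration, so it decays as the speckle is smoothed.

Two diffusion-coefficient forms are provided:

    reciprocal :  c = 1 / (1 + (q^2 - q0^2) / (q0^2 (1 + q0^2)))
    exponential:  c = exp(- (q^2 - q0^2) / (q0^2 (1 + q0^2)))

Discretisation is the canonical explicit 4-neighbour scheme with central
differences and reflective borders; the explicit scheme is stable for
time steps up to 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GastrolayerError

_POSITIVITY_FLOOR = 1e-8


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the SRAD filter.

    ``homog_window`` is (r0, r1, c0, c1), half-open, delimiting a
    homogeneous (pure speckle) region used to estimate q0 at every
    iteration; on phantoms the lumen/background serves, on real images
    the operator supplies it.
    """

    time_step: float = 0.05
    n_iterations: int = 100
    variant: str = "reciprocal"  # or "exponential"
    homog_window: tuple[int, int, int, int] = (0, 16, 0, 16)
    clamp_c: bool = True

    def __post_init__(self):
        if not 0.0 < self.time_step <= 0.25:
            raise GastrolayerError("time_step must be in (0, 0.25]")
        if self.n_iterations < 0:
            raise GastrolayerError("n_iterations must be >= 0")
        if self.variant not in ("reciprocal", "exponential"):
            raise GastrolayerError(f"unknown variant {self.variant!r}")


def _check_positive(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise GastrolayerError("SRAD operates on 2-D images")
    if (image <= 0).any():
        raise GastrolayerError("SRAD requires positive intensities")
    return image


def _reflect_shifts(a: np.ndarray):
    """North/south/west/east neighbours under reflective (zero-flux) borders."""
    n = np.vstack([a[:1], a[:-1]])
    s = np.vstack([a[1:], a[-1:]])
    w = np.hstack([a[:, :1], a[:, :-1]])
    e = np.hstack([a[:, 1:], a[:, -1:]])
    return n, s, w, e


def icov(image: np.ndarray) -> np.ndarray:
    """Instantaneous coefficient of variation q(x, y).

    Central-difference gradient and 4-neighbour Laplacian with
    reflective borders; the numerator of q^2 can go slightly negative in
    smooth regions and is clamped at zero before the square root.  q is
    invariant to uniform intensity scaling because I only enters through
    |grad I|/I and lap I/I.
    """
    image = _check_positive(image)
    n, s, w, e = _reflect_shifts(image)
    gx = 0.5 * (e - w)
    gy = 0.5 * (s - n)
    grad2 = (gx * gx + gy * gy) / (image * image)
    lap_over_i = (n + s + w + e - 4.0 * image) / image
    num = 0.5 * grad2 - (1.0 / 16.0) * lap_over_i**2
    den = (1.0 + 0.25 * lap_over_i) ** 2
    q2 = np.where(den > 0, np.clip(num, 0.0, None) / np.where(den > 0, den, 1.0), 0.0)
    return np.sqrt(q2)


def speckle_scale(image: np.ndarray, homog_window) -> float:
    """q0: coefficient of variation (population SD / mean) in the window."""
    image = _check_positive(image)
    r0, r1, c0, c1 = homog_window
    if r1 - r0 < 3 or c1 - c0 < 3:
        raise GastrolayerError("homogeneous window must be at least 3x3")
    if r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]:
        raise GastrolayerError("homogeneous window lies outside the image")
    patch = image[r0:r1, c0:c1]
    mean = patch.mean()
    if mean == 0:
        raise GastrolayerError("window mean is zero")
    return float(patch.std() / mean)


def diffusion_coefficient(
    q: np.ndarray, q0: float, variant: str = "reciprocal", clamp_c: bool = True
) -> np.ndarray:
    """c(q) for either diffusion-coefficient form.

    q0 = 0 is the fully smoothed degenerate case: every fluctuation
    counts as an edge and c collapses to its clamped value 1 only where
    q = 0; we simply return c = 1 everywhere (no speckle left to judge
    against), which also makes the constant image a true fixed point.
    """
    q = np.asarray(q, dtype=float)
    if q0 < 0:
        raise GastrolayerError("q0 must be nonnegative")
    if q0 == 0.0:
        return np.ones_like(q)
    arg = (q * q - q0 * q0) / (q0 * q0 * (1.0 + q0 * q0))
    if variant == "reciprocal":
        # the reciprocal form blows up as arg -> -1+; guard before clamping
        one_plus = 1.0 + arg
        safe = one_plus > 0
        c = np.where(safe, 1.0 / np.where(safe, one_plus, 1.0), np.inf)
    elif variant == "exponential":
        c = np.exp(-arg)
    else:
        raise GastrolayerError(f"unknown variant {variant!r}")
    if clamp_c:
        c = np.clip(c, 0.0, 1.0)
    return c


def srad_step(image: np.ndarray, c: np.ndarray, time_step: float) -> np.ndarray:
    """One explicit update I <- I + dt * div(c grad I).

    Fluxes are evaluated on the 4-neighbour lattice with the diffusion
    coefficient averaged onto cell faces, so the inter-pixel flux is
    antisymmetric and the global mean is conserved exactly under the
    reflective boundary (up to the positivity floor).
    """
    image = np.asarray(image, dtype=float)
    c = np.asarray(c, dtype=float)
    if image.shape != c.shape:
        raise GastrolayerError("image and coefficient field shapes differ")
    if not 0.0 < time_step <= 0.25:
        raise GastrolayerError("time_step must be in (0, 0.25]")
    i_n, i_s, i_w, i_e = _reflect_shifts(image)
    c_n, c_s, c_w, c_e = _reflect_shifts(c)
    div = (
        0.5 * (c + c_n) * (i_n - image)
        + 0.5 * (c + c_s) * (i_s - image)
        + 0.5 * (c + c_w) * (i_w - image)
        + 0.5 * (c + c_e) * (i_e - image)
    )
    out = image + time_step * div
    return np.maximum(out, _POSITIVITY_FLOOR)


def srad_filter(image: np.ndarray, params: DiffusionParams) -> np.ndarray:
    """Run the full SRAD loop: ICOV, q0, c(q), explicit update, repeated."""
    out = _check_positive(image).copy()
    for _ in range(params.n_iterations):
        q = icov(out)
        q0 = speckle_scale(out, params.homog_window)
        c = diffusion_coefficient(q, q0, params.variant, params.clamp_c)
        out = srad_step(out, c, params.time_step)
    return out
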