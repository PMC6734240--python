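"""Theoretical confocal PSFs, depth bricks, and MLE (Richardson-Lucy) deconvolution.

The point spread function is modelled as a normalized 3D Gaussian, the standard
closed-form approximation of the confocal PSF:

    sigma_xy = K_LATERAL * lambda_em / NA
    sigma_z  = K_AXIAL   * lambda_em * n / NA**2

with ``K_LATERAL = 0.21`` and ``K_AXIAL = 0.66`` (paraxial Gaussian fits to the
confocal intensity PSF; Zhang, Zerubia & Olivo-Marin, Appl. Opt. 46, 2007).
Spherical aberration deepens the axial blur with imaging depth; this is modelled
as a linear inflation ``sigma_z(depth) = sigma_z0 * (1 + beta * depth)`` with a
documented default ``beta = 0.01 / µm``.

Deconvolution is the classical maximum-likelihood estimator for Poisson data,
i.e. Richardson-Lucy multiplicative updates, run per depth "brick" (a z-slab
deconvolved with the PSF evaluated at its mid-depth, slabs padded by the kernel
half-width and feather-blended). Regularization is a Tikhonov-style damping of
the multiplicative update with strength ``lam = 1 / snr**2``; iteration stops
when the relative change of the restoration quality (the normalized L2 residual
between the re-blurred estimate and the data) falls below the quality-change
threshold (default 0.1%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, signal
from scipy.special import erf

from .errors import ConfigurationError
from .stack import ImageStack

__all__ = [
    "PSFModel",
    "DeconvolutionSettings",
    "theoretical_psf",
    "build_bricks",
    "deconvolve_mle",
    "poisson_loglik",
]

K_LATERAL = 0.21
K_AXIAL = 0.66
#: per-tail mass below which the Gaussian kernel support is trimmed
_TAIL_MASS = 1e-6
#: half-width in sigmas beyond which a Gaussian tail holds < 1e-6 mass
_TAIL_SIGMAS = 4.75

_BRICK_COUNTS = {"more": 6, "few": 2, "one": 1}


def _gaussian_1d(sigma_um: float, spacing_um: float) -> np.ndarray:
    """Voxel-integrated normalized 1D Gaussian (exact within each voxel)."""
    if sigma_um <= 0:
        return np.ones(1)
    hw = max(1, int(math.ceil(_TAIL_SIGMAS * sigma_um / spacing_um)))
    edges = (np.arange(-hw, hw + 1 + 1) - 0.5) * spacing_um
    cdf = 0.5 * (1.0 + erf(edges / (sigma_um * math.sqrt(2.0))))
    g = np.diff(cdf)
    return g / g.sum()


def _outer3(gz: np.ndarray, gy: np.ndarray, gx: np.ndarray) -> np.ndarray:
    return gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def build_bricks(stack_depth_um: float, mode: str = "more") -> np.ndarray:
    """Partition ``[0, stack_depth]`` into contiguous depth bricks.

    ``mode`` is a brick-density label: ``"more"`` -> 6 bricks, ``"few"`` -> 2,
    ``"one"`` -> 1.  Returns the ``n_bricks + 1`` boundary depths in µm.
    """
    if stack_depth_um <= 0:
        raise ConfigurationError(f"stack depth must be positive, got {stack_depth_um}")
    try:
        n = _BRICK_COUNTS[mode]
    except KeyError:
        raise ConfigurationError(
            f"unknown brick mode {mode!r}; choose from {sorted(_BRICK_COUNTS)}"
        )
    return np.linspace(0.0, float(stack_depth_um), n + 1)


def theoretical_psf(
    spacing: Sequence[float],
    depth_um: float = 0.0,
    *,
    numerical_aperture: float = 1.30,
    emission_wavelength_nm: float = 527.0,
    refractive_index: float = 1.515,
    depth_aberration: float = 0.01,
) -> np.ndarray:
    """Normalized theoretical confocal PSF kernel at a given imaging depth.

    Parameters
    ----------
    spacing:
        ``(dz, dy, dx)`` grid sampling, µm.
    depth_um:
        Imaging depth; the axial sigma is inflated by ``1 + depth_aberration*depth``.
    """
    gz, gy, gx = _theoretical_factors(
        spacing,
        depth_um,
        numerical_aperture=numerical_aperture,
        emission_wavelength_nm=emission_wavelength_nm,
        refractive_index=refractive_index,
        depth_aberration=depth_aberration,
    )
    return _outer3(gz, gy, gx)


def _theoretical_factors(
    spacing,
    depth_um,
    *,
    numerical_aperture,
    emission_wavelength_nm,
    refractive_index,
    depth_aberration,
):
    if numerical_aperture <= 0 or emission_wavelength_nm <= 0:
        raise ConfigurationError("NA and wavelength must be positive")
    dz, dy, dx = (float(s) for s in spacing)
    if min(dz, dy, dx) <= 0:
        raise ConfigurationError("grid sampling must be positive")
    if depth_um < 0:
        raise ConfigurationError("depth must be >= 0")
    lam_um = emission_wavelength_nm * 1e-3
    sigma_xy = K_LATERAL * lam_um / numerical_aperture
    sigma_z = (
        K_AXIAL
        * lam_um
        * refractive_index
        / numerical_aperture**2
        * (1.0 + depth_aberration * depth_um)
    )
    if sigma_xy < 0.5 * min(dy, dx):
        raise ConfigurationError(
            f"lateral sampling {min(dy, dx):.3f} µm too coarse to resolve "
            f"sigma_xy = {sigma_xy:.3f} µm; use sampling <= {2 * sigma_xy:.3f} µm"
        )
    return (
        _gaussian_1d(sigma_z, dz),
        _gaussian_1d(sigma_xy, dy),
        _gaussian_1d(sigma_xy, dx),
    )


@dataclass
class PSFModel:
    """Theoretical PSF parameters plus the depth-brick kernel layout.

    ``brick_boundaries`` (length ``n+1``, strictly increasing, spanning the
    stack depth) assigns kernel ``i`` to depths in
    ``[brick_boundaries[i], brick_boundaries[i+1])``; each kernel is evaluated
    at its brick's mid-depth, is non-negative and sums to 1.
    """

    numerical_aperture: float
    emission_wavelength_nm: float
    refractive_index_immersion: float
    grid_sampling: tuple[float, float, float]  # (dz, dy, dx) µm
    brick_boundaries: np.ndarray
    kernels: list[np.ndarray]
    depth_aberration: float = 0.01
    # separable (gz, gy, gx) factors per brick, when the kernel is rank-1
    factors: list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        self.brick_boundaries = np.asarray(self.brick_boundaries, dtype=float)
        if len(self.kernels) != len(self.brick_boundaries) - 1:
            raise ConfigurationError("need one kernel per brick")
        if np.any(np.diff(self.brick_boundaries) <= 0):
            raise ConfigurationError("brick boundaries must be strictly increasing")
        for k in self.kernels:
            if np.any(k < 0) or abs(k.sum() - 1.0) > 1e-9:
                raise ConfigurationError("kernels must be non-negative and sum to 1")

    @property
    def n_bricks(self) -> int:
        return len(self.kernels)

    @classmethod
    def theoretical(
        cls,
        stack_depth_um: float,
        *,
        spacing: Sequence[float] = (0.200, 0.112, 0.112),
        brick_mode: str = "more",
        numerical_aperture: float = 1.30,
        emission_wavelength_nm: float = 527.0,
        refractive_index: float = 1.515,
        depth_aberration: float = 0.01,
    ) -> "PSFModel":
        """Build the depth-brick PSF stack for a stack of the given depth."""
        bounds = build_bricks(stack_depth_um, brick_mode)
        mids = 0.5 * (bounds[:-1] + bounds[1:])
        factors = [
            _theoretical_factors(
                spacing,
                d,
                numerical_aperture=numerical_aperture,
                emission_wavelength_nm=emission_wavelength_nm,
                refractive_index=refractive_index,
                depth_aberration=depth_aberration,
            )
            for d in mids
        ]
        kernels = [_outer3(*f) for f in factors]
        return cls(
            numerical_aperture,
            emission_wavelength_nm,
            refractive_index,
            tuple(float(s) for s in spacing),
            bounds,
            kernels,
            depth_aberration,
            factors,
        )

    @classmethod
    def gaussian(
        cls,
        sigma_zyx_um: Sequence[float],
        *,
        spacing: Sequence[float],
        stack_depth_um: float,
    ) -> "PSFModel":
        """Single-brick isoplanatic Gaussian PSF (used for controlled fixtures)."""
        dz, dy, dx = spacing
        sz, sy, sx = sigma_zyx_um
        f = (_gaussian_1d(sz, dz), _gaussian_1d(sy, dy), _gaussian_1d(sx, dx))
        return cls(
            float("nan"),
            float("nan"),
            float("nan"),
            tuple(float(s) for s in spacing),
            np.array([0.0, float(stack_depth_um)]),
            [_outer3(*f)],
            0.0,
            [f],
        )

    @classmethod
    def delta(cls, *, spacing: Sequence[float], stack_depth_um: float) -> "PSFModel":
        """Identity optics (a 1-voxel delta kernel)."""
        return cls.gaussian((0.0, 0.0, 0.0), spacing=spacing, stack_depth_um=stack_depth_um)


@dataclass
class DeconvolutionSettings:
    """Restoration settings mirroring the acquisition software's knobs.

    ``snr`` controls the Tikhonov damping ``lam = 1/snr**2`` of the
    multiplicative update; ``quality_change_threshold`` is the relative L2
    change between successive estimates below which iteration stops.
    """

    snr: float = 10.0
    quality_change_threshold: float = 0.001
    max_iterations: int = 100
    background_estimate: float = 0.0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ConfigurationError("snr must be > 0")
        if not (0 < self.quality_change_threshold < 1):
            raise ConfigurationError("quality_change_threshold must be in (0, 1)")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


# -- convolution machinery ---------------------------------------------------


def _conv_brick(
    volume: np.ndarray,
    psf: PSFModel,
    brick: int,
    flipped: bool = False,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Convolve a z-slab with one brick's kernel (zero boundary)."""
    if psf.factors is not None:
        gz, gy, gx = psf.factors[brick]
        if flipped:
            gz, gy, gx = gz[::-1], gy[::-1], gx[::-1]
        if out is None:
            out = np.empty_like(volume)
        ndimage.convolve1d(volume, gz, axis=0, mode="constant", cval=0.0, output=out)
        ndimage.convolve1d(out, gy, axis=1, mode="constant", cval=0.0, output=out)
        ndimage.convolve1d(out, gx, axis=2, mode="constant", cval=0.0, output=out)
        return out
    k = psf.kernels[brick]
    if flipped:
        k = k[::-1, ::-1, ::-1]
    res = signal.oaconvolve(volume, k, mode="same").astype(volume.dtype, copy=False)
    if out is not None:
        out[...] = res
        return out
    return res


def _brick_plan(psf: PSFModel, n_z: int, dz: float):
    """Per brick: (core z-range, padded z-range, kernel z half-width)."""
    plan = []
    for b in range(psf.n_bricks):
        z0 = int(round(psf.brick_boundaries[b] / dz))
        z1 = int(round(psf.brick_boundaries[b + 1] / dz)) if b + 1 < psf.n_bricks else n_z
        z1 = min(z1, n_z)
        if z1 <= z0:
            continue
        pad = psf.kernels[b].shape[0] // 2
        s0, s1 = max(0, z0 - pad), min(n_z, z1 + pad)
        plan.append((b, z0, z1, s0, s1))
    return plan


def _feather_weights(z0, z1, s0, s1):
    """Weight 1 on the brick core, linear ramp to the slab edges."""
    w = np.ones(s1 - s0)
    lo, hi = z0 - s0, s1 - z1
    if lo:
        w[:lo] = np.linspace(0, 1, lo + 2)[1:-1]
    if hi:
        w[-hi:] = np.linspace(1, 0, hi + 2)[1:-1]
    return w


def convolve_depth_varying(volume: np.ndarray, psf: PSFModel, dz: float) -> np.ndarray:
    """Blur a ``(z, y, x)`` volume with the depth-appropriate PSF brick.

    Each brick's slab is convolved with its own kernel (slabs padded by the
    kernel half-width) and the overlaps are blended by linear feathering.
    """
    n_z = volume.shape[0]
    for k in psf.kernels:
        if any(ks > vs for ks, vs in zip(k.shape, volume.shape)):
            raise ConfigurationError(
                f"PSF kernel {k.shape} larger than stack {volume.shape}"
            )
    if psf.n_bricks == 1:
        return _conv_brick(volume, psf, 0)
    out = np.zeros_like(volume)
    wsum = np.zeros(n_z, dtype=volume.dtype)
    for b, z0, z1, s0, s1 in _brick_plan(psf, n_z, dz):
        sub = _conv_brick(volume[s0:s1], psf, b)
        w = _feather_weights(z0, z1, s0, s1).astype(volume.dtype)
        out[s0:s1] += sub * w[:, None, None]
        wsum[s0:s1] += w
    out /= wsum[:, None, None]
    return out


# -- Richardson-Lucy ---------------------------------------------------------


def _rl_slab(data: np.ndarray, psf: PSFModel, brick: int, settings: DeconvolutionSettings):
    """Damped RL on one slab; returns (estimate, n_iter, final_change, quality).

    The restoration quality is the normalized L2 data residual
    ``q = ||data - H est|| / ||data||`` (fidelity of the re-blurred estimate to
    the measurement); iteration stops when the relative improvement of q drops
    below ``quality_change_threshold``.
    """
    lam = 1.0 / settings.snr**2
    est = np.maximum(data, 0.0)
    dnorm = math.sqrt(float(np.sum(np.square(data, dtype=np.float64))))
    if dnorm == 0.0:
        return est, 0, 0.0, 0.0
    change = np.inf
    q_prev = None
    it = 0
    q = 1.0
    buf = np.empty_like(est)
    tiny = np.float32(1e-25)
    for it in range(1, settings.max_iterations + 1):
        blur = _conv_brick(est, psf, brick, out=buf)
        q = (
            math.sqrt(float(np.einsum("ijk,ijk->", data - blur, data - blur, dtype=np.float64)))
            / dnorm
        )
        if q_prev is not None:
            change = abs(q_prev - q) / max(q_prev, 1e-30)
            if change < settings.quality_change_threshold:
                break
        q_prev = q
        np.maximum(blur, tiny, out=blur)
        np.divide(data, blur, out=blur)  # data==0 where blur was 0 -> ratio 0
        corr = _conv_brick(blur, psf, brick, flipped=True, out=blur)
        corr += lam
        corr /= 1.0 + lam
        est = est * corr
    return est, it, change, q


def deconvolve_mle(
    stack: ImageStack,
    psf: PSFModel,
    settings: DeconvolutionSettings | None = None,
) -> ImageStack:
    """Maximum-likelihood (Richardson-Lucy) deconvolution with depth bricks.

    The detector baseline/background (``settings.background_estimate``) is
    subtracted and the result clipped at zero before restoration; the output is
    therefore background-free. Above-background flux is conserved within ~1%
    for interior content. Non-convergence by ``max_iterations`` is recorded in
    the returned stack's ``metadata["deconvolution"]`` and warned about, the
    result is still returned.
    """
    if settings is None:
        settings = DeconvolutionSettings()
    if not np.all(np.isfinite(stack.data)):
        raise ValueError("stack contains non-finite voxels")
    dz = stack.spacing[0]
    if psf.brick_boundaries[-1] < stack.depth_um - dz / 2:
        raise ConfigurationError(
            f"PSF bricks span {psf.brick_boundaries[-1]:.2f} µm but the stack is "
            f"{stack.depth_um:.2f} µm deep"
        )
    n_z = stack.shape_zyx[0]
    out = np.empty_like(stack.data, dtype=np.float32)
    prov: dict = {"settings": vars(settings).copy(), "channels": {}}
    warn_msgs = []
    for c, name in enumerate(stack.channel_names):
        data = np.maximum(
            stack.data[c].astype(np.float32) - settings.background_estimate, 0.0
        )
        info = []
        if psf.n_bricks == 1:
            est, it, change, q = _rl_slab(data, psf, 0, settings)
            out[c] = est
            info.append({"brick": 0, "iterations": it, "final_change": change, "quality": q})
        else:
            acc = np.zeros_like(data)
            wsum = np.zeros(n_z, dtype=np.float32)
            for b, z0, z1, s0, s1 in _brick_plan(psf, n_z, dz):
                est, it, change, q = _rl_slab(data[s0:s1], psf, b, settings)
                w = _feather_weights(z0, z1, s0, s1).astype(np.float32)
                acc[s0:s1] += est * w[:, None, None]
                wsum[s0:s1] += w
                info.append({"brick": b, "iterations": it, "final_change": change, "quality": q})
            acc /= wsum[:, None, None]
            out[c] = acc
        for rec in info:
            if rec["final_change"] >= settings.quality_change_threshold:
                warn_msgs.append(
                    f"channel {name} brick {rec['brick']}: quality change "
                    f"{rec['final_change']:.2e} still above threshold after "
                    f"{rec['iterations']} iterations"
                )
        prov["channels"][name] = info
    prov["warnings"] = warn_msgs
    for msg in warn_msgs:
        warnings.warn("deconvolution did not converge: " + msg, stacklevel=2)
    meta = dict(stack.metadata)
    meta["deconvolution"] = prov
    return stack.with_data(out, meta)


def poisson_loglik(data: np.ndarray, estimate: np.ndarray, psf: PSFModel, brick: int = 0) -> float:
    """Poisson log-likelihood of ``data`` under the blurred ``estimate``.

    The quantity RL maximizes: ``sum(d * log(H e) - H e)`` (additive constants
    dropped); used to verify monotone data fidelity across iterations.
    """
    blur = _conv_brick(np.asarray(estimate, dtype=np.float64), psf, brick)
    mask = blur > 1e-30
    d = np.asarray(data, dtype=np.float64)
    return float(np.sum(d[mask] * np.log(blur[mask]) - blur[mask]) - np.sum(blur[~mask]))
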