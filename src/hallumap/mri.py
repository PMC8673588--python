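"""Stylized 2D single-coil MRI system: masked unitary Fourier forward model.

The imaging operator is ``H = M F`` where ``F`` is the unitary 2D discrete
Fourier transform (DC at grid center) and ``M`` zeroes the unsampled k-space
locations of a binary Cartesian mask.  Because ``F`` is unitary, every
nonzero singular value of ``H`` equals 1, the Moore-Penrose pseudoinverse is
exactly the inverse FFT of the zero-filled k-space data, and no singular
value truncation is needed: the generalized null space coincides with the
true null space (the span of the unsampled Fourier modes).

Measurement errors are emulated by a per-sample multiplicative uniform phase
perturbation (model error) followed by additive iid Gaussian noise on the
real and imaginary channels, applied at sampled k-space locations only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np
from numpy.fft import fft2, fftshift, ifft2, ifftshift

from .operators import DEFAULT_NULL_FLOOR, LinearOperator


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered unitary 2D FFT (DC at ``(rows//2, cols//2)``)."""
    return fftshift(fft2(ifftshift(x), norm="ortho"))


def ifft2c(k: np.ndarray) -> np.ndarray:
    """Centered unitary 2D inverse FFT; the adjoint (and inverse) of :func:`fft2c`."""
    return fftshift(ifft2(ifftshift(k), norm="ortho"))


@dataclass
class SamplingMask:
    """Binary Cartesian k-space sampling mask on the image grid."""

    grid: np.ndarray
    accel: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2D")
        if not np.any(self.grid):
            raise ValueError("mask must sample at least one location")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.grid.shape

    @property
    def n_sampled(self) -> int:
        return int(np.count_nonzero(self.grid))


@dataclass
class NoiseModel:
    """k-space corruption model.

    ``gaussian_sigma`` is the std of the iid Gaussian noise added to the real
    and imaginary channels; ``phase_amp`` the half-width (radians) of the
    zero-mean uniform multiplicative phase perturbation that emulates model
    error.
    """

    gaussian_sigma: float = 0.0
    phase_amp: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.gaussian_sigma < 0 or self.phase_amp < 0:
            raise ValueError("noise amplitudes must be nonnegative")


def make_cartesian_mask(
    rows: int, cols: int, accel: int, center_offset: int | None = None
) -> SamplingMask:
    """Uniform Cartesian mask sampling every ``accel``-th phase-encode row.

    Rows ``r`` with ``r % accel == center_offset`` are sampled; with
    ``center_offset=0`` exactly ``ceil(rows/accel)`` rows are kept.  The
    default ``center_offset=None`` aligns the comb with the DC row (grid
    center under the shifted FFT convention), i.e. uses
    ``(rows//2) % accel``.  ``accel == 1`` gives a fully sampled mask.
    """
    if accel < 1:
        raise ValueError("accel must be >= 1")
    if accel > rows:
        raise ValueError(f"accel {accel} exceeds number of rows {rows}")
    if center_offset is None:
        center_offset = (rows // 2) % accel
    r = np.arange(rows)
    sampled = r % accel == center_offset % accel
    grid = np.zeros((rows, cols), dtype=np.uint8)
    grid[sampled, :] = 1
    return SamplingMask(grid=grid, accel=float(accel))


def forward(obj: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Noiseless measurement ``g = M F obj`` (zeros at unsampled locations)."""
    obj = np.asarray(obj)
    if obj.shape != mask.shape:
        raise ValueError(f"object shape {obj.shape} != mask shape {mask.shape}")
    return mask.grid * fft2c(obj)


def corrupt(g: np.ndarray, mask: SamplingMask, noise: NoiseModel) -> np.ndarray:
    """Apply phase perturbation then additive Gaussian noise at sampled locations.

    Reproducible: the same ``noise.seed`` yields the same corruption.
    """
    g = np.asarray(g, dtype=complex)
    rng = np.random.default_rng(noise.seed)
    phase = rng.uniform(-noise.phase_amp, noise.phase_amp, size=g.shape)
    eta = rng.normal(0.0, noise.gaussian_sigma, size=g.shape) + 1j * rng.normal(
        0.0, noise.gaussian_sigma, size=g.shape
    )
    return mask.grid * (g * np.exp(1j * phase) + eta)


def pseudoinverse(g: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Zero-filled inverse FFT, the exact Moore-Penrose pseudoinverse of ``M F``."""
    return ifft2c(mask.grid * np.asarray(g))


def fourier_projectors(
    mask: SamplingMask, zero_floor: float = DEFAULT_NULL_FLOOR
) -> Tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]:
    """Analytic measurement/null projectors of the masked unitary Fourier operator.

    All nonzero singular values equal 1, so ``P_meas = F^-1 M F`` and
    ``P_null = F^-1 (1 - M) F``.  In the null projector, retained k-space
    coefficients with magnitude below ``zero_floor * max|F theta|`` are
    snapped to zero: an image lying exactly in the measurement space (any
    zero-filled pseudoinverse reconstruction) then projects to a bitwise-zero
    array instead of FFT round-trip dust.
    """
    sampled = mask.grid.astype(bool)

    def p_meas(theta: np.ndarray) -> np.ndarray:
        return ifft2c(np.where(sampled, fft2c(theta), 0.0))

    def p_null(theta: np.ndarray) -> np.ndarray:
        k = fft2c(theta)
        kn = np.where(sampled, 0.0, k)
        scale = np.max(np.abs(k))
        if scale > 0 and zero_floor > 0:
            kn = np.where(np.abs(kn) <= zero_floor * scale, 0.0, kn)
        if not np.any(kn):
            return np.zeros(theta.shape, dtype=complex)
        return ifft2c(kn)

    return p_meas, p_null


class MaskedFourierOperator(LinearOperator):
    """The masked unitary Fourier operator as a structured :class:`LinearOperator`.

    The measurement space is the full k-space grid with zeros at unsampled
    entries.  Provides an analytic singular system (unit singular values;
    right vectors are the complex exponentials of the sampled frequencies) so
    dense materialization is only needed for oracle comparisons.
    """

    def __init__(self, mask: SamplingMask):
        self.mask = mask
        super().__init__(
            shape_in=mask.shape,
            shape_out=mask.shape,
            apply=lambda x: forward(x, mask),
            adjoint_apply=lambda y: pseudoinverse(y, mask),
            kind="structured",
        )

    def singular_system(self):
        rows, cols = self.mask.shape
        idx = np.flatnonzero(self.mask.grid.reshape(-1))
        P = idx.size
        sigma = np.ones(P)
        V = np.zeros((rows * cols, P), dtype=complex)
        V[idx, np.arange(P)] = 1.0
        U = np.zeros((rows * cols, P), dtype=complex)
        delta = np.zeros((rows, cols), dtype=complex)
        flat = delta.reshape(-1)
        for j, i in enumerate(idx):
            flat[i] = 1.0
            U[:, j] = np.ravel(ifft2c(delta))
            flat[i] = 0.0
        return sigma, U, V

    @property
    def null_dim(self) -> int:
        return self.n_object - self.mask.n_sampled
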