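"""Reconstruction methods analyzed for hallucination behavior.

Two concrete reconstructors are provided:

* ``recon_tp`` — the zero-filled pseudoinverse (the stable linear estimate;
  for the unitary masked-Fourier system no singular-value truncation is
  needed).  It imposes no prior and by construction carries no hallucination.
* ``recon_plstv`` — penalized least squares with an isotropic total-variation
  penalty, ``argmin_theta 1/2 ||g - H theta||^2 + lambda TV(theta)``, solved
  by a monotone accelerated proximal-gradient scheme (MFISTA) with a
  Chambolle-type dual iteration for the TV proximal map.

Any external method can be analyzed through the same contract: a callable
``(g, mask) -> complex image`` is all the hallucination-map machinery needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from .mri import SamplingMask, fft2c, ifft2c, pseudoinverse


@dataclass
class ReconResult:
    """Estimate plus solver provenance."""

    estimate: np.ndarray
    method: str
    iterations: int = 0
    objective_trace: List[float] = field(default_factory=list)
    config: Dict = field(default_factory=dict)


def _forward_diff(x: np.ndarray):
    """Forward differences with reflective boundary (zero difference at the edge)."""
    dy = np.zeros_like(x)
    dx = np.zeros_like(x)
    dy[:-1, :] = x[1:, :] - x[:-1, :]
    dx[:, :-1] = x[:, 1:] - x[:, :-1]
    return dy, dx


def _divergence(py: np.ndarray, px: np.ndarray) -> np.ndarray:
    """Negative adjoint of :func:`_forward_diff`."""
    div = np.zeros_like(py)
    div[0, :] += py[0, :]
    div[1:-1, :] += py[1:-1, :] - py[:-2, :]
    div[-1, :] += -py[-2, :]
    div[:, 0] += px[:, 0]
    div[:, 1:-1] += px[:, 1:-1] - px[:, :-2]
    div[:, -1] += -px[:, -2]
    return div


def tv(theta: np.ndarray) -> float:
    """Isotropic total variation; complex images contribute real + imaginary parts."""
    theta = np.asarray(theta)
    if np.iscomplexobj(theta):
        return tv(theta.real) + tv(theta.imag)
    dy, dx = _forward_diff(theta.astype(float))
    return float(np.sum(np.sqrt(dy**2 + dx**2)))


def _tv_prox_real(f: np.ndarray, weight: float, n_iter: int = 30, tau: float = 0.249) -> np.ndarray:
    """Chambolle dual iteration for ``argmin_u 1/2||u-f||^2 + weight*TV(u)``."""
    if weight <= 0:
        return f.copy()
    py = np.zeros_like(f)
    px = np.zeros_like(f)
    for _ in range(n_iter):
        u = _divergence(py, px) - f / weight
        gy, gx = _forward_diff(u)
        denom = 1.0 + tau * np.sqrt(gy**2 + gx**2)
        py = (py + tau * gy) / denom
        px = (px + tau * gx) / denom
    return f - weight * _divergence(py, px)


def tv_prox(f: np.ndarray, weight: float, n_iter: int = 30) -> np.ndarray:
    """TV proximal map; applied to real and imaginary channels separately."""
    f = np.asarray(f)
    if np.iscomplexobj(f):
        return _tv_prox_real(f.real, weight, n_iter) + 1j * _tv_prox_real(f.imag, weight, n_iter)
    return _tv_prox_real(f.astype(float), weight, n_iter)


def recon_tp(g: np.ndarray, mask: SamplingMask) -> ReconResult:
    """Truncated/Moore-Penrose pseudoinverse estimate (zero-filled inverse FFT)."""
    return ReconResult(estimate=pseudoinverse(g, mask), method="tp")


def recon_plstv(
    g: np.ndarray,
    mask: SamplingMask,
    lam: float,
    max_iter: int = 500,
    tol: float = 1e-6,
    step: float = 1.0,
    prox_iter: int = 30,
    divergence_patience: int = 30,
) -> ReconResult:
    """PLS-TV reconstruction by monotone FISTA.

    The data-fidelity gradient is ``H^dagger(H theta - g)``; the operator norm
    of the unitary masked-Fourier system is 1, so the default step size 1 is
    the exact Lipschitz step.  Accelerated candidates are accepted only when
    they do not increase the objective, so the objective trace is
    nonincreasing even with an inexact inner TV prox.

    Raises ``RuntimeError`` if candidates increase the objective for
    ``divergence_patience`` consecutive iterations (a too-large ``step``).
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    g = np.asarray(g, dtype=complex)
    sampled = mask.grid.astype(bool)
    gm = np.where(sampled, g, 0.0)

    def objective(theta):
        resid = np.where(sampled, fft2c(theta), 0.0) - gm
        return 0.5 * float(np.sum(np.abs(resid) ** 2)) + lam * tv(theta)

    def grad(theta):
        return ifft2c(np.where(sampled, fft2c(theta), 0.0) - gm)

    x_prev = np.zeros(mask.shape, dtype=complex)
    y = x_prev
    t = 1.0
    f_prev = objective(x_prev)
    trace = [f_prev]
    n_bad = 0
    iterations = 0
    for k in range(max_iter):
        iterations = k + 1
        z = tv_prox(y - step * grad(y), step * lam, n_iter=prox_iter)
        f_z = objective(z)
        accepted = f_z <= f_prev
        if accepted:
            x, f_x = z, f_z
            n_bad = 0
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            y = x + (t / t_next) * (z - x) + ((t - 1.0) / t_next) * (x - x_prev)
            t = t_next
        else:
            # monotone safeguard: keep the previous iterate, restart momentum.
            # A benign stall from an inexact prox hovers just above f_prev;
            # an unstable step overshoots it badly — only the latter counts
            # toward divergence.
            x, f_x = x_prev, f_prev
            if f_z > 1.01 * f_prev + 1e-12:
                n_bad += 1
            if n_bad >= divergence_patience:
                raise RuntimeError(
                    f"PLS-TV objective increased for {n_bad} consecutive iterations; "
                    f"step size {step} is too large for this operator"
                )
            y = x
            t = 1.0
        trace.append(f_x)
        converged = accepted and abs(f_prev - f_x) <= tol * max(abs(f_prev), 1e-30)
        x_prev, f_prev = x, f_x
        if converged:
            break

    return ReconResult(
        estimate=x_prev,
        method="plstv",
        iterations=iterations,
        objective_trace=trace,
        config=dict(lam=lam, max_iter=max_iter, tol=tol, step=step, prox_iter=prox_iter),
    )
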