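"""Hallucination, error, and bias maps.

A reconstructed estimate ``theta_hat`` splits uniquely into a generalized
measurement component (stably determined by the data) and a generalized null
component (determined only by the reconstruction prior).  The maps defined
here isolate the error attributable to the prior:

* measurement-space hallucination map: ``P_meas theta_hat - theta_hat_tp``,
  the deviation of the estimate's stable component from the truncated
  pseudoinverse solution.  Needs no knowledge of the true object.
* null-space hallucination map: ``1(theta_hat_null) * (theta_hat_null -
  theta_null)``, where ``1`` is the pixelwise exact-zero indicator.  The
  indicator guarantees that an estimator that never invents null-space
  content (the pseudoinverse) has an identically zero map, while any
  prior-driven null content is compared against the true object's null
  component.
* error map: the conventional ``theta_hat - theta_true``.
* bias map: the ensemble mean of estimates minus the truth, over repeated
  Gaussian noise realizations with the model-error phase perturbation held
  fixed.

Maps are computed in complex arithmetic; the stored real ``values`` default
to the real part (``reduction="magnitude"`` is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple, Union

import numpy as np

from . import operators as ops
from .mri import NoiseModel, SamplingMask, forward, fourier_projectors, pseudoinverse

SystemSpec = Union[SamplingMask, Tuple[ops.OperatorSVD, ops.TruncationSpec]]


@dataclass
class ProjectorSet:
    """Measurement/null projectors plus the stable (tp) estimator for a system."""

    project_meas: Callable[[np.ndarray], np.ndarray]
    project_null: Callable[[np.ndarray], np.ndarray]
    tp: Callable[[np.ndarray], np.ndarray]

    @classmethod
    def from_mask(cls, mask: SamplingMask) -> "ProjectorSet":
        p_meas, p_null = fourier_projectors(mask)
        return cls(p_meas, p_null, lambda g: pseudoinverse(g, mask))

    @classmethod
    def from_svd(cls, svd: ops.OperatorSVD, trunc: ops.TruncationSpec) -> "ProjectorSet":
        return cls(
            lambda x: ops.project_meas(svd, trunc, x),
            lambda x: ops.project_null(svd, trunc, x),
            lambda g: ops.truncated_pinv_apply(svd, trunc, g),
        )


def resolve_system(system: SystemSpec) -> ProjectorSet:
    if isinstance(system, ProjectorSet):
        return system
    if isinstance(system, SamplingMask):
        return ProjectorSet.from_mask(system)
    svd, trunc = system
    return ProjectorSet.from_svd(svd, trunc)


@dataclass
class HallucinationMap:
    """A labeled real-valued 2D map together with its complex source."""

    values: np.ndarray
    space: str  # {measurement, null, error, bias}
    method: str = ""
    reduction: str = "real_part"
    complex_values: Optional[np.ndarray] = None
    meta: Dict = field(default_factory=dict)

    def l2(self) -> float:
        src = self.complex_values if self.complex_values is not None else self.values
        return float(np.linalg.norm(src))


def _reduce(cmap: np.ndarray, reduction: str) -> np.ndarray:
    if reduction == "real_part":
        return cmap.real.copy()
    if reduction == "magnitude":
        return np.abs(cmap)
    raise ValueError(f"unknown reduction {reduction!r}")


def _finish(cmap, space, method, reduction, **meta) -> HallucinationMap:
    cmap = np.asarray(cmap, dtype=complex)
    return HallucinationMap(
        values=_reduce(cmap, reduction),
        space=space,
        method=method,
        reduction=reduction,
        complex_values=cmap,
        meta=meta,
    )


def measurement_hallucination_map(
    theta_hat: np.ndarray,
    g: np.ndarray,
    system: SystemSpec,
    method: str = "",
    reduction: str = "real_part",
) -> HallucinationMap:
    """``P_meas theta_hat - theta_hat_tp``; no true object required."""
    proj = resolve_system(system)
    cmap = proj.project_meas(np.asarray(theta_hat, dtype=complex)) - proj.tp(g)
    return _finish(cmap, "measurement", method, reduction)


def null_hallucination_map(
    theta_hat: np.ndarray,
    theta_true: np.ndarray,
    system: SystemSpec,
    method: str = "",
    reduction: str = "real_part",
    indicator_atol: float = 0.0,
) -> HallucinationMap:
    """``1(theta_hat_null) * (theta_hat_null - theta_null)``.

    The pixel indicator is 1 where the estimate's null component is nonzero.
    ``indicator_atol`` widens "zero" to ``|.| <= atol`` for studying near-zero
    cases; the default 0 keeps the literal exact-zero definition (estimates
    with a structurally zero null component, such as any pseudoinverse image,
    yield an identically zero map).
    """
    proj = resolve_system(system)
    hat_null = proj.project_null(np.asarray(theta_hat, dtype=complex))
    true_null = proj.project_null(np.asarray(theta_true, dtype=complex))
    indicator = np.abs(hat_null) > indicator_atol if indicator_atol > 0 else hat_null != 0
    cmap = np.where(indicator, hat_null - true_null, 0.0)
    return _finish(cmap, "null", method, reduction, indicator_atol=indicator_atol)


def error_map(
    theta_hat: np.ndarray,
    theta_true: np.ndarray,
    method: str = "",
    reduction: str = "real_part",
) -> HallucinationMap:
    """Conventional error map ``theta_hat - theta_true``."""
    cmap = np.asarray(theta_hat, dtype=complex) - np.asarray(theta_true, dtype=complex)
    return _finish(cmap, "error", method, reduction)


def bias_map(
    recon_fn: Callable[[np.ndarray, SamplingMask], np.ndarray],
    theta_true: np.ndarray,
    mask: SamplingMask,
    noise: NoiseModel,
    n_realizations: int = 100,
    seed: int = 0,
    method: str = "",
    reduction: str = "real_part",
) -> HallucinationMap:
    """Empirical bias ``E[theta_hat] - theta_true`` over noise realizations.

    The uniform phase perturbation (model error) is drawn once from ``seed``
    and held fixed; the iid Gaussian measurement noise is redrawn for each of
    the ``n_realizations`` (default 100) realizations.  ``recon_fn`` maps
    ``(g, mask)`` to an estimate (a :class:`~hallumap.recon.ReconResult` or a
    plain complex image).
    """
    if n_realizations < 2:
        raise ValueError("n_realizations must be >= 2")
    theta_true = np.asarray(theta_true, dtype=complex)
    g_clean = forward(theta_true, mask)
    rng = np.random.default_rng(seed)
    phase = rng.uniform(-noise.phase_amp, noise.phase_amp, size=g_clean.shape)
    g_phase = g_clean * np.exp(1j * phase)
    sampled = mask.grid.astype(bool)
    acc = np.zeros(theta_true.shape, dtype=complex)
    for _ in range(n_realizations):
        eta = rng.normal(0.0, noise.gaussian_sigma, size=g_clean.shape) + 1j * rng.normal(
            0.0, noise.gaussian_sigma, size=g_clean.shape
        )
        g_i = np.where(sampled, g_phase + eta, 0.0)
        est = recon_fn(g_i, mask)
        est = getattr(est, "estimate", est)
        acc += est
    cmap = acc / n_realizations - theta_true
    return _finish(
        cmap, "bias", method, reduction, n_realizations=n_realizations, seed=seed
    )
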