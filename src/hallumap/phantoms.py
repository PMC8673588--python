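"""Seeded synthetic test objects with anatomy-like structure.

Two visually distinct phantom families stand in for in-distribution and
out-of-distribution image populations: family A uses a few large smooth
ellipses with low-frequency internal texture, family B many smaller ellipses
with higher-frequency texture.  Every phantom is a real-valued image in
[0, 1] whose support lies strictly inside the field of view, optionally with
an inserted circular lesion of known contrast, plus a binary support mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .mri import fft2c, ifft2c

# family-specific generator settings: (default n_ellipses, axis range as a
# fraction of the grid, texture low-pass cutoff as a fraction of Nyquist)
_FAMILY_PARAMS = {
    "A": dict(n_ellipses=4, axis_frac=(0.18, 0.34), cutoff_frac=0.12),
    "B": dict(n_ellipses=9, axis_frac=(0.07, 0.16), cutoff_frac=0.45),
}


@dataclass
class PhantomSpec:
    """Recipe for one synthetic object; identical specs give identical phantoms."""

    size: Tuple[int, int] = (64, 64)
    family: str = "A"
    n_ellipses: Optional[int] = None
    texture_amp: float = 0.03
    lesion: Optional[Tuple[Tuple[float, float], float, float]] = None  # (center, radius, contrast)
    seed: int = 0

    def __post_init__(self):
        if self.family not in _FAMILY_PARAMS:
            raise ValueError(f"unknown family {self.family!r}; choose A or B")
        if min(self.size) < 32:
            raise ValueError("phantom size must be at least 32x32")
        if self.n_ellipses is None:
            self.n_ellipses = _FAMILY_PARAMS[self.family]["n_ellipses"]


def _ellipse_mask(shape, center, axes, angle) -> np.ndarray:
    rows, cols = shape
    y, x = np.mgrid[0:rows, 0:cols]
    y = y - center[0]
    x = x - center[1]
    c, s = np.cos(angle), np.sin(angle)
    yr = c * y + s * x
    xr = -s * y + c * x
    return (yr / axes[0]) ** 2 + (xr / axes[1]) ** 2 <= 1.0


def _bandlimited_texture(shape, cutoff_frac, rng) -> np.ndarray:
    """Unit-RMS low-pass-filtered white noise (isotropic cutoff in k-space)."""
    rows, cols = shape
    noise = rng.normal(size=shape)
    k = fft2c(noise)
    fy = np.fft.fftshift(np.fft.fftfreq(rows))
    fx = np.fft.fftshift(np.fft.fftfreq(cols))
    radius = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    k = np.where(radius <= 0.5 * cutoff_frac, k, 0.0)
    tex = ifft2c(k).real
    rms = np.sqrt(np.mean(tex**2))
    return tex / rms if rms > 0 else tex


def generate(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Generate one phantom and its binary support mask.

    The image is the sum of overlapping constant-intensity ellipses, rescaled
    to peak 0.8, plus zero-mean band-limited texture of RMS ``texture_amp``
    restricted to the support, plus an optional additive lesion disk of the
    requested contrast.  Values are clipped to [0, 1].
    """
    params = _FAMILY_PARAMS[spec.family]
    rows, cols = spec.size
    rng = np.random.default_rng(spec.seed)

    margin = 0.12 * min(rows, cols)
    img = np.zeros(spec.size)
    support = np.zeros(spec.size, dtype=bool)
    lo, hi = params["axis_frac"]
    for _ in range(spec.n_ellipses):
        axes = rng.uniform(lo, hi, size=2) * min(rows, cols)
        amax = axes.max()
        center = (
            rng.uniform(margin + amax, rows - margin - amax),
            rng.uniform(margin + amax, cols - margin - amax),
        )
        angle = rng.uniform(0, np.pi)
        level = rng.uniform(0.35, 0.9)
        mask = _ellipse_mask(spec.size, center, axes, angle)
        img += level * mask
        support |= mask

    peak = img.max()
    if peak > 0:
        img *= 0.8 / peak

    if spec.texture_amp > 0:
        tex = _bandlimited_texture(spec.size, params["cutoff_frac"], rng)
        img = img + spec.texture_amp * tex * support

    if spec.lesion is not None:
        (cy, cx), radius, contrast = spec.lesion
        y, x = np.mgrid[0:rows, 0:cols]
        disk = (y - cy) ** 2 + (x - cx) ** 2 <= radius**2
        if not np.all(support[disk]):
            raise ValueError("lesion extends outside the phantom support")
        img = img + contrast * disk

    return np.clip(img, 0.0, 1.0), support


def generate_ensemble(
    spec_template: PhantomSpec, n: int, base_seed: int
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """``n`` independently seeded phantoms sharing the template's parameters."""
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for s in seeds:
        spec = PhantomSpec(
            size=spec_template.size,
            family=spec_template.family,
            n_ellipses=spec_template.n_ellipses,
            texture_amp=spec_template.texture_amp,
            lesion=spec_template.lesion,
            seed=int(s),
        )
        out.append(generate(spec))
    return out


def texture_power(img: np.ndarray, cutoff_frac: float = 0.2) -> float:
    """Fraction of image energy above an isotropic frequency cutoff.

    A simple summary statistic that separates the two phantom families
    (family B carries more high-frequency texture energy than family A).
    """
    k = fft2c(img)
    rows, cols = img.shape
    fy = np.fft.fftshift(np.fft.fftfreq(rows))
    fx = np.fft.fftshift(np.fft.fftfreq(cols))
    radius = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    total = np.sum(np.abs(k) ** 2)
    if total == 0:
        return 0.0
    return float(np.sum(np.abs(k[radius > 0.5 * cutoff_frac]) ** 2) / total)
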