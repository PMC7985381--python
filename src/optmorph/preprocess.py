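"""Projection-stack preprocessing.

Bright-field stacks get homomorphic brightness normalization (multiplicative
illumination bias is separated from scene content in the log domain) and,
when the acquisition was simulated as raw transmission, the log linearization
that turns transmitted intensity back into attenuation line integrals.
Fluorescence stacks get median filtering against photon noise, linear
brightness adjustment, and per-angle rigid alignment of the dead channel to
the live channel for live/dead composites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import fft, ndimage

from .simulate import ProjectionStack

__all__ = [
    "homomorphic_filter",
    "median_filter_stack",
    "brightness_adjust",
    "compose_live_dead",
    "transmission_to_attenuation",
    "CompositeStack",
]

log = logging.getLogger(__name__)


def _high_emphasis_transfer(shape, cutoff: float, low_gain: float, high_gain: float):
    fy = fft.fftfreq(shape[0])[:, None]
    fx = fft.fftfreq(shape[1])[None, :]
    f2 = fy * fy + fx * fx
    return low_gain + (high_gain - low_gain) * (1.0 - np.exp(-f2 / (2.0 * cutoff * cutoff)))


def homomorphic_filter(
    stack: ProjectionStack,
    cutoff_freq: float = 0.02,
    low_gain: float = 0.3,
    high_gain: float = 1.0,
) -> ProjectionStack:
    """Normalize image brightness with a Gaussian high-emphasis homomorphic filter.

    Per projection: log-transform, multiply the spectrum by
    ``H(f) = low_gain + (high_gain − low_gain)·(1 − exp(−f²/(2·cutoff²)))``
    (attenuates the low-frequency illumination term, passes scene detail),
    then exponentiate.  ``cutoff_freq`` is in cycles/pixel.
    """
    if not (0.0 < low_gain <= 1.0 <= high_gain):
        raise ValueError("require 0 < low_gain <= 1 <= high_gain")
    if not (0.0 < cutoff_freq < 0.5):
        raise ValueError("cutoff_freq must be in (0, 0.5) cycles/pixel")
    data = stack.data
    if data.min() <= 0.0:
        eps = 1e-6 * max(data.max(), 1.0)
        log.warning("homomorphic_filter: nonpositive intensities, adding epsilon %.3g", eps)
        data = data + eps
    h = _high_emphasis_transfer(data.shape[1:], cutoff_freq, low_gain, high_gain)
    out = np.empty_like(data)
    for i in range(data.shape[0]):
        spectrum = fft.fft2(np.log(data[i]))
        out[i] = np.exp(np.real(fft.ifft2(spectrum * h)))
    return stack.copy_with(out)


def median_filter_stack(stack: ProjectionStack, window: int = 3) -> ProjectionStack:
    """2D median filter applied to each projection; window must be odd, 1 = identity."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window == 1:
        return stack.copy_with(stack.data.copy())
    out = np.empty_like(stack.data)
    for i in range(stack.data.shape[0]):
        out[i] = ndimage.median_filter(stack.data[i], size=window)
    return stack.copy_with(out)


def brightness_adjust(
    stack: ProjectionStack,
    out_range: tuple[float, float] = (0.0, 1.0),
    percentiles: tuple[float, float] = (0.5, 99.5),
) -> ProjectionStack:
    """Linear rescale of the stack's percentile range onto ``out_range``.

    The map is a pure affine transform anchored at the two percentiles, so
    pixel ordering is preserved exactly (no clipping).
    """
    lo_p, hi_p = percentiles
    lo, hi = np.percentile(stack.data, [lo_p, hi_p])
    if hi <= lo:
        raise ValueError("stack has no dynamic range between the chosen percentiles")
    a, b = out_range
    out = (stack.data - lo) * ((b - a) / (hi - lo)) + a
    return stack.copy_with(out)


def transmission_to_attenuation(stack: ProjectionStack, i0: float = 1.0) -> ProjectionStack:
    """Log-linearize raw transmission projections: p = −log(I / I0)."""
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    data = stack.data
    if data.min() <= 0:
        eps = 1e-9 * max(data.max(), 1.0)
        log.warning("transmission_to_attenuation: zeros present, clamping at %.3g", eps)
        data = np.maximum(data, eps)
    return stack.copy_with(-np.log(data / i0))


@dataclass
class CompositeStack:
    """Two-channel live/dead composite with the per-angle alignment shifts."""

    live: ProjectionStack
    dead_aligned: ProjectionStack
    shifts: np.ndarray  # (n_angles, 2): (d_row, d_col) applied to the dead channel


def _best_integer_shift(ref: np.ndarray, mov: np.ndarray, radius: int) -> tuple[int, int]:
    """Integer shift of ``mov`` maximizing normalized cross-correlation to ``ref``."""
    ref_c = ref - ref.mean()
    ref_norm = np.linalg.norm(ref_c)
    best, best_shift = -np.inf, (0, 0)
    for dy in range(-radius, radius + 1):
        rolled_y = np.roll(mov, dy, axis=0)
        for dx in range(-radius, radius + 1):
            shifted = np.roll(rolled_y, dx, axis=1)
            s_c = shifted - shifted.mean()
            denom = ref_norm * np.linalg.norm(s_c)
            ncc = 0.0 if denom == 0 else float(np.dot(ref_c.ravel(), s_c.ravel()) / denom)
            if ncc > best or (ncc == best and (abs(dy) + abs(dx) < abs(best_shift[0]) + abs(best_shift[1]))):
                best, best_shift = ncc, (dy, dx)
    return best_shift


def compose_live_dead(
    live: ProjectionStack,
    dead: ProjectionStack,
    search_radius: int = 10,
) -> CompositeStack:
    """Align the dead channel to the live channel per angle and stack channels.

    Alignment is an exhaustive integer-shift search (±``search_radius`` px)
    maximizing normalized cross-correlation.  An all-zero dead projection
    gets zero shift and a logged warning.
    """
    if live.data.shape != dead.data.shape or not np.array_equal(live.angles_deg, dead.angles_deg):
        raise ValueError("live and dead stacks must share angles and frame shape")
    n = live.n_angles
    shifts = np.zeros((n, 2), dtype=int)
    aligned = np.empty_like(dead.data)
    for i in range(n):
        mov = dead.data[i]
        if not np.any(mov) or np.ptp(mov) == 0:
            log.warning("compose_live_dead: degenerate dead projection at angle index %d", i)
            aligned[i] = mov
            continue
        dy, dx = _best_integer_shift(live.data[i], mov, search_radius)
        shifts[i] = (dy, dx)
        aligned[i] = np.roll(np.roll(mov, dy, axis=0), dx, axis=1)
    dead_out = ProjectionStack(aligned, dead.angles_deg.copy(), dead.pixel_pitch_um, dead.modality)
    return CompositeStack(live=live, dead_aligned=dead_out, shifts=shifts)
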