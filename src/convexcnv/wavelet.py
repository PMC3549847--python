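"""Haar wavelet denoising of the ratio track with level-wise SURE thresholding.

The per-exon ratio is modelled as a piecewise-constant copy-number signal
plus iid Gaussian noise.  Each chromosome is smoothed independently:

* the ratio vector is extended on the right by reflection to the next
  power-of-two length and decomposed with the orthonormal Haar wavelet
  (periodized, so the transform is exactly orthogonal and energy-preserving);
* the noise scale sigma is estimated from the finest detail level by the
  median-absolute-deviation rule, median(|d|)/0.6745;
* every detail level gets its own soft threshold chosen by minimizing
  Stein's unbiased risk estimate (SURE) over the candidate set
  {0} union {|d_i|}; approximation coefficients are never thresholded;
* the inverse transform is cropped back to the original length and clipped
  at zero (ratios are non-negative by construction).

Because the Haar transform is orthonormal, the noise has the same standard
deviation at every level and the finest-level estimate is reused unscaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .preprocess import RatioTrack
from .targets_io import InputError

__all__ = [
    "WaveletDecomposition",
    "SmoothingConfig",
    "haar_dwt",
    "inverse_haar_dwt",
    "estimate_noise_sigma",
    "sure_threshold",
    "soft_threshold",
    "smooth_signal",
    "smooth_track",
]

#: coefficient of the MAD-to-sigma conversion for Gaussian noise
MAD_GAUSS = 0.6745

#: chromosomes shorter than this are passed through unsmoothed
MIN_SMOOTH_LEN = 4

#: default cap on decomposition depth; deeper levels on exome-sized
#: chromosomes carry too few coefficients for a stable SURE minimum
MAX_LEVELS = 6


@dataclass
class WaveletDecomposition:
    """Orthonormal Haar decomposition of one (padded) chromosome signal."""

    approx: np.ndarray
    details: list[np.ndarray]  # coarsest first, finest last
    original_length: int
    padded_length: int
    pad_spec: str = "reflect-right"

    @property
    def levels(self) -> int:
        return len(self.details)


@dataclass
class SmoothingConfig:
    """Knobs of the denoising stage (wavelet family and rule are fixed)."""

    wavelet: str = "haar"
    threshold_rule: str = "sure"
    threshold_mode: str = "soft"
    max_levels: int | None = None  # None = floor(log2 n) capped at MAX_LEVELS
    sigma_estimator: str = "mad"


def _pad_to_dyadic(signal: np.ndarray) -> np.ndarray:
    n = signal.size
    padded = 1 << max(0, (n - 1).bit_length())
    if padded == n:
        return signal
    # reflect the tail; numpy 'symmetric' repeats the edge sample, which keeps
    # the extension continuous for piecewise-constant signals
    return np.pad(signal, (0, padded - n), mode="symmetric")


def _auto_levels(n: int, max_levels: int | None) -> int:
    cap = MAX_LEVELS if max_levels is None else max_levels
    return max(1, min(int(np.floor(np.log2(n))), cap))


def haar_dwt(signal: np.ndarray, levels: int | None = None) -> WaveletDecomposition:
    """Orthonormal Haar DWT of ``signal`` after right-reflect dyadic padding."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2:
        raise InputError("signal must have length >= 2")
    padded = _pad_to_dyadic(signal)
    if levels is None:
        levels = _auto_levels(signal.size, None)
    max_possible = int(np.log2(padded.size))
    if not 1 <= levels <= max_possible:
        raise InputError(f"levels must be in [1, {max_possible}], got {levels}")
    coeffs = pywt.wavedec(padded, "haar", mode="periodization", level=levels)
    return WaveletDecomposition(
        approx=coeffs[0],
        details=list(coeffs[1:]),
        original_length=signal.size,
        padded_length=padded.size,
    )


def inverse_haar_dwt(dec: WaveletDecomposition) -> np.ndarray:
    """Reconstruct the signal and crop the dyadic padding."""
    rec = pywt.waverec([dec.approx, *dec.details], "haar", mode="periodization")
    return rec[: dec.original_length]


def estimate_noise_sigma(finest_details: np.ndarray) -> float:
    """MAD noise-scale estimate median(|d|)/0.6745 from the finest details."""
    d = np.asarray(finest_details, dtype=float)
    if d.size == 0:
        raise InputError("empty detail vector")
    return float(np.median(np.abs(d)) / MAD_GAUSS)


def sure_threshold(details: np.ndarray, sigma_noise: float) -> float:
    """Soft threshold minimizing Stein's unbiased risk estimate.

    SURE(t) = n*sigma^2 - 2*sigma^2 * #{|d_i| <= t} + sum_i min(d_i^2, t^2),
    minimized over t in {0} union {|d_i|}.  Ties go to the smallest
    threshold (the one that shrinks least).
    """
    d = np.abs(np.asarray(details, dtype=float))
    n = d.size
    if n == 0:
        return 0.0
    if sigma_noise < 0:
        raise InputError("sigma_noise must be >= 0")
    a = np.sort(d)
    sq = np.concatenate([[0.0], np.cumsum(a**2)])
    cand = np.concatenate([[0.0], a])
    # rightmost insertion point = #{|d_i| <= t} for each candidate
    counts = np.searchsorted(a, cand, side="right")
    risks = (
        n * sigma_noise**2
        - 2.0 * sigma_noise**2 * counts
        + sq[counts]
        + (n - counts) * cand**2
    )
    best = np.flatnonzero(risks == risks.min())
    return float(cand[best].min())


def soft_threshold(coeffs: np.ndarray, t: float) -> np.ndarray:
    """Shrink towards zero: sign(c) * max(|c| - t, 0)."""
    if t < 0:
        raise InputError("threshold must be >= 0")
    c = np.asarray(coeffs, dtype=float)
    return np.sign(c) * np.maximum(np.abs(c) - t, 0.0)


def smooth_signal(signal: np.ndarray, config: SmoothingConfig | None = None) -> np.ndarray:
    """Denoise one chromosome's ratio vector; length < MIN_SMOOTH_LEN passes through."""
    config = config or SmoothingConfig()
    signal = np.asarray(signal, dtype=float)
    if signal.size < MIN_SMOOTH_LEN:
        return signal.copy()
    levels = _auto_levels(signal.size, config.max_levels)
    dec = haar_dwt(signal, levels)
    sigma = estimate_noise_sigma(dec.details[-1])
    dec.details = [
        soft_threshold(d, sure_threshold(d, sigma)) for d in dec.details
    ]
    return np.clip(inverse_haar_dwt(dec), 0.0, None)


def smooth_track(track: RatioTrack, config: SmoothingConfig | None = None) -> RatioTrack:
    """Per-chromosome Haar/SURE denoising of a median-normalized ratio track."""
    if track.stage != "median_normalized":
        raise InputError(f"smooth_track expects a median_normalized track, got {track.stage}")
    out = np.empty_like(track.values)
    for sl in track.chrom_index.values():
        out[sl] = smooth_signal(track.values[sl], config)
    return track.with_values(out, stage="smoothed")
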