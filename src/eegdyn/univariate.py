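"""Per-channel variability metrics: power spectrum, multiscale SD, MSE, MSEn.

Multiscale entropy (MSE) is sample entropy computed on progressively
coarse-grained (non-overlapping block-averaged) copies of the signal, with
the tolerance r fixed as a fraction of the scale-1 SD. MSEn instead re-derives
r from each coarse scale's own SD — equivalent to z-scoring every coarse
series — which removes the confound of SD shrinking with coarse-graining and
focuses the metric on temporal structure rather than amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import Segment

logger = logging.getLogger(__name__)


@dataclass
class SpectrumTable:
    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # (n_channels, n_freqs), uV^2/Hz
    channel_labels: tuple[str, ...] = ()
    settings: dict | None = None


@dataclass
class MultiscaleCurve:
    scales_s: np.ndarray  # seconds (coarse factor / rate), strictly increasing
    values: np.ndarray  # (n_channels, n_scales); NaN = undefined
    metric: str  # "sigma" | "MSE" | "MSEn"
    scale_factors: np.ndarray | None = None
    channel_labels: tuple[str, ...] = ()


@dataclass
class EntropyParams:
    """Sample-entropy settings: template length m and tolerance fraction r."""

    m: int = 2
    r_frac: float = 0.5
    r_mode: str = "scale1_sd"  # "scale1_sd" (MSE) | "per_scale_sd" (MSEn)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("template length m must be >= 1")
        if self.r_frac <= 0:
            raise ValueError("tolerance fraction must be positive")
        if self.r_mode not in ("scale1_sd", "per_scale_sd"):
            raise ValueError(f"unknown r_mode {self.r_mode!r}")


def power_spectrum(seg: Segment, window_s: float = 1.0, overlap: float = 0.5,
                   window: str = "hann") -> SpectrumTable:
    """Welch power spectral density per channel (averaged modified periodograms).

    Defaults: 1-s Hann windows with 50% overlap, giving a 1-Hz frequency grid.
    """
    nperseg = int(round(window_s * seg.rate))
    if nperseg > seg.n_samples // 2:
        raise ValueError(
            f"estimator window of {nperseg} samples needs a segment of at "
            f"least {2 * nperseg} samples"
        )
    freqs, power = signal.welch(
        seg.samples, fs=seg.rate, window=window, nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), axis=1, detrend=False,
    )
    return SpectrumTable(
        freqs=freqs, power=power, channel_labels=seg.channel_labels,
        settings={"window_s": window_s, "overlap": overlap, "window": window},
    )


def coarse_grain(x: np.ndarray, scale_factor: int) -> np.ndarray:
    """Non-overlapping block average with block length ``scale_factor``."""
    x = np.asarray(x, dtype=float)
    s = int(scale_factor)
    if s < 1:
        raise ValueError("scale factor must be >= 1")
    if s > x.size:
        raise ValueError(f"scale factor {s} exceeds series length {x.size}")
    n = x.size // s
    return x[: n * s].reshape(n, s).mean(axis=1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   r_frac: float = 0.5) -> float:
    """SampEn(m, r) = -ln(A/B) with Chebyshev template matching.

    B counts pairs of length-m templates within tolerance r (self-matches
    excluded), A the same for length m+1. ``r`` defaults to
    ``r_frac * SD(x)``. Returns NaN (and logs) when A or B is zero — the
    statistic is undefined there, never silently substituted.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series length {n} too short for m={m}")
    if r is None:
        r = r_frac * x.std()
    if r <= 0:
        logger.warning("sample_entropy: nonpositive tolerance (constant "
                       "series?); undefined")
        return float("nan")
    # both counts use the same n - m templates (Richman-Moorman convention),
    # so a constant series gives A/B = 1 and SampEn = 0 exactly
    B = _template_matches(x, m, r, n_templates=n - m)
    A = _template_matches(x, m + 1, r)
    if B == 0 or A == 0:
        logger.warning("sample_entropy: no template matches (A=%d, B=%d); "
                       "undefined", A, B)
        return float("nan")
    return float(-np.log(A / B))


def _template_matches(x: np.ndarray, length: int, r: float,
                      n_templates: int | None = None) -> int:
    """Number of template pairs (i < j) within Chebyshev distance r."""
    from numpy.lib.stride_tricks import sliding_window_view
    from scipy.spatial.distance import pdist

    templates = sliding_window_view(x, length)
    if n_templates is not None:
        templates = templates[:n_templates]
    if templates.shape[0] < 2:
        return 0
    return int(np.count_nonzero(pdist(templates, metric="chebyshev") <= r))


def multiscale_std(seg: Segment, scale_factors=range(1, 26)) -> MultiscaleCurve:
    """SD of the coarse-grained series per channel and scale."""
    factors = np.asarray(list(scale_factors), dtype=int)
    values = np.empty((seg.n_channels, factors.size))
    for ch in range(seg.n_channels):
        for si, s in enumerate(factors):
            values[ch, si] = coarse_grain(seg.samples[ch], s).std(ddof=0)
    return MultiscaleCurve(
        scales_s=factors / seg.rate, values=values, metric="sigma",
        scale_factors=factors, channel_labels=seg.channel_labels,
    )


def multiscale_entropy(
    seg: Segment,
    scale_factors=range(1, 26),
    params: EntropyParams | None = None,
) -> MultiscaleCurve:
    """Sample entropy of coarse-grained series per channel and scale.

    ``params.r_mode`` picks the tolerance convention: "scale1_sd" fixes
    r = r_frac * SD(raw series) at every scale (MSE); "per_scale_sd" re-derives
    r from the coarse series' own SD (MSEn). Undefined cells are NaN.
    """
    params = params or EntropyParams()
    factors = np.asarray(list(scale_factors), dtype=int)
    largest = factors.max()
    min_coarse = seg.n_samples // largest
    if min_coarse < 10 * (params.m + 1):
        raise ValueError(
            f"largest scale {largest} leaves only {min_coarse} coarse samples; "
            f"need >= {10 * (params.m + 1)}"
        )
    values = np.full((seg.n_channels, factors.size), np.nan)
    for ch in range(seg.n_channels):
        x = seg.samples[ch]
        r1 = params.r_frac * x.std()
        for si, s in enumerate(factors):
            coarse = coarse_grain(x, s)
            if params.r_mode == "scale1_sd":
                r = r1
            else:
                r = params.r_frac * coarse.std()
            if r <= 0:
                logger.warning("multiscale_entropy: zero tolerance at scale %d "
                               "(channel %d); flagged", s, ch)
                continue
            values[ch, si] = sample_entropy(coarse, m=params.m, r=r)
    metric = "MSE" if params.r_mode == "scale1_sd" else "MSEn"
    return MultiscaleCurve(
        scales_s=factors / seg.rate, values=values, metric=metric,
        scale_factors=factors, channel_labels=seg.channel_labels,
    )
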