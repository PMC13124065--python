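"""Morlet phase extraction and sliding-window circular-correlation networks.

The functional-connectivity measure is the circular correlation coefficient
(CCorr) between the instantaneous phases of two channels within a short
sliding window:

    CCorr = sum sin(phi_i - phibar_i) sin(phi_j - phibar_j)
            / sqrt( sum sin^2(phi_i - phibar_i) sum sin^2(phi_j - phibar_j) )

with phibar the sample mean of the wrapped phase inside the window. CCorr is
1 for perfect in-phase coupling, -1 for antiphase, and near 0 for
unsynchronized signals. Collecting CCorr for all channel pairs at every
window center yields a per-frequency "network movie" (SyncSeries); its
quadratic-mean norm |PS(t,f)| summarizes overall synchronization strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import Segment

logger = logging.getLogger(__name__)

DEFAULT_FREQS = tuple(float(f) for f in range(2, 21, 2))  # 2..20 Hz, 10 bins


@dataclass
class WaveletConfig:
    """Complex Morlet wavelet settings.

    ``cycles`` fixes the time/frequency trade-off: sigma_t = cycles/(2 pi f)
    and sigma_f = f/cycles, so sigma_t * sigma_f = 1/(2 pi) at every center
    frequency. Amplitude normalization is chosen so a unit-amplitude sinusoid
    at the center frequency yields unit coefficient magnitude.
    """

    freqs: tuple[float, ...] = DEFAULT_FREQS
    cycles: float = 7.0
    support_sigmas: float = 5.0  # kernel half-length in units of sigma_t

    def __post_init__(self) -> None:
        self.freqs = tuple(float(f) for f in self.freqs)
        if any(f <= 0 for f in self.freqs):
            raise ValueError("center frequencies must be positive")
        if self.cycles <= 0:
            raise ValueError("cycle number must be positive")

    def sigma_t(self, f: float) -> float:
        return self.cycles / (2.0 * np.pi * f)

    def sigma_f(self, f: float) -> float:
        return f / self.cycles


@dataclass
class TFPhase:
    """Instantaneous phase per channel x frequency x sample, wrapped to (-pi, pi]."""

    phase: np.ndarray  # (n_channels, n_freqs, n_samples)
    freqs: tuple[float, ...]
    rate: float
    channel_labels: tuple[str, ...] = ()
    coefficients: np.ndarray | None = None  # optional complex WT

    @property
    def n_channels(self) -> int:
        return self.phase.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phase.shape[2]


@dataclass
class SyncSeries:
    """CCorr values per connection and window center, one slab per frequency."""

    values: np.ndarray  # (n_freqs, n_connections, n_windows); NaN = undefined
    freqs: tuple[float, ...]
    window_centers: np.ndarray  # sample indices of window centers
    rate: float
    window_samples: int
    step_samples: int
    pairs: tuple[tuple[int, int], ...]  # connection index -> (i, j)
    channel_labels: tuple[str, ...] = ()
    segment_duration: float | None = None

    @property
    def n_connections(self) -> int:
        return self.values.shape[1]

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]

    @property
    def center_times(self) -> np.ndarray:
        return self.window_centers / self.rate


def morlet_kernel(f: float, rate: float, cfg: WaveletConfig) -> np.ndarray:
    """Complex Morlet kernel at center frequency ``f``, unit sinusoid gain."""
    sigma_t = cfg.sigma_t(f)
    half = int(np.ceil(cfg.support_sigmas * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    envelope = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = envelope * np.exp(2j * np.pi * f * t)
    # a_f: unit-amplitude cosine at f -> unit coefficient magnitude
    return kernel * (2.0 / envelope.sum())


def morlet_phase(seg: Segment, cfg: WaveletConfig | None = None,
                 keep_coefficients: bool = False) -> TFPhase:
    """Instantaneous phase of each channel at each wavelet center frequency.

    Convolution runs in the frequency domain with zero padding; coefficients
    within one kernel half-length of either edge are contaminated and should
    be excluded downstream (the jump-length trimming does this).
    """
    cfg = cfg or WaveletConfig()
    x = np.asarray(seg.samples, dtype=float)
    n_ch, n_t = x.shape
    lowest = min(cfg.freqs)
    support = 2 * int(np.ceil(cfg.support_sigmas * cfg.sigma_t(lowest) * seg.rate)) + 1
    if support > n_t:
        raise ValueError(
            f"wavelet support {support} samples at {lowest} Hz exceeds "
            f"segment length {n_t}"
        )
    coeffs = np.empty((n_ch, len(cfg.freqs), n_t), dtype=complex)
    for fi, f in enumerate(cfg.freqs):
        kernel = morlet_kernel(f, seg.rate, cfg)
        half = (len(kernel) - 1) // 2
        n_fft = int(2 ** np.ceil(np.log2(n_t + len(kernel) - 1)))
        xf = np.fft.fft(x, n_fft, axis=1)
        kf = np.fft.fft(kernel, n_fft)
        conv = np.fft.ifft(xf * kf[None, :], axis=1)
        coeffs[:, fi, :] = conv[:, half : half + n_t]
    return TFPhase(
        phase=np.angle(coeffs),
        freqs=cfg.freqs,
        rate=seg.rate,
        channel_labels=seg.channel_labels,
        coefficients=coeffs if keep_coefficients else None,
    )


def ccorr(phi_i: np.ndarray, phi_j: np.ndarray, phase_mean: str = "arithmetic") -> float:
    """Circular correlation of two equal-length phase windows.

    ``phase_mean`` selects the deviation reference: "arithmetic" (sample mean
    of the wrapped phase, the printed-formula convention and the default) or
    "circular" (argument of the mean resultant vector).

    Returns NaN for a degenerate window (zero sine-deviation energy), which
    callers must treat as flagged-undefined.
    """
    phi_i = np.asarray(phi_i, dtype=float)
    phi_j = np.asarray(phi_j, dtype=float)
    if phi_i.shape != phi_j.shape or phi_i.ndim != 1 or phi_i.size < 3:
        raise ValueError("phase windows must be equal-length 1-D arrays, n >= 3")
    si = np.sin(phi_i - _phase_reference(phi_i, phase_mean))
    sj = np.sin(phi_j - _phase_reference(phi_j, phase_mean))
    denom = np.sqrt((si**2).sum() * (sj**2).sum())
    if denom == 0.0:
        return float("nan")
    return float((si * sj).sum() / denom)


def _phase_reference(phi: np.ndarray, mode: str) -> float:
    if mode == "arithmetic":
        return float(phi.mean())
    if mode == "circular":
        return float(np.angle(np.exp(1j * phi).mean()))
    raise ValueError(f"unknown phase_mean mode {mode!r}")


def connection_pairs(n_channels: int) -> tuple[tuple[int, int], ...]:
    """Unordered channel pairs in row-major upper-triangle order."""
    return tuple(
        (i, j) for i in range(n_channels) for j in range(i + 1, n_channels)
    )


def sliding_sync(
    tf: TFPhase,
    window_samples: int = 251,
    step_samples: int = 1,
    phase_mean: str = "arithmetic",
    segment_duration: float | None = None,
) -> SyncSeries:
    """CCorr for every channel pair at every sliding-window position.

    Windows start at ``c - window_samples//2`` for center ``c``; for the
    default odd 251-sample window this is the symmetric c-125..c+125 span.
    Degenerate windows yield NaN entries (logged once).

    The inner loop is an algebraic expansion of the CCorr sums: with
    s = sin(phi), c = cos(phi), sin(phi - phibar) = s*cos(phibar) -
    c*sin(phibar), so every windowed sum reduces to sliding sums of s, c and
    their pairwise products, computed with cumulative sums.
    """
    L = int(window_samples)
    step = int(step_samples)
    n_ch, n_freq, n_t = tf.phase.shape
    if L > n_t:
        raise ValueError("window longer than segment")
    if step < 1:
        raise ValueError("step must be >= 1")
    if phase_mean != "arithmetic":
        return _sliding_sync_direct(tf, L, step, phase_mean, segment_duration)

    half = L // 2
    starts = np.arange(0, n_t - L + 1, step)
    centers = starts + half
    pairs = connection_pairs(n_ch)
    pair_i = np.array([p[0] for p in pairs])
    pair_j = np.array([p[1] for p in pairs])
    n_con = len(pairs)
    n_win = len(starts)
    out = np.empty((n_freq, n_con, n_win), dtype=float)
    degenerate = 0

    def win_sum(arr: np.ndarray) -> np.ndarray:
        # sliding sums over length-L windows at `starts`, along last axis
        cs = np.cumsum(arr, axis=-1, dtype=float)
        cs = np.concatenate([np.zeros(arr.shape[:-1] + (1,)), cs], axis=-1)
        return cs[..., starts + L] - cs[..., starts]

    for fi in range(n_freq):
        phi = tf.phase[:, fi, :]
        s, c = np.sin(phi), np.cos(phi)
        mu = win_sum(phi) / L  # (n_ch, n_win) window phase means
        cm, sm = np.cos(mu), np.sin(mu)
        # per-channel window sums
        S, C = win_sum(s), win_sum(c)
        SS, CC, SC = win_sum(s * s), win_sum(c * c), win_sum(s * c)
        # sum sin^2(phi - mu) per channel/window
        energy = cm**2 * SS + sm**2 * CC - 2 * cm * sm * SC
        energy = np.maximum(energy, 0.0)  # guard rounding of the quadratic form
        # pairwise cross sums
        si, sj = s[pair_i], s[pair_j]
        ci, cj = c[pair_i], c[pair_j]
        SiSj = win_sum(si * sj)
        SiCj = win_sum(si * cj)
        CiSj = win_sum(ci * sj)
        CiCj = win_sum(ci * cj)
        cmi, smi = cm[pair_i], sm[pair_i]
        cmj, smj = cm[pair_j], sm[pair_j]
        num = (
            cmi * cmj * SiSj
            - cmi * smj * SiCj
            - smi * cmj * CiSj
            + smi * smj * CiCj
        )
        denom = np.sqrt(energy[pair_i] * energy[pair_j])
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
        degenerate += int(np.isnan(vals).sum())
        out[fi] = np.clip(vals, -1.0, 1.0)

    if degenerate:
        logger.info("sliding_sync: %d degenerate (constant-phase) windows flagged",
                    degenerate)
    return SyncSeries(
        values=out,
        freqs=tf.freqs,
        window_centers=centers,
        rate=tf.rate,
        window_samples=L,
        step_samples=step,
        pairs=pairs,
        channel_labels=tf.channel_labels,
        segment_duration=segment_duration if segment_duration is not None
        else n_t / tf.rate,
    )


def _sliding_sync_direct(tf: TFPhase, L: int, step: int, phase_mean: str,
                         segment_duration: float | None) -> SyncSeries:
    """Window-by-window fallback used for the circular-mean convention."""
    n_ch, n_freq, n_t = tf.phase.shape
    half = L // 2
    starts = np.arange(0, n_t - L + 1, step)
    centers = starts + half
    pairs = connection_pairs(n_ch)
    out = np.empty((n_freq, len(pairs), len(starts)), dtype=float)
    for fi in range(n_freq):
        for wi, st in enumerate(starts):
            win = tf.phase[:, fi, st : st + L]
            refs = np.array([_phase_reference(win[ch], phase_mean)
                             for ch in range(n_ch)])
            dev = np.sin(win - refs[:, None])
            energy = (dev**2).sum(axis=1)
            for ki, (i, j) in enumerate(pairs):
                denom = np.sqrt(energy[i] * energy[j])
                out[fi, ki, wi] = (dev[i] * dev[j]).sum() / denom if denom > 0 else np.nan
    return SyncSeries(
        values=out, freqs=tf.freqs, window_centers=centers, rate=tf.rate,
        window_samples=L, step_samples=step, pairs=pairs,
        channel_labels=tf.channel_labels,
        segment_duration=segment_duration if segment_duration is not None
        else n_t / tf.rate,
    )


def phases_to_sync(
    phases: np.ndarray,
    rate: float,
    window_samples: int,
    step_samples: int,
    freq_label: float = 10.0,
) -> SyncSeries:
    """Sliding CCorr directly on given phase time series (channels x samples).

    Used by the oscillator-model pipeline, where phases are state variables
    and no wavelet transform is involved.
    """
    phases = np.asarray(phases, dtype=float)
    tf = TFPhase(
        phase=np.angle(np.exp(1j * phases))[:, None, :],
        freqs=(freq_label,),
        rate=rate,
    )
    return sliding_sync(tf, window_samples, step_samples)


def ps_norm_series(ss: SyncSeries, max_undefined_frac: float = 0.05) -> np.ndarray:
    """Normalized Euclidean norm |PS(t,f)| per frequency and window.

    |PS| = sqrt(mean_k CCorr_k^2) over connections; a window with more than
    ``max_undefined_frac`` flagged connections is itself flagged (NaN).
    """
    vals = ss.values
    bad = np.isnan(vals)
    bad_frac = bad.mean(axis=1)  # (n_freqs, n_windows)
    with np.errstate(invalid="ignore"):
        norm = np.sqrt(np.nanmean(vals**2, axis=1))
    norm[bad_frac > max_undefined_frac] = np.nan
    return norm


def ps_norm_stats(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Time mean and sample SD of |PS(t,f)| per frequency, skipping flags."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_ok = np.sum(~np.isnan(series), axis=1)
    if np.any(n_ok < 2):
        logger.warning("ps_norm_stats: fewer than 2 unflagged windows at some "
                       "frequency; stats undefined there")
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(series, axis=1)
        sd = np.nanstd(series, axis=1, ddof=1)
    mu = np.where(n_ok >= 2, mu, np.nan)
    sd = np.where(n_ok >= 2, sd, np.nan)
    return mu, sd
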