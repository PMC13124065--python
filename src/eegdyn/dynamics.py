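"""Switching dynamics of phase-synchronization networks.

Treating the connection vector PS(t,f) at each sliding-window center as a
point in N_con-dimensional network space, the correlation distance

    D(t1, t2) = 1 - corr(PS(t1,f), PS(t2,f))

between every pair of window centers quantifies how much network *topology*
(not magnitude) reconfigured between the two times. The tau-th diagonal of
D is the sequence of "jump lengths" JL(tau,f) — how far the network walked
in topology space over lag tau. Their mean quantifies switching speed, their
SD its heterogeneity, and their Pearson kurtosis (normal -> 3) flags
leptokurtic, switching-like dynamics in which very small and very large
jumps are both over-represented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phase import SyncSeries

logger = logging.getLogger(__name__)


@dataclass
class PSDMatrix:
    """Per-frequency window x window correlation-distance matrix."""

    distances: np.ndarray  # (n_freqs, n_windows, n_windows); NaN = undefined
    freqs: tuple[float, ...]
    center_times: np.ndarray  # seconds
    segment_duration: float

    @property
    def n_windows(self) -> int:
        return self.distances.shape[1]

    @property
    def step_s(self) -> float:
        if len(self.center_times) < 2:
            return float("nan")
        return float(self.center_times[1] - self.center_times[0])


@dataclass
class JLGrid:
    """Jump-length statistics over a timescale x frequency grid."""

    taus: np.ndarray  # seconds
    freqs: tuple[float, ...]
    mean: np.ndarray  # (n_taus, n_freqs)
    sd: np.ndarray
    kurtosis: np.ndarray
    counts: np.ndarray  # contributing pairs per cell

    def to_frame(self) -> pd.DataFrame:
        """Tidy (frequency, tau, stat, value) table."""
        rows = []
        for ti, tau in enumerate(self.taus):
            for fi, f in enumerate(self.freqs):
                for stat, arr in (("mu_jl", self.mean), ("sigma_jl", self.sd),
                                  ("k_jl", self.kurtosis)):
                    rows.append((f, float(tau), stat, arr[ti, fi]))
        return pd.DataFrame(rows, columns=["frequency", "tau", "stat", "value"])


def psd_matrix(ss: SyncSeries) -> PSDMatrix:
    """Correlation distance between synchronization networks at all window pairs.

    The correlation runs across connections, so D is invariant to positive
    affine rescaling of a network vector. Windows whose network vector is
    constant (zero variance across connections) or contains flagged values
    are themselves flagged: their row/column is NaN.
    """
    n_freq, n_con, n_win = ss.values.shape
    if n_win < 2:
        raise ValueError("need at least 2 windows for a distance matrix")
    out = np.empty((n_freq, n_win, n_win), dtype=float)
    for fi in range(n_freq):
        X = ss.values[fi].T  # (n_windows, n_connections)
        bad = np.isnan(X).any(axis=1)
        sd = np.nanstd(X, axis=1)
        bad |= sd < 1e-12
        if bad.any():
            logger.info("psd_matrix: %d window(s) flagged (constant or undefined "
                        "network vector) at %g Hz", int(bad.sum()), ss.freqs[fi])
        Xc = X - np.nanmean(X, axis=1, keepdims=True)
        norm = np.sqrt((Xc**2).sum(axis=1))
        norm_safe = np.where(norm > 0, norm, 1.0)
        Xn = Xc / norm_safe[:, None]
        D = 1.0 - Xn @ Xn.T
        D[bad, :] = np.nan
        D[:, bad] = np.nan
        ok = ~bad
        D[np.ix_(ok, ok)] = np.clip(D[np.ix_(ok, ok)], 0.0, 2.0)
        np.fill_diagonal(D, np.where(ok, 0.0, np.nan))
        out[fi] = D
    return PSDMatrix(
        distances=out,
        freqs=ss.freqs,
        center_times=ss.center_times,
        segment_duration=float(ss.segment_duration
                               if ss.segment_duration is not None
                               else ss.center_times[-1]),
    )


def jump_lengths(
    psd: PSDMatrix,
    tau: float,
    freq_index: int = 0,
    edge_margin_s: float = 0.5,
    trim: str = "edge-margin",
) -> np.ndarray:
    """The tau-diagonal of the distance matrix, time-ordered and edge-trimmed.

    ``tau`` must sit on the window-center lag grid. Trimming modes:

    - "edge-margin" (default): keep pairs whose window centers both lie at
      least ``edge_margin_s`` from the segment boundaries — the geometric
      reading of the conventional [0.5*tau + step, T - 0.5] s restriction.
    - "literal": keep pairs whose *earlier* center t satisfies
      0.5*tau + step <= t <= T - 0.5, the printed-range convention.
    - "none": whole diagonal.
    """
    step = psd.step_s
    offset = tau / step
    k = int(round(offset))
    if abs(offset - k) > 1e-6 or k < 1:
        raise ValueError(f"tau={tau} s is not a positive multiple of the "
                         f"window-center step {step} s")
    D = psd.distances[freq_index]
    n = D.shape[0]
    if k >= n:
        return np.empty(0)
    t_early = psd.center_times[: n - k]
    t_late = psd.center_times[k:]
    diag = D[np.arange(n - k), np.arange(k, n)]
    T = psd.segment_duration
    if trim == "edge-margin":
        keep = (t_early >= edge_margin_s) & (t_late <= T - edge_margin_s)
    elif trim == "literal":
        keep = (t_early >= 0.5 * tau + step - 1e-9) & (t_early <= T - 0.5 + 1e-9)
    elif trim == "none":
        keep = np.ones(n - k, dtype=bool)
    else:
        raise ValueError(f"unknown trim mode {trim!r}")
    return diag[keep]


def jl_stats(jl: np.ndarray) -> tuple[float, float, float]:
    """Sample mean, sample SD, and Pearson kurtosis of a jump-length sequence.

    Kurtosis is the non-excess m4/m2^2 with population central moments
    (normal -> 3); it is NaN for a constant sequence (m2 = 0), and SD uses
    the n-1 denominator. Flagged (NaN) jumps are excluded.
    """
    jl = np.asarray(jl, dtype=float)
    jl = jl[~np.isnan(jl)]
    if jl.size < 4:
        return (float(np.mean(jl)) if jl.size else float("nan"),
                float(np.std(jl, ddof=1)) if jl.size >= 2 else float("nan"),
                float("nan"))
    mu = jl.mean()
    dev = jl - mu
    m2 = (dev**2).mean()
    if m2 == 0.0:
        return float(mu), 0.0, float("nan")
    m4 = (dev**4).mean()
    return float(mu), float(jl.std(ddof=1)), float(m4 / m2**2)


def default_tau_grid(step_s: float = 0.004, tau_min: float = 1.004,
                     tau_max: float = 2.0) -> np.ndarray:
    """Timescale grid tau_min..tau_max in steps of the window-center step."""
    n = int(round((tau_max - tau_min) / step_s)) + 1
    return tau_min + step_s * np.arange(n)


def snapped_tau_grid(step_s: float, tau_min: float = 1.004,
                     tau_max: float = 2.0) -> np.ndarray:
    """Tau grid snapped onto multiples of the window-center step.

    At the fully overlapping EEG step (4 ms at 250 Hz) this is the
    1.004..2.000 s grid (250 timescales); at the 100-ms simulation step it is
    1.0..2.0 s (11 timescales).
    """
    k0 = max(1, int(round(tau_min / step_s)))
    k1 = int(np.floor(tau_max / step_s + 1e-9))
    if k1 < k0:
        raise ValueError("tau range contains no multiple of the step")
    return step_s * np.arange(k0, k1 + 1)


def jl_grid(
    psd: PSDMatrix,
    taus: np.ndarray | None = None,
    edge_margin_s: float = 0.5,
    trim: str = "edge-margin",
) -> JLGrid:
    """Jump-length statistics for every (tau, frequency) cell."""
    if taus is None:
        taus = snapped_tau_grid(psd.step_s)
    taus = np.asarray(taus, dtype=float)
    n_f = len(psd.freqs)
    shape = (len(taus), n_f)
    mean = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    kurt = np.full(shape, np.nan)
    counts = np.zeros(shape, dtype=int)
    for ti, tau in enumerate(taus):
        for fi in range(n_f):
            jl = jump_lengths(psd, tau, freq_index=fi,
                              edge_margin_s=edge_margin_s, trim=trim)
            counts[ti, fi] = jl[~np.isnan(jl)].size
            if counts[ti, fi] == 0:
                continue
            mean[ti, fi], sd[ti, fi], kurt[ti, fi] = jl_stats(jl)
    return JLGrid(taus=taus, freqs=psd.freqs, mean=mean, sd=sd,
                  kurtosis=kurt, counts=counts)
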