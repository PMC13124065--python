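"""Seeded synthetic EEG cohorts with controllable network-switching structure.

The generator emulates the statistical regime the analysis pipeline assumes:
multichannel band-limited oscillations (2-20 Hz) over a 1/f background, whose
pairwise phase coupling follows one of a small set of latent coupling
topologies that alternate at gamma-distributed dwell times. Channels that are
coupled under the active topology share a common latent phase process (one
per connected component of the coupling graph) plus a state-specific phase
offset; uncoupled channels carry independent phase noise. Switching the
active topology therefore reconfigures the sliding-window CCorr network, so
downstream correlation-distance dynamics see a switching "network movie"
whose tempo (dwell mean) and heterogeneity (dwell CV) are planted knobs, as
is a per-group gain on the slow-band (2-8 Hz) oscillation amplitudes.

What it does not emulate: volume conduction, electrode geometry, evoked
responses, or any biophysical forward model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Segment, StudyDesign

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = ("YC", "OC", "YA", "OA")
DEFAULT_CONDITIONS = ("REC", "UOT", "AOT")
SLOW_BAND = (2.0, 8.0)


@dataclass
class SynthSpec:
    """Study-generator settings; defaults mirror a 4-group x 3-condition cohort."""

    n_groups: int = 4
    n_conditions: int = 3
    subjects_per_group: int = 24
    segments_range: tuple[int, int] = (5, 25)
    n_channels: int = 19
    rate: float = 250.0
    segment_length_s: float = 10.0
    freqs: tuple[float, ...] = (4.0, 10.0)
    n_states: int = 3
    # planted per-group effects (length n_groups each; None = all equal)
    slow_gain: tuple[float, ...] | None = None
    dwell_mean_s: tuple[float, ...] | None = None
    dwell_cv: tuple[float, ...] | None = None
    noise_1f_exponent: float = 1.0
    snr: float = 3.0
    seed: int = 0
    group_labels: tuple[str, ...] | None = None
    condition_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("n_groups", "n_conditions", "subjects_per_group",
                     "n_channels", "n_states"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.segments_range[0] < 1 or self.segments_range[1] < self.segments_range[0]:
            raise ValueError("segments_range must be a nondecreasing pair >= 1")
        if self.slow_gain is None:
            self.slow_gain = (1.0,) * self.n_groups
        if self.dwell_mean_s is None:
            self.dwell_mean_s = (1.0,) * self.n_groups
        if self.dwell_cv is None:
            self.dwell_cv = (0.5,) * self.n_groups
        for name in ("slow_gain", "dwell_mean_s", "dwell_cv"):
            if len(getattr(self, name)) != self.n_groups:
                raise ValueError(f"{name} needs one value per group")
        if any(g <= 0 for g in self.slow_gain):
            raise ValueError("slow-band gains must be positive")
        lowest = min(self.freqs)
        if any(d <= 2.0 / lowest for d in self.dwell_mean_s):
            raise ValueError(
                f"dwell means must exceed 2/lowest-frequency = {2.0 / lowest:.3g} s")
        if self.group_labels is None:
            self.group_labels = (DEFAULT_GROUPS[: self.n_groups]
                                 if self.n_groups <= len(DEFAULT_GROUPS)
                                 else tuple(f"G{i + 1}" for i in range(self.n_groups)))
        if self.condition_labels is None:
            self.condition_labels = (
                DEFAULT_CONDITIONS[: self.n_conditions]
                if self.n_conditions <= len(DEFAULT_CONDITIONS)
                else tuple(f"C{i + 1}" for i in range(self.n_conditions)))


@dataclass
class StudyDataset:
    """Design + segments per (subject, condition) + generation provenance."""

    design: StudyDesign
    segments: dict[tuple[str, str], list[Segment]]
    spec: SynthSpec | None = None
    provenance: dict = field(default_factory=dict)

    def iter_segments(self):
        for key, segs in self.segments.items():
            for seg in segs:
                yield key, seg


# ---------------------------------------------------------------------------
# topology helpers


def partition_topology(membership) -> np.ndarray:
    """Connection-weight vector (upper-triangle order): 1 within a module.

    ``membership`` assigns each channel to a module id; channels sharing a
    module are fully coupled, cross-module pairs uncoupled.
    """
    membership = np.asarray(membership)
    n = membership.size
    return np.array([
        1.0 if membership[i] == membership[j] else 0.0
        for i in range(n) for j in range(i + 1, n)
    ])


def random_partition_topologies(n_channels: int, n_states: int,
                                rng: np.random.Generator,
                                n_modules: int = 3) -> list[np.ndarray]:
    """Distinct random module partitions, one coupling topology per state."""
    topologies = []
    seen = set()
    while len(topologies) < n_states:
        membership = rng.integers(0, n_modules, size=n_channels)
        key = tuple(membership)
        if key in seen and len(seen) < 3**n_channels:
            continue
        seen.add(key)
        topologies.append(partition_topology(membership))
    return topologies


def _topology_components(weights: np.ndarray, n_channels: int,
                         threshold: float = 0.5) -> np.ndarray:
    """Connected-component labels of the thresholded coupling graph."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = np.zeros((n_channels, n_channels))
    k = 0
    for i in range(n_channels):
        for j in range(i + 1, n_channels):
            if weights[k] > threshold:
                adj[i, j] = adj[j, i] = 1.0
            k += 1
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


# ---------------------------------------------------------------------------
# segment generators


def gen_iid_gaussian_segment(n_channels: int, n_samples: int, rate: float,
                             seed: int | None = None, **meta) -> Segment:
    """Independent standard-normal channels, mean-centered; seeded."""
    if n_channels < 1 or n_samples < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_channels, n_samples))
    x -= x.mean(axis=1, keepdims=True)
    return Segment(x, rate, tuple(f"ch{i + 1:02d}" for i in range(n_channels)),
                   **meta)


def _ou_paths(n_paths: int, n: int, dt: float, tau: float, sigma: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck paths (exact discretization, AR(1))."""
    from scipy.signal import lfilter

    rho = np.exp(-dt / tau)
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    x0 = sigma * rng.standard_normal((n_paths, 1))
    noise = innov_sd * rng.standard_normal((n_paths, n - 1))
    driven = np.concatenate([x0, noise], axis=1)
    return lfilter([1.0], [1.0, -rho], driven, axis=1)


def _gamma_dwell_sequence(total_s: float, mean_s: float, cv: float,
                          n_states: int, rng: np.random.Generator
                          ) -> list[tuple[int, float]]:
    """(state, dwell seconds) runs covering ``total_s``; no immediate repeats."""
    runs = []
    t = 0.0
    state = int(rng.integers(n_states))
    while t < total_s:
        if cv <= 1e-6:
            dwell = mean_s
        else:
            shape = 1.0 / cv**2
            dwell = rng.gamma(shape, mean_s / shape)
        dwell = max(dwell, 1e-3)
        runs.append((state, dwell))
        t += dwell
        if n_states > 1:
            nxt = int(rng.integers(n_states - 1))
            state = nxt if nxt < state else nxt + 1
    return runs


def _one_over_f_noise(n_channels: int, n_samples: int, exponent: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent noise by spectral shaping of white noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping[None, :], n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    return shaped / np.where(sd > 0, sd, 1.0)


def gen_switching_segment(
    topologies,
    dwell_mean_s: float,
    dwell_cv: float = 0.5,
    freqs=(4.0, 10.0),
    noise_1f_exponent: float = 1.0,
    snr: float = 3.0,
    rate: float = 250.0,
    length_s: float = 10.0,
    seed: int | None = None,
    slow_gain: float = 1.0,
    jitter_sd: float = 0.4,
    jitter_tau_s: float = 0.25,
    channel_jitter_sd: float = 0.15,
    state_offsets: np.ndarray | None = None,
    **meta,
) -> Segment:
    """One multichannel segment whose phase coupling switches among topologies.

    Each topology is a connection-weight vector (upper-triangle order over
    channel pairs). While a topology is active, every connected component of
    its >0.5-threshold coupling graph shares one latent slow phase process
    and one state-specific phase offset; singleton channels drift
    independently. Dwell times are gamma(mean ``dwell_mean_s``, CV
    ``dwell_cv``). ``slow_gain`` multiplies amplitudes of components in the
    2-8 Hz band. ``snr`` is oscillation power over 1/f background power
    (np.inf disables the background). Deterministic given ``seed``.

    ``state_offsets`` (n_states x n_freqs x n_channels), if given, pins the
    state-specific phase offsets — used by the cohort generator so that all
    subjects express the same latent network states.
    """
    topologies = [np.asarray(t, dtype=float) for t in topologies]
    if len(topologies) < 1:
        raise ValueError("need at least one topology")
    n_con = topologies[0].size
    n_channels = int(round((1 + np.sqrt(1 + 8 * n_con)) / 2))
    if n_channels * (n_channels - 1) // 2 != n_con:
        raise ValueError(f"topology length {n_con} is not a triangular number")
    if any(t.size != n_con for t in topologies):
        raise ValueError("all topologies must have equal length")
    if dwell_mean_s >= length_s:
        raise ValueError("dwell_mean_s must be smaller than the segment length")

    rng = np.random.default_rng(seed)
    n_t = int(round(length_s * rate))
    dt = 1.0 / rate
    freqs = tuple(float(f) for f in freqs)
    n_states = len(topologies)

    components = [_topology_components(t, n_channels) for t in topologies]
    if state_offsets is None:
        state_offsets = _draw_state_offsets(components, freqs, rng)
    state_offsets = np.asarray(state_offsets, dtype=float)
    if state_offsets.shape != (n_states, len(freqs), n_channels):
        raise ValueError("state_offsets must be (n_states, n_freqs, n_channels)")

    runs = _gamma_dwell_sequence(length_s, dwell_mean_s, dwell_cv, n_states, rng)
    state_of_sample = np.empty(n_t, dtype=int)
    pos = 0
    for state, dwell in runs:
        n_run = min(int(round(dwell * rate)), n_t - pos)
        state_of_sample[pos : pos + n_run] = state
        pos += n_run
        if pos >= n_t:
            break
    if pos < n_t:
        state_of_sample[pos:] = runs[-1][0]

    x = np.zeros((n_channels, n_t))
    t_axis = np.arange(n_t) * dt
    for fi, f in enumerate(freqs):
        amp = slow_gain if SLOW_BAND[0] <= f <= SLOW_BAND[1] else 1.0
        # latent component processes: one OU phase path per (state, component)
        comp_paths = [
            _ou_paths(components[s].max() + 1, n_t, dt, jitter_tau_s,
                      jitter_sd, rng)
            for s in range(n_states)
        ]
        chan_noise = _ou_paths(n_channels, n_t, dt, jitter_tau_s,
                               channel_jitter_sd, rng)
        carrier = 2.0 * np.pi * f * t_axis
        phase = np.empty((n_channels, n_t))
        for s in range(n_states):
            mask = state_of_sample == s
            if not mask.any():
                continue
            comp = components[s]
            for c in range(n_channels):
                phase[c, mask] = (carrier[mask]
                                  + state_offsets[s, fi, c]
                                  + comp_paths[s][comp[c], mask]
                                  + chan_noise[c, mask])
        x += amp * np.cos(phase)

    if np.isfinite(snr):
        osc_power = x.var(axis=1, keepdims=True)
        noise = _one_over_f_noise(n_channels, n_t, noise_1f_exponent, rng)
        x = x + noise * np.sqrt(osc_power / snr)

    x -= x.mean(axis=1, keepdims=True)
    labels = tuple(f"ch{i + 1:02d}" for i in range(n_channels))
    return Segment(x, rate, labels, **meta)


def _draw_state_offsets(components, freqs, rng) -> np.ndarray:
    """State/frequency/channel phase offsets; shared within each component."""
    n_states = len(components)
    n_channels = components[0].size
    offsets = np.empty((n_states, len(freqs), n_channels))
    for s in range(n_states):
        comp = components[s]
        n_comp = comp.max() + 1
        for fi in range(len(freqs)):
            comp_offsets = rng.uniform(-np.pi, np.pi, size=n_comp)
            offsets[s, fi] = comp_offsets[comp]
    return offsets


# ---------------------------------------------------------------------------
# cohort generator


def gen_study(spec: SynthSpec) -> StudyDataset:
    """Full synthetic cohort with planted group effects, reproducible by seed."""
    root = np.random.SeedSequence(spec.seed)
    topo_seed, design_seed, segment_root = root.spawn(3)
    rng_topo = np.random.default_rng(topo_seed)
    topologies = random_partition_topologies(spec.n_channels, spec.n_states,
                                             rng_topo)
    components = [_topology_components(t, spec.n_channels) for t in topologies]
    state_offsets = _draw_state_offsets(components, spec.freqs, rng_topo)

    rng_design = np.random.default_rng(design_seed)
    rows = []
    segments: dict[tuple[str, str], list[Segment]] = {}
    seg_seeds = segment_root.generate_state(
        spec.n_groups * spec.subjects_per_group * spec.n_conditions * 64
    ) % (2**31)
    seed_i = 0
    for gi, group in enumerate(spec.group_labels):
        for si in range(spec.subjects_per_group):
            subject = f"{group}-{si + 1:03d}"
            for condition in spec.condition_labels:
                n_seg = int(rng_design.integers(spec.segments_range[0],
                                                spec.segments_range[1] + 1))
                segs = []
                for k in range(n_seg):
                    seg = gen_switching_segment(
                        topologies,
                        dwell_mean_s=spec.dwell_mean_s[gi],
                        dwell_cv=spec.dwell_cv[gi],
                        freqs=spec.freqs,
                        noise_1f_exponent=spec.noise_1f_exponent,
                        snr=spec.snr,
                        rate=spec.rate,
                        length_s=spec.segment_length_s,
                        seed=int(seg_seeds[seed_i]),
                        slow_gain=spec.slow_gain[gi],
                        state_offsets=state_offsets,
                        subject_id=subject,
                        group_label=group,
                        condition_label=condition,
                        segment_index=k,
                    )
                    seed_i += 1
                    segs.append(seg)
                rows.append({"subject": subject, "group": group,
                             "condition": condition})
                segments[(subject, condition)] = segs
    design = StudyDesign(pd.DataFrame(rows),
                         groups=spec.group_labels,
                         conditions=spec.condition_labels)
    return StudyDataset(
        design=design, segments=segments, spec=spec,
        provenance={"seed": spec.seed, "n_states": spec.n_states,
                    "freqs": spec.freqs},
    )
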