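"""Synthetic MEG-like data with planted ground truth.

Everything downstream (filtering, beamforming, statistics, parcellation) is
validated against datasets produced here, where the generating sources are
known exactly.  The design emulates a two-condition auditory recognition
experiment: five 250 ms tones per 1,250 ms sequence, a sustained slow
(0.1-1 Hz) "global" component that is stronger for the memorized condition
(M) in a deep "memory network" voxel set, and item-locked fast (2-8 Hz)
Gabor bursts that are stronger for the novel condition (N) in "auditory"
voxels.  Sensor noise is white Gaussian (optionally AR(1)).

The leadfield uses a Gaussian sensitivity profile rather than a physical
(Sarvas/Nolte) head model: channel sensitivity to a source decays smoothly
with source-sensor distance and the orientation structure comes from the
source-to-sensor direction vector.  This is deliberately non-physical; it is
sufficient to exercise the inverse linear algebra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

SEQUENCE_DURATION = 1.25  # s, five tones at 0, .25, .5, .75, 1.0
TONE_ONSETS = (0.0, 0.25, 0.5, 0.75, 1.0)

__all__ = [
    "SourceGrid",
    "SyntheticLeadfield",
    "ChannelLayout",
    "SensorDataset",
    "EffectSpec",
    "SimulationConfig",
    "GroundTruth",
    "make_grid",
    "make_sensor_sites",
    "make_channel_layout",
    "make_leadfield",
    "channel_leadfield",
    "simulate_evoked",
    "simulate_melodies",
    "slow_waveform",
    "fast_waveform",
]


# ---------------------------------------------------------------------------
# source grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceGrid:
    """Regular lattice of candidate dipole locations (MNI-like mm frame)."""

    coordinates: np.ndarray  # (n_sources, 3) mm
    spacing: float  # mm

    @property
    def n_sources(self) -> int:
        return self.coordinates.shape[0]

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3)")


def make_grid(
    box: tuple[float, float, float, float, float, float] = (-60, 60, -60, 60, -60, 60),
    spacing: float = 10.0,
    radii: tuple[float, float, float] | None = None,
) -> SourceGrid:
    """Regular lattice inside ``box`` restricted to an ellipsoidal brain mask.

    Parameters
    ----------
    box : (xmin, xmax, ymin, ymax, zmin, zmax) in mm.
    spacing : lattice step in mm.
    radii : ellipsoid semi-axes (mm), centered on the box center.  Defaults to
        the half-widths of the box (ellipsoid inscribed in the box).
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    lo = np.array(box[0::2], dtype=float)
    hi = np.array(box[1::2], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("degenerate box")
    center = 0.5 * (lo + hi)
    if radii is None:
        radii = tuple((hi - lo) / 2.0)
    axes = [np.arange(lo[i], hi[i] + 0.5 * spacing, spacing) for i in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    r = np.asarray(radii, dtype=float)
    inside = np.sum(((pts - center) / r) ** 2, axis=1) <= 1.0 + 1e-12
    pts = pts[inside]
    if pts.shape[0] == 0:
        raise ValueError("brain mask is empty for the requested box/spacing")
    return SourceGrid(coordinates=pts, spacing=float(spacing))


# ---------------------------------------------------------------------------
# sensors and leadfield
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelLayout:
    """Channel positions and roles.

    Gradiometer pairs are modelled as two channels sharing one sensor site
    (two noisy projections of the same field pattern), mirroring how paired
    planar gradiometers are handled downstream (RSS combination).
    """

    positions: np.ndarray       # (n_channels, 3) mm
    roles: tuple[str, ...]      # 'mag' | 'grad'
    grad_pairs: tuple[tuple[int, int], ...]
    names: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


def make_sensor_sites(n_sites: int, radius: float = 110.0) -> np.ndarray:
    """Deterministic quasi-uniform sites on a sphere (Fibonacci lattice)."""
    if n_sites < 2:
        raise ValueError("need at least 2 sensor sites")
    i = np.arange(n_sites)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_sites
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return radius * pts


def make_channel_layout(
    n_mag: int = 102, n_grad_pairs: int = 102, radius: float = 110.0
) -> ChannelLayout:
    sites = make_sensor_sites(max(n_mag, n_grad_pairs), radius=radius)
    positions, roles, names = [], [], []
    pairs = []
    for i in range(n_mag):
        positions.append(sites[i])
        roles.append("mag")
        names.append(f"MAG{i:03d}")
    for i in range(n_grad_pairs):
        a = len(positions)
        positions.append(sites[i])
        roles.append("grad")
        names.append(f"GRAD{i:03d}a")
        positions.append(sites[i])
        roles.append("grad")
        names.append(f"GRAD{i:03d}b")
        pairs.append((a, a + 1))
    return ChannelLayout(
        positions=np.array(positions),
        roles=tuple(roles),
        grad_pairs=tuple(pairs),
        names=tuple(names),
    )


@dataclass(frozen=True)
class SyntheticLeadfield:
    """Gaussian-profile leadfield: (sources, 3 orientations, sites)."""

    tensor: np.ndarray
    sigma: float  # mm, spatial scale of the sensitivity profile


def make_leadfield(
    grid: SourceGrid, sensor_positions: np.ndarray, sigma: float = 80.0
) -> SyntheticLeadfield:
    """Sensitivity of site c to source s, orientation o:
    ``u_o(s, c) * exp(-d(s, c)^2 / (2 sigma^2))`` where u is the unit
    source-to-sensor direction and d the distance.
    """
    sens = np.atleast_2d(np.asarray(sensor_positions, dtype=float))
    if sens.shape[0] < 2:
        raise ValueError("need at least 2 sensors")
    diff = sens[None, :, :] - grid.coordinates[:, None, :]  # (s, c, 3)
    d = np.linalg.norm(diff, axis=2)
    if np.any(d < 1e-9):
        raise ValueError("coincident sensor and source: singular geometry")
    u = diff / d[:, :, None]
    gain = np.exp(-(d**2) / (2.0 * sigma**2))
    tensor = np.transpose(u * gain[:, :, None], (0, 2, 1))  # (s, 3, c)
    if not np.all(np.isfinite(tensor)):
        raise ValueError("non-finite leadfield")
    return SyntheticLeadfield(tensor=tensor, sigma=float(sigma))


def channel_leadfield(lf: SyntheticLeadfield, layout: ChannelLayout) -> np.ndarray:
    """Expand a site-level leadfield to the channel list of a layout.

    Both members of a gradiometer pair map to their shared site; magnetometer
    channel i maps to site i.
    """
    n_sites = lf.tensor.shape[2]
    site_of_channel = []
    mag_i = 0
    grad_pair_site = {}
    for idx, role in enumerate(layout.roles):
        if role == "mag":
            site_of_channel.append(mag_i)
            mag_i += 1
        else:
            pair = next(p for p in layout.grad_pairs if idx in p)
            if pair not in grad_pair_site:
                grad_pair_site[pair] = len(grad_pair_site)
            site_of_channel.append(grad_pair_site[pair])
    site_of_channel = np.asarray(site_of_channel)
    if site_of_channel.max() >= n_sites:
        raise ValueError("layout requires more sites than the leadfield provides")
    return lf.tensor[:, :, site_of_channel]


# ---------------------------------------------------------------------------
# sensor dataset container
# ---------------------------------------------------------------------------

@dataclass
class SensorDataset:
    """Sensor-space recording, continuous (channels x samples) or epoched
    (channels x samples x trials)."""

    data: np.ndarray
    sfreq: float
    ch_names: tuple[str, ...]
    ch_roles: tuple[str, ...]
    grad_pairs: tuple[tuple[int, int], ...] = ()
    times: np.ndarray | None = None            # epoched: per-sample time re onset
    onsets: np.ndarray | None = None           # continuous: stimulus onsets (s)
    condition_labels: tuple[str, ...] = ()     # per trial
    is_epoched: bool = False

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2] if self.is_epoched else 0

    def copy_with(self, **kw) -> "SensorDataset":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# simulation config / ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """One planted source population.

    For slow components ``peak_time`` is the raised-cosine peak (s); for the
    fast component per-tone burst amplitudes may be given (scalar amplitude
    applies to all five tones).
    """

    voxels: tuple[int, ...]
    amplitude_M: float | tuple[float, ...]
    amplitude_N: float | tuple[float, ...]
    peak_time: float = SEQUENCE_DURATION / 2.0

    def amps(self, condition: str, n_tones: int) -> np.ndarray:
        a = self.amplitude_M if condition == "M" else self.amplitude_N
        arr = np.atleast_1d(np.asarray(a, dtype=float))
        if arr.size == 1:
            arr = np.full(n_tones, arr[0])
        if np.any(arr < 0):
            raise ValueError("amplitudes must be >= 0")
        return arr


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 10
    n_trials_per_condition: int = 20
    sfreq: float = 150.0
    tmin: float = -0.1
    tmax: float = 3.5
    tone_onsets: tuple[float, ...] = TONE_ONSETS
    slow_effects: tuple[EffectSpec, ...] = ()
    fast_effect: EffectSpec | tuple[EffectSpec, ...] | None = None
    fast_freq: float = 4.0          # Hz, Gabor center (within 2-8)
    fast_fwhm: float = 0.15         # s, Gabor envelope FWHM
    fast_latency: float = 0.1       # s, burst peak delay after tone onset
    # per-trial, per-effect sd (s) of the fast-burst latency.  Non-zero
    # jitter decorrelates simultaneously active fast populations (e.g. the
    # two hemispheres); perfectly coherent sources are a degenerate case
    # that minimum-variance beamformers are known to cancel.
    fast_latency_jitter_sd: float = 0.0
    noise_sd: float = 0.5
    ar_coeff: float = 0.0           # optional AR(1) temporal correlation
    inter_trial_gap: float = 0.4    # s of silence appended after each epoch
    seed: int = 0

    def fast_list(self) -> tuple[EffectSpec, ...]:
        if self.fast_effect is None:
            return ()
        if isinstance(self.fast_effect, EffectSpec):
            return (self.fast_effect,)
        return tuple(self.fast_effect)

    def validate(self, n_sources: int) -> None:
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fast_latency_jitter_sd < 0:
            raise ValueError("fast_latency_jitter_sd must be >= 0")
        for eff in list(self.slow_effects) + list(self.fast_list()):
            for v in eff.voxels:
                if not (0 <= v < n_sources):
                    raise ValueError(f"voxel index {v} outside grid (n={n_sources})")
            eff.amps("M", len(self.tone_onsets))
            eff.amps("N", len(self.tone_onsets))


@dataclass
class GroundTruth:
    """What was planted: voxel sets, orientations, waveforms, amplitude ratios."""

    slow_voxels: tuple[tuple[int, ...], ...]
    slow_peak_times: tuple[float, ...]
    fast_voxels: tuple[int, ...]
    orientations: dict[int, np.ndarray]     # voxel -> unit 3-vector
    waveforms: dict[str, np.ndarray]        # condition -> (n_active, n_samples)
    active_voxels: tuple[int, ...]          # row order of `waveforms`
    epoch_times: np.ndarray
    amplitude_ratio: dict[str, float]       # component -> M/N amplitude ratio


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def slow_waveform(t: np.ndarray, peak_time: float,
                  duration: float = SEQUENCE_DURATION) -> np.ndarray:
    """Half-cycle raised cosine (Hann bump) of the given duration, peaking at
    ``peak_time``; spectral energy sits around 1/duration ~ 0.8 Hz."""
    start = peak_time - duration / 2.0
    x = (t - start) / duration
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * x))
    w[(x < 0) | (x > 1)] = 0.0
    return w


def fast_waveform(t: np.ndarray, tone_onsets, amps: np.ndarray,
                  freq: float = 4.0, fwhm: float = 0.15,
                  latency: float = 0.1) -> np.ndarray:
    """Sum of per-tone Gabor bursts (cosine carrier, Gaussian envelope)."""
    sig = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    out = np.zeros_like(t)
    for onset, a in zip(tone_onsets, amps):
        tc = onset + latency
        out += a * np.exp(-((t - tc) ** 2) / (2 * sig**2)) * np.cos(
            2 * np.pi * freq * (t - tc)
        )
    return out


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def _epoch_times(cfg: SimulationConfig) -> np.ndarray:
    n = int(round((cfg.tmax - cfg.tmin) * cfg.sfreq))
    return cfg.tmin + np.arange(n) / cfg.sfreq


def _source_epoch(cfg: SimulationConfig, condition: str,
                  active: list[int], times: np.ndarray,
                  fast_latencies=None) -> np.ndarray:
    """(n_active, n_samples) source moment waveforms for one trial.

    ``fast_latencies`` optionally overrides the burst latency per fast
    effect (one value per entry of ``cfg.fast_list()``).
    """
    out = np.zeros((len(active), times.size))
    row = {v: i for i, v in enumerate(active)}
    n_tones = len(cfg.tone_onsets)
    for eff in cfg.slow_effects:
        amp = eff.amps(condition, 1)[0]
        w = amp * slow_waveform(times, eff.peak_time)
        for v in eff.voxels:
            out[row[v]] += w
    fast = cfg.fast_list()
    if fast_latencies is None:
        fast_latencies = [cfg.fast_latency] * len(fast)
    for eff, lat in zip(fast, fast_latencies):
        amps = eff.amps(condition, n_tones)
        w = fast_waveform(times, cfg.tone_onsets, amps,
                          freq=cfg.fast_freq, fwhm=cfg.fast_fwhm,
                          latency=lat)
        for v in eff.voxels:
            out[row[v]] += w
    return out


def simulate_evoked(
    cfg: SimulationConfig,
    grid: SourceGrid,
    leadfield: np.ndarray,
    layout: ChannelLayout,
    continuous: bool = True,
    edge_duration: float = 2.5,
) -> tuple[list[SensorDataset], GroundTruth]:
    """Simulate per-subject recordings with the configured planted effects.

    Parameters
    ----------
    leadfield : (sources, 3, channels) channel-level leadfield
        (see :func:`channel_leadfield`).
    continuous : if True (default) each subject gets one continuous recording
        with stimulus ``onsets``, ready for the filtering -> epoching chain;
        otherwise pre-epoched data is returned.
    edge_duration : s of signal-free padding at both ends of a continuous
        recording (covers long baselines and filter edge effects).
    """
    cfg.validate(grid.n_sources)
    if leadfield.shape[2] != layout.n_channels:
        raise ValueError("leadfield/channel-count mismatch")

    fast_effects = cfg.fast_list()
    active = sorted(
        {v for eff in cfg.slow_effects for v in eff.voxels}
        | {v for eff in fast_effects for v in eff.voxels}
    )
    master = np.random.default_rng(cfg.seed)
    # fixed dipole orientation per active voxel, shared by all subjects
    orientations = {}
    for v in active:
        vec = master.normal(size=3)
        orientations[v] = vec / np.linalg.norm(vec)

    times = _epoch_times(cfg)
    src = {c: _source_epoch(cfg, c, active, times) for c in ("M", "N")}
    # effective channel pattern per active voxel: orientation . leadfield3
    patterns = (
        np.array([orientations[v] @ leadfield[v] for v in active])
        if active else np.zeros((0, layout.n_channels))
    )
    pre = times < 0  # signal only after stimulus onset

    def make_sensor_epoch(lab: str, rng) -> np.ndarray:
        """(ch, n_samp) sensor-level signal for one trial."""
        if cfg.fast_latency_jitter_sd > 0 and fast_effects:
            lats = cfg.fast_latency + rng.normal(
                scale=cfg.fast_latency_jitter_sd, size=len(fast_effects))
            ep = patterns.T @ _source_epoch(cfg, lab, active, times,
                                            fast_latencies=lats)
        else:
            ep = patterns.T @ src[lab]
        ep = np.array(ep, copy=True)
        ep[:, pre] = 0.0
        return ep

    n_samp = times.size
    n_trials = 2 * cfg.n_trials_per_condition
    datasets = []
    for subj in range(cfg.n_subjects):
        rng = np.random.default_rng([cfg.seed, 1 + subj])
        labels = np.array(["M"] * cfg.n_trials_per_condition
                          + ["N"] * cfg.n_trials_per_condition)
        rng.shuffle(labels)
        if continuous:
            step = int(round((cfg.tmax - cfg.tmin + cfg.inter_trial_gap) * cfg.sfreq))
            edge = int(round(edge_duration * cfg.sfreq))
            total = 2 * edge + n_trials * step
            data = _noise(rng, (layout.n_channels, total), cfg.noise_sd, cfg.ar_coeff)
            onset_samples = edge + np.arange(n_trials) * step + int(
                round(-cfg.tmin * cfg.sfreq)
            )
            for k, lab in enumerate(labels):
                s0 = onset_samples[k] + int(round(cfg.tmin * cfg.sfreq))
                data[:, s0:s0 + n_samp] += make_sensor_epoch(lab, rng)
            ds = SensorDataset(
                data=data, sfreq=cfg.sfreq, ch_names=layout.names,
                ch_roles=layout.roles, grad_pairs=layout.grad_pairs,
                onsets=onset_samples / cfg.sfreq,
                condition_labels=tuple(str(l) for l in labels), is_epoched=False,
            )
        else:
            data = _noise(rng, (layout.n_channels, n_samp, n_trials),
                          cfg.noise_sd, cfg.ar_coeff)
            for k, lab in enumerate(labels):
                data[:, :, k] += make_sensor_epoch(lab, rng)
            ds = SensorDataset(
                data=data, sfreq=cfg.sfreq, ch_names=layout.names,
                ch_roles=layout.roles, grad_pairs=layout.grad_pairs,
                times=times.copy(),
                condition_labels=tuple(str(l) for l in labels),
                is_epoched=True,
            )
        datasets.append(ds)

    ratio = {}
    for i, eff in enumerate(cfg.slow_effects):
        aM, aN = eff.amps("M", 1)[0], eff.amps("N", 1)[0]
        ratio[f"slow{i}"] = float(aM / aN) if aN else np.inf
    if fast_effects:
        aM = np.mean([e.amps("M", len(cfg.tone_onsets)).mean()
                      for e in fast_effects])
        aN = np.mean([e.amps("N", len(cfg.tone_onsets)).mean()
                      for e in fast_effects])
        ratio["fast"] = float(aM / aN) if aN else np.inf
    truth = GroundTruth(
        slow_voxels=tuple(eff.voxels for eff in cfg.slow_effects),
        slow_peak_times=tuple(eff.peak_time for eff in cfg.slow_effects),
        fast_voxels=tuple(sorted({v for e in fast_effects for v in e.voxels})),
        orientations=orientations,
        waveforms=src,
        active_voxels=tuple(active),
        epoch_times=times,
        amplitude_ratio=ratio,
    )
    return datasets, truth


def _noise(rng: np.random.Generator, shape, sd: float, ar: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    x = rng.normal(scale=sd, size=shape)
    if ar:
        # AR(1) along the time axis (axis 1), stationary innovation scaling
        innov_sd = np.sqrt(1.0 - ar**2)
        y = np.empty_like(x)
        y[:, 0] = x[:, 0]
        for t in range(1, shape[1]):
            y[:, t] = ar * y[:, t - 1] + innov_sd * x[:, t]
        return y
    return x


# ---------------------------------------------------------------------------
# symbolic melodies (first-order Markov source)
# ---------------------------------------------------------------------------

def simulate_melodies(
    alphabet_size: int,
    length: int,
    transition_matrix: np.ndarray,
    n: int,
    seed: int,
    initial: np.ndarray | None = None,
) -> list[list[int]]:
    """Draw ``n`` tone sequences of the given length from a first-order
    Markov source over ``{0 .. alphabet_size-1}``."""
    P = np.asarray(transition_matrix, dtype=float)
    if P.shape != (alphabet_size, alphabet_size):
        raise ValueError("transition matrix shape mismatch")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("rows of the transition matrix must sum to 1")
    if initial is None:
        initial = np.full(alphabet_size, 1.0 / alphabet_size)
    initial = np.asarray(initial, dtype=float)
    if not np.isclose(initial.sum(), 1.0, atol=1e-9):
        raise ValueError("initial distribution must sum to 1")
    rng = np.random.default_rng(seed)
    out = []
    syms = np.arange(alphabet_size)
    for _ in range(n):
        seq = [int(rng.choice(syms, p=initial))]
        for _ in range(length - 1):
            seq.append(int(rng.choice(syms, p=P[seq[-1]])))
        out.append(seq)
    return out
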