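"""Narrow-band phase extraction, Morlet time-frequency power, and cluster-based
permutation statistics.

Phases feed the circular-correlation coupling analysis (:mod:`dyadcoupling.btbc`);
the time-frequency path quantifies each participant's own oscillatory response to
the conditioned stimuli, with multiple comparisons handled non-parametrically by
cluster-mass permutation over (channel, frequency, time) adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from ._utils import as_rng

__all__ = [
    "Band", "DEFAULT_BANDS", "PhaseSeries", "TFPower", "Cluster",
    "ClusterPermutationResult", "DegeneratePhaseError", "band_phase",
    "morlet_tf", "relative_power", "cluster_permutation",
]


class DegeneratePhaseError(ValueError):
    """Raised when instantaneous phase is undefined (e.g. constant signal)."""


@dataclass(frozen=True)
class Band:
    """A named frequency band with edges in Hz."""
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


#: Canonical band partition used throughout: delta and theta are the a-priori
#: low-frequency bands of interest; alpha and beta serve as controls.
DEFAULT_BANDS = {
    "delta": Band("delta", 1.0, 3.0),
    "theta": Band("theta", 4.0, 8.0),
    "alpha": Band("alpha", 9.0, 12.0),
    "beta": Band("beta", 13.0, 30.0),
}


@dataclass
class PhaseSeries:
    """Instantaneous phase of one or more channels in a narrow band.

    ``phase`` has shape (..., n_samples) with values in (-pi, pi]. ``valid`` masks
    out filter edge effects (1 s at each end is untrusted).
    """
    phase: np.ndarray
    fs: float
    band: Band
    valid: np.ndarray = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return self.phase.shape[-1]


def _bandpass_sos(band: Band, fs: float, order: int = 4):
    return signal.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs,
                         output="sos")


def bandpass(x: np.ndarray, fs: float, band: Band, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) band-pass along the last axis."""
    if fs < 4.0 * band.hi:
        raise ValueError(f"fs={fs} too low for band {band.name} (need >= {4*band.hi})")
    sos = _bandpass_sos(band, fs, order)
    return signal.sosfiltfilt(sos, x, axis=-1)


def band_phase(recording: np.ndarray, fs: float, band: Band,
               edge_s: float = 1.0) -> PhaseSeries:
    """Narrow-band instantaneous phase via zero-phase band-pass + analytic signal.

    Parameters
    ----------
    recording : array (..., n_samples)
        Continuous signal(s); time on the last axis.
    fs : float
        Sampling rate in Hz; must be at least four times the band's upper edge.
    band : Band
    edge_s : float
        Span at each end flagged untrusted in the returned ``valid`` mask.
    """
    recording = np.asarray(recording, dtype=float)
    if not np.all(np.isfinite(recording)):
        raise ValueError("recording contains non-finite samples")
    if recording.shape[-1] < 8:
        raise ValueError("signal too short for phase estimation")
    if np.any(np.ptp(recording, axis=-1) == 0):
        raise DegeneratePhaseError("constant signal has no defined phase")
    filtered = bandpass(recording, fs, band)
    analytic = signal.hilbert(filtered, axis=-1)
    phase = np.angle(analytic)
    n = phase.shape[-1]
    valid = np.ones(n, dtype=bool)
    edge = int(round(edge_s * fs))
    if edge > 0:
        valid[:edge] = False
        valid[n - edge:] = False
    return PhaseSeries(phase=phase, fs=fs, band=band, valid=valid)


@dataclass
class TFPower:
    """Trial-averaged time-frequency power: (channels, frequencies, times)."""
    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    relative: bool = False


def _morlet_wavelet(freq: float, fs: float, n_cycles: float) -> np.ndarray:
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    wav = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    wav /= np.sqrt(np.sum(np.abs(wav) ** 2))  # unit energy
    return wav


def morlet_tf(epochs: np.ndarray, fs: float, times: np.ndarray,
              freqs: np.ndarray | None = None, n_cycles: float = 7.0) -> TFPower:
    """Trial-averaged Morlet wavelet power.

    Parameters
    ----------
    epochs : array (n_trials, n_channels, n_times)
    fs : float
    times : array (n_times,)
        Time axis in seconds relative to stimulus onset.
    freqs : array, optional
        Analysis frequencies in Hz; default 1..30 Hz in 1 Hz steps.
    n_cycles : float
        Gaussian kernel width of the wavelet, in cycles (default 7).

    Frequencies whose 7-cycle wavelet does not fit in the epoch are dropped with
    a warning.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3:
        raise ValueError("epochs must be (trials, channels, times)")
    if freqs is None:
        freqs = np.arange(1.0, 31.0)
    freqs = np.asarray(freqs, dtype=float)
    n_trials, n_ch, n_t = epochs.shape
    if len(times) != n_t:
        raise ValueError("times length does not match epochs")

    keep, powers = [], []
    flat = epochs.reshape(n_trials * n_ch, n_t)
    for f in freqs:
        wav = _morlet_wavelet(f, fs, n_cycles)
        if len(wav) > n_t:
            warnings.warn(f"epoch too short for {n_cycles}-cycle wavelet at "
                          f"{f:g} Hz; frequency dropped")
            continue
        conv = signal.fftconvolve(flat, wav[np.newaxis, :], mode="same", axes=-1)
        pw = np.abs(conv) ** 2
        powers.append(pw.reshape(n_trials, n_ch, n_t).mean(axis=0))
        keep.append(f)
    if not powers:
        raise ValueError("no analysis frequency fits the epoch")
    power = np.stack(powers, axis=1)  # (channels, freqs, times)
    return TFPower(power=power, freqs=np.array(keep), times=np.asarray(times),
                   fs=fs)


def relative_power(tf: TFPower, baseline_window: tuple[float, float] = (-2.0, -0.2)
                   ) -> TFPower:
    """Power as fractional change relative to the pre-stimulus baseline mean.

    ``(power - baseline_mean) / baseline_mean`` per channel and frequency.
    """
    lo, hi = baseline_window
    mask = (tf.times >= lo) & (tf.times <= hi)
    if not mask.any():
        raise ValueError("baseline window outside epoch")
    base = tf.power[..., mask].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ZeroDivisionError("zero baseline power; relative change undefined")
    rel = (tf.power - base) / base
    return TFPower(power=rel, freqs=tf.freqs, times=tf.times, fs=tf.fs,
                   relative=True)


@dataclass
class Cluster:
    """A connected suprathreshold set in (channel, frequency, time) space."""
    mass: float
    p: float
    sign: int
    voxels: list
    channels: set
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass
class ClusterPermutationResult:
    clusters: list
    t_map: np.ndarray
    t_crit: float
    n_perm: int

    @property
    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c.significant]


def write_epochs_hdf5(path, epochs: np.ndarray, fs: float, t0: float):
    """Store an epochs array (trials x channels x time) with fs/t0 attrs."""
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("epochs", data=np.asarray(epochs))
        ds.attrs["fs"] = fs
        ds.attrs["t0"] = t0


def read_epochs_hdf5(path):
    """Read an epochs array written by :func:`write_epochs_hdf5`."""
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["epochs"]
        return ds[()], float(ds.attrs["fs"]), float(ds.attrs["t0"])


def _t_paired(diff: np.ndarray) -> np.ndarray:
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf  # degenerate samples excluded from clustering
    return mean / (sd / np.sqrt(n))


def _t_independent(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1.0 / na + 1.0 / nb))
    denom[denom == 0] = np.inf
    return (a.mean(axis=0) - b.mean(axis=0)) / denom


def _find_clusters(supra: np.ndarray, t_map: np.ndarray, neighbors: list,
                   min_channels: int = 3):
    """Connected components over (channel graph) x (freq +-1) x (time +-1).

    Returns (mass, voxel list, channel set) per cluster with more than
    ``min_channels - 1`` distinct channels.
    """
    n_ch, n_f, n_t = supra.shape
    visited = np.zeros_like(supra, dtype=bool)
    out = []
    idx_ch, idx_f, idx_t = np.nonzero(supra)
    for c0, f0, t0 in zip(idx_ch, idx_f, idx_t):
        if visited[c0, f0, t0]:
            continue
        stack = [(c0, f0, t0)]
        visited[c0, f0, t0] = True
        vox = []
        while stack:
            c, f, t = stack.pop()
            vox.append((c, f, t))
            for nc in neighbors[c]:
                if supra[nc, f, t] and not visited[nc, f, t]:
                    visited[nc, f, t] = True
                    stack.append((nc, f, t))
            for nf in (f - 1, f + 1):
                if 0 <= nf < n_f and supra[c, nf, t] and not visited[c, nf, t]:
                    visited[c, nf, t] = True
                    stack.append((c, nf, t))
            for nt in (t - 1, t + 1):
                if 0 <= nt < n_t and supra[c, f, nt] and not visited[c, f, nt]:
                    visited[c, f, nt] = True
                    stack.append((c, f, nt))
        chans = {v[0] for v in vox}
        if len(chans) >= min_channels:
            mass = float(sum(t_map[v] for v in vox))
            out.append((mass, vox, chans))
    return out


def _max_cluster_mass(t_map: np.ndarray, t_crit: float, neighbors: list,
                      min_channels: int) -> float:
    best = 0.0
    for sign in (1, -1):
        supra = (sign * t_map) > t_crit
        for mass, _, _ in _find_clusters(supra, t_map, neighbors, min_channels):
            best = max(best, abs(mass))
    return best


def _neighbor_index_lists(neighbor_graph: dict, channel_names: list) -> list:
    pos = {name: i for i, name in enumerate(channel_names)}
    missing = [c for c in channel_names if c not in neighbor_graph]
    if missing:
        raise ValueError(f"neighbor graph missing channels: {missing[:5]}")
    return [[pos[n] for n in neighbor_graph[c] if n in pos] for c in channel_names]


def cluster_permutation(tf_a: np.ndarray, tf_b: np.ndarray, design: str,
                        neighbor_graph: dict, channel_names: list,
                        n_perm: int = 1000, alpha: float = 0.05,
                        min_channels: int = 3, seed=0) -> ClusterPermutationResult:
    """Cluster-mass permutation test on per-subject time-frequency maps.

    Parameters
    ----------
    tf_a, tf_b : arrays (n_subjects, n_channels, n_freqs, n_times)
        Condition maps. For ``design='paired'`` subjects must align; the null is
        generated by per-subject condition sign flips. For ``'independent'`` the
        null shuffles group labels.
    neighbor_graph : dict channel -> iterable of neighboring channels
    channel_names : channel order of axis 1
    n_perm : permutations for the max-cluster-mass null (default 1000)
    alpha : two-tailed sample-level threshold and cluster significance level
    min_channels : clusters must span at least this many distinct channels

    Cluster mass is the sum of sample t-values; cluster p-values use the
    (b + 1)/(m + 1) exceedance estimator against the max-|mass| null.
    """
    tf_a = np.asarray(tf_a, dtype=float)
    tf_b = np.asarray(tf_b, dtype=float)
    if design not in ("paired", "independent"):
        raise ValueError("design must be 'paired' or 'independent'")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null distribution")
    rng = as_rng(seed)
    neighbors = _neighbor_index_lists(neighbor_graph, channel_names)

    if design == "paired":
        if tf_a.shape != tf_b.shape:
            raise ValueError("paired design requires matching shapes")
        n = tf_a.shape[0]
        if n < 6:
            raise ValueError("need at least 6 subjects")
        diff = tf_a - tf_b
        df = n - 1
        t_map = _t_paired(diff)
    else:
        if tf_a.shape[0] < 6 or tf_b.shape[0] < 6:
            raise ValueError("need at least 6 subjects per group")
        df = tf_a.shape[0] + tf_b.shape[0] - 2
        t_map = _t_independent(tf_a, tf_b)

    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))

    observed = []
    for sign in (1, -1):
        supra = (sign * t_map) > t_crit
        for mass, vox, chans in _find_clusters(supra, t_map, neighbors,
                                               min_channels):
            observed.append((mass, vox, chans, sign))

    null = np.empty(n_perm)
    if design == "paired":
        for i in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=diff.shape[0])
            t_p = _t_paired(diff * signs[:, None, None, None])
            null[i] = _max_cluster_mass(t_p, t_crit, neighbors, min_channels)
    else:
        pooled = np.concatenate([tf_a, tf_b], axis=0)
        na = tf_a.shape[0]
        for i in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            t_p = _t_independent(pooled[perm[:na]], pooled[perm[na:]])
            null[i] = _max_cluster_mass(t_p, t_crit, neighbors, min_channels)

    clusters = []
    for mass, vox, chans, sign in observed:
        b = int(np.sum(null >= abs(mass)))
        p = (b + 1.0) / (n_perm + 1.0)
        clusters.append(Cluster(mass=mass, p=p, sign=sign, voxels=vox,
                                channels=chans, alpha=alpha))
    clusters.sort(key=lambda c: c.p)
    return ClusterPermutationResult(clusters=clusters, t_map=t_map,
                                    t_crit=t_crit, n_perm=n_perm)
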