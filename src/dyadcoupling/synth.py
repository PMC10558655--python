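"""Synthetic demonstrator-observer dyads with planted ground truth.

Every downstream stage of the package (coupling, learning model, clustering,
prediction, peripheral measures) is exercisable on data from this module: a
Pavlovian trial schedule (6 s CS, US at 5.5 s on a fraction of CS+ trials,
8-12 s ITI), paired multichannel 1/f-like "neural" signals with controllable
narrow-band phase coupling planted per condition, Rescorla-Wagner-generated
skin conductance, pupil traces with a shared dyadic component and blink gaps,
and fixation streams over the hand/face/stimulus areas of interest.

Coupling is planted in phase only (the coupling statistic is phase-only): a
planted observer channel carries the demonstrator's natural narrow-band
component rotated by a continuous phase-offset process. Inside designated
trial windows the offset is held constant per trial with slow wrapped-Gaussian
jitter whose concentration grows with the planted strength ``kappa``
(kappa = 1 -> no jitter, i.e. perfect per-trial phase locking; kappa = 0 ->
no planting); outside those windows the offset drifts rapidly, so baseline
segments and non-designated conditions are phase-decoupled. The pre-task head
segment of each recording therefore never contains planted coupling and
serves as the stimulus-free baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from ._utils import as_rng, one_over_f_noise, ou_process
from .ocular import DEFAULT_AOIS, SCREEN, FixationStream, PupilTrace
from .spectral import Band, DEFAULT_BANDS, bandpass

__all__ = [
    "Trial", "TrialSchedule", "DyadRecording", "PlantedCoupling", "GroundTruth",
    "make_schedule", "grid_neighbor_graph", "simulate_dyad_signals",
    "simulate_scr", "make_pseudo_demonstrator", "simulate_pupil_and_fixations",
]

US_DELAY_S = 5.5
CS_DURATION_S = 6.0


@dataclass(frozen=True)
class Trial:
    onset_s: float
    cs_type: str  # "CS+" or "CS-"
    us: bool
    us_onset_s: float | None
    block: int = 1


@dataclass
class TrialSchedule:
    """Ordered CS/US events of one conditioning block (or session)."""
    trials: list
    cs_duration_s: float = CS_DURATION_S
    iti_range_s: tuple = (8.0, 12.0)

    def __post_init__(self):
        onsets = [t.onset_s for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")
        for t in self.trials:
            if t.cs_type == "CS-" and t.us:
                raise ValueError("CS- trials can never carry a US")
            if t.us and abs((t.us_onset_s - t.onset_s) - US_DELAY_S) > 1e-9:
                raise ValueError(f"US must occur {US_DELAY_S} s after CS onset")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset_s for t in self.trials])

    @property
    def us_flags(self) -> np.ndarray:
        return np.array([t.us for t in self.trials])

    @property
    def cs_types(self) -> list:
        return [t.cs_type for t in self.trials]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"onset_s": t.onset_s, "duration_s": self.cs_duration_s,
                 "label": t.cs_type,
                 "extra": json.dumps({"us": t.us, "us_onset_s": t.us_onset_s,
                                      "block": t.block})}
                for t in self.trials]
        return pd.DataFrame(rows)

    def to_tsv(self, path):
        # %.17g guarantees float64 round-trip through text
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.17g")

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        trials = []
        for _, row in df.iterrows():
            extra = json.loads(row["extra"])
            trials.append(Trial(onset_s=float(row["onset_s"]),
                                cs_type=str(row["label"]),
                                us=bool(extra["us"]),
                                us_onset_s=extra["us_onset_s"],
                                block=int(extra.get("block", 1))))
        return cls(trials=trials,
                   cs_duration_s=float(df["duration_s"].iloc[0]))


@dataclass
class PlantedCoupling:
    """Ground-truth phase coupling for one channel pair in one band."""
    dem_channel: str
    obs_channel: str
    band: str = "delta"
    condition: str = "both"  # "CS+", "CS-" or "both"
    kappa: float = 0.8
    window: tuple | None = None  # seconds relative to CS onset; None = full CS

    def __post_init__(self):
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What recovery tests check against."""
    plantings: list = field(default_factory=list)
    rw_params: dict = field(default_factory=dict)
    pupil_shared_gain: float = 0.0
    status_group: str = "LS"

    def to_json(self, path):
        payload = {
            "plantings": [vars(p) for p in self.plantings],
            "rw_params": {k: vars(v) for k, v in self.rw_params.items()},
            "pupil_shared_gain": self.pupil_shared_gain,
            "status_group": self.status_group,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class DyadRecording:
    """Paired continuous recordings for one demonstrator-observer dyad."""
    demonstrator_signals: np.ndarray  # (n_channels, n_samples)
    observer_signals: np.ndarray
    fs: float
    channel_names: dict  # {"demonstrator": [...], "observer": [...]}
    neighbor_graph: dict  # adjacency over observer channels
    schedule: TrialSchedule
    ground_truth: GroundTruth | None = None

    def __post_init__(self):
        if self.demonstrator_signals.shape[-1] != self.observer_signals.shape[-1]:
            raise ValueError("both roles must share sample count")
        if not (np.all(np.isfinite(self.demonstrator_signals))
                and np.all(np.isfinite(self.observer_signals))):
            raise ValueError("non-finite samples in recording")
        if any(len(self.neighbor_graph.get(c, ())) == 0
               for c in self.channel_names["observer"]):
            raise ValueError("every observer channel needs >= 1 neighbor")

    @property
    def n_samples(self) -> int:
        return self.demonstrator_signals.shape[-1]

    def to_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as fh:
            d = fh.create_dataset("/dem/data", data=self.demonstrator_signals)
            o = fh.create_dataset("/obs/data", data=self.observer_signals)
            fh.attrs["fs"] = self.fs
            d.attrs["channels"] = self.channel_names["demonstrator"]
            o.attrs["channels"] = self.channel_names["observer"]


def make_schedule(n_cs_plus: int, n_cs_minus: int,
                  reinforcement_rate: float = 0.625, seed=0, *,
                  start_s: float = 60.0, iti_range_s: tuple = (8.0, 12.0),
                  cs_duration_s: float = CS_DURATION_S,
                  block: int = 1) -> TrialSchedule:
    """Pseudo-randomized Pavlovian schedule.

    Exactly ``round(n_cs_plus * reinforcement_rate)`` CS+ trials carry a US
    5.5 s after onset; CS- trials never do. Inter-trial intervals are uniform
    in ``iti_range_s`` (default 8-12 s). The first onset is at ``start_s``,
    leaving a stimulus-free head segment used as baseline downstream.
    """
    if n_cs_plus < 0 or n_cs_minus < 0:
        raise ValueError("trial counts must be non-negative")
    if not 0.0 <= reinforcement_rate <= 1.0:
        raise ValueError("reinforcement_rate must lie in [0, 1]")
    rng = as_rng(seed)
    labels = ["CS+"] * n_cs_plus + ["CS-"] * n_cs_minus
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    n_us = int(round(n_cs_plus * reinforcement_rate))
    plus_positions = [i for i, lab in enumerate(labels) if lab == "CS+"]
    us_positions = set(rng.choice(plus_positions, size=n_us, replace=False)
                       ) if n_us else set()
    trials = []
    t = float(start_s)
    for i, lab in enumerate(labels):
        us = i in us_positions
        trials.append(Trial(onset_s=t, cs_type=lab, us=us,
                            us_onset_s=t + US_DELAY_S if us else None,
                            block=block))
        t += cs_duration_s + rng.uniform(*iti_range_s)
    return TrialSchedule(trials=trials, cs_duration_s=cs_duration_s,
                         iti_range_s=tuple(iti_range_s))


def grid_neighbor_graph(names: list) -> dict:
    """Rook adjacency on a near-square grid layout of the given channels."""
    n = len(names)
    rows = int(np.floor(np.sqrt(n)))
    while n % rows:
        rows -= 1
    cols = n // rows
    if rows == 1 and n > 1:  # prime counts: fall back to a ring
        return {names[i]: [names[(i - 1) % n], names[(i + 1) % n]]
                for i in range(n)}
    graph = {}
    for i, name in enumerate(names):
        r, c = divmod(i, cols)
        nbrs = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                nbrs.append(names[rr * cols + cc])
        graph[name] = nbrs
    return graph


def _jitter_sd(kappa: float) -> float:
    """Phase-jitter SD (radians) decreasing in planted strength kappa.

    Equivalent von-Mises concentration is ~1/sd**2: infinite at kappa = 1
    (no jitter), tiny at kappa -> 0. The realized per-trial circular
    correlation is approximately exp(-sd**2), so kappa = {0.3, 0.6, 0.9}
    land near r = {0.3, 0.85, 0.99}.
    """
    return 0.8 * (1.0 - kappa) / (kappa + 0.2)


def simulate_dyad_signals(schedule: TrialSchedule, plantings=(),
                          band: Band | None = None, fs: float = 250.0,
                          n_channels: int = 8, seed=0,
                          ground_truth: GroundTruth | None = None
                          ) -> DyadRecording:
    """Paired multichannel signals with phase coupling planted per condition.

    All channels are independent unit-variance 1/f-like noise. For each
    planted pair, inside trial windows of the designated condition, the
    observer channel's narrow-band component is replaced by the
    demonstrator's band component rotated by a per-trial constant phase offset
    plus slow phase jitter scaled by ``1 - kappa`` (see module docstring). The
    head segment before the first trial is left free of coupling.
    """
    band = band or DEFAULT_BANDS["delta"]
    if fs < 4.0 * band.hi:
        raise ValueError(f"fs={fs} too low for band {band.name}")
    plantings = list(plantings)
    for p in plantings:
        if not 0.0 <= p.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
    rng = as_rng(seed)
    if isinstance(n_channels, tuple):
        n_dem, n_obs = n_channels
    else:
        n_dem = n_obs = int(n_channels)
    dem_names = [f"D{i:02d}" for i in range(n_dem)]
    obs_names = [f"O{i:02d}" for i in range(n_obs)]

    last = schedule.trials[-1]
    duration_s = last.onset_s + schedule.cs_duration_s + 2.0
    n_samp = int(round(duration_s * fs))

    dem = one_over_f_noise(n_samp, rng, size=(n_dem,))
    obs = one_over_f_noise(n_samp, rng, size=(n_obs,))

    active = [p for p in plantings if p.kappa > 0.0 and p.band == band.name]
    if active:
        # The circular correlation's phase means are ill-determined when the
        # marginal phase distribution is near-uniform (many oscillatory cycles
        # per window), so independent in-band noise on either channel would
        # randomize per-trial values even at kappa = 1. Planted pairs
        # therefore share *identical* band-vicinity content: each channel's
        # own content is removed over a widened guard band and replaced by the
        # demonstrator's natural band component — the observer's copy rotated
        # by a continuous phase-offset process theta(t). A real filter
        # commutes with a constant rotation of the analytic signal, so inside
        # planted windows (theta held, jitter sigma(kappa)) the extracted
        # phases differ by exactly theta; outside, theta drifts rapidly and
        # the pair is phase-decoupled. No window splicing, hence no filter
        # transients.
        guard = Band("guard", 0.5 * band.lo,
                     min(1.5 * band.hi, 0.45 * fs))
        dem_band = bandpass(dem, fs, band)
        dem_guard = bandpass(dem, fs, guard)
        obs_guard = bandpass(obs, fs, guard)
        obs_band_sd = bandpass(obs, fs, band).std(axis=-1)
        obs_partner: dict = {}
        dem_groups: dict = {}
        for p in active:
            if obs_partner.setdefault(p.obs_channel, p.dem_channel) != \
                    p.dem_channel:
                raise ValueError(f"observer channel {p.obs_channel} planted "
                                 "against multiple demonstrator channels in "
                                 "one band")
            dem_groups.setdefault(p.dem_channel, {}).setdefault(
                p.obs_channel, []).append(p)
        drift_rate = 20.0   # rad / sqrt(s) outside planted windows
        sigma_out = 4.0    # jitter SD outside planted windows
        smooth = max(int(round(0.2 * fs)), 1)
        kernel = np.ones(smooth) / smooth
        for dem_ch, per_obs in dem_groups.items():
            di = dem_names.index(dem_ch)
            core = hilbert(dem_band[di])
            dem[di] = dem[di] - dem_guard[di] + core.real
            for obs_ch, plist in per_obs.items():
                oi = obs_names.index(obs_ch)
                sd = np.full(n_samp, sigma_out)
                rate = np.full(n_samp, drift_rate)
                margin = 0.75  # hold theta slightly past the window so the
                # smoothed transition stays outside the scored epoch
                for p in plist:
                    w_lo, w_hi = p.window if p.window is not None else (
                        0.0, schedule.cs_duration_s)
                    for tr in schedule.trials:
                        if p.condition != "both" and tr.cs_type != p.condition:
                            continue
                        i0 = max(int(round((tr.onset_s + w_lo - margin) * fs)),
                                 0)
                        i1 = min(int(round((tr.onset_s + w_hi + margin) * fs)),
                                 n_samp)
                        sd[i0:i1] = _jitter_sd(p.kappa)
                        rate[i0:i1] = 0.0
                sd = np.convolve(sd, kernel, mode="same")
                rate = np.convolve(rate, kernel, mode="same")
                carrier = np.cumsum(
                    rate * rng.standard_normal(n_samp)) / np.sqrt(fs)
                theta = (rng.uniform(-np.pi, np.pi) + carrier
                         + sd * ou_process(n_samp, fs, rng))
                scale = obs_band_sd[oi] / max(dem_band[di].std(), 1e-12)
                comp = scale * (core * np.exp(1j * theta)).real
                obs[oi] = obs[oi] - obs_guard[oi] + comp

    gt = ground_truth or GroundTruth(plantings=plantings)
    return DyadRecording(
        demonstrator_signals=dem, observer_signals=obs, fs=fs,
        channel_names={"demonstrator": dem_names, "observer": obs_names},
        neighbor_graph=grid_neighbor_graph(obs_names), schedule=schedule,
        ground_truth=gt)


def simulate_scr(schedule: TrialSchedule, rw_params, seed=0) -> np.ndarray:
    """Per-trial SCR drawn from the Rescorla-Wagner observation model.

    ``SCR_t ~ Normal(beta0 + beta1 * V_t(s_t), sigma)`` with the value
    trajectory driven by the schedule's US sequence. One value per trial, in
    schedule order.
    """
    from .rlmodel import rw_trajectory

    if not 0.0 < rw_params.alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if rw_params.sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = as_rng(seed)
    traj = rw_trajectory(schedule, V0=rw_params.V0, alpha=rw_params.alpha)
    mean = rw_params.beta0 + rw_params.beta1 * traj.V
    return mean + rw_params.sigma * rng.standard_normal(len(mean))


def make_pseudo_demonstrator(recordings, seed=0) -> np.ndarray:
    """Surrogate demonstrator: each time point from a random real demonstrator.

    ``recordings`` is a sequence of (n_channels, n_samples) arrays with equal
    shapes. Sample t of the output is taken from exactly one randomly chosen
    source at the same time index, serially over time, destroying any
    dyad-specific temporal coupling while preserving marginal statistics.
    """
    recordings = [np.asarray(r, dtype=float) for r in recordings]
    if len(recordings) < 2:
        raise ValueError("need at least 2 source demonstrators")
    shape = recordings[0].shape
    if any(r.shape != shape for r in recordings):
        raise ValueError("source demonstrators must share shape (channels, "
                         "samples)")
    rng = as_rng(seed)
    stack = np.stack(recordings)  # (n_src, n_ch, n_samp)
    idx = rng.integers(0, len(recordings), size=shape[-1])
    return stack[idx, :, np.arange(shape[-1])].T.copy()


def _blinked(x: np.ndarray, fs: float, rng, rate_hz: float = 0.2,
             dur_range_s=(0.1, 0.4)):
    """Insert Poisson-timed NaN blink runs; returns (trace, onsets_s)."""
    n = len(x)
    t = rng.exponential(1.0 / rate_hz)
    onsets = []
    while t * fs < n:
        dur = rng.uniform(*dur_range_s)
        i0 = int(t * fs)
        i1 = min(int((t + dur) * fs), n)
        x[i0:i1] = np.nan
        onsets.append(t)
        t += dur + rng.exponential(1.0 / rate_hz)
    return x, np.array(onsets)


def _slow_noise(n_samp, fs, rng, lo=0.1, hi=2.0):
    x = bandpass(rng.standard_normal(n_samp), fs, Band("slow", lo, hi), order=2)
    return x / max(x.std(), 1e-12)


def simulate_pupil_and_fixations(schedule: TrialSchedule, shared_gain: float,
                                 seed=0, *, fs: float = 250.0,
                                 hand_bias: float = 0.5,
                                 shared_condition: str = "both",
                                 blink_rate_hz: float = 0.2,
                                 bias_window=(4.7, 5.5),
                                 cs_response_gain: float = 0.0):
    """Dyadic pupil traces plus an observer fixation stream.

    Both pupil traces share a slow 0.1-2 Hz component scaled by
    ``shared_gain`` (optionally present only in ``shared_condition`` trial
    windows) on top of independent slow noise, with Poisson blink gaps
    (NaN runs). ``cs_response_gain`` adds a smooth conditioned dilation of
    that amplitude to the observer trace on CS+ trials (a controllable
    learning-outcome signal). The fixation stream allocates dwell over the
    hand / face / stimulus / elsewhere areas; on CS+ trials, fixations inside
    ``bias_window`` post-onset land on the hand with probability
    ``hand_bias`` (1 forces full allocation).
    """
    if shared_gain < 0:
        raise ValueError("shared_gain must be non-negative")
    rng = as_rng(seed)
    last = schedule.trials[-1]
    duration_s = last.onset_s + schedule.cs_duration_s + 2.0
    n = int(round(duration_s * fs))

    shared = _slow_noise(n, fs, rng)
    if shared_condition != "both":
        mask = np.zeros(n)
        for tr in schedule.trials:
            if tr.cs_type == shared_condition:
                i0 = int(round(tr.onset_s * fs))
                i1 = min(int(round((tr.onset_s + schedule.cs_duration_s) * fs)), n)
                mask[i0:i1] = 1.0
        shared = shared * mask
    dem_raw = shared_gain * shared + _slow_noise(n, fs, rng)
    obs_raw = shared_gain * shared + _slow_noise(n, fs, rng)
    if cs_response_gain:
        # conditioned pupil response: smooth dilation on CS+ trials
        t_resp = np.arange(int(round(US_DELAY_S * fs))) / fs
        bump = cs_response_gain * np.sin(np.pi * t_resp / US_DELAY_S) ** 2
        for tr in schedule.trials:
            if tr.cs_type != "CS+":
                continue
            i0 = int(round(tr.onset_s * fs))
            i1 = min(i0 + len(bump), n)
            obs_raw[i0:i1] += bump[:i1 - i0]
    dem_raw, dem_onsets = _blinked(dem_raw, fs, rng, blink_rate_hz)
    obs_raw, obs_onsets = _blinked(obs_raw, fs, rng, blink_rate_hz)
    dem_trace = PupilTrace(data=dem_raw, fs=fs, blink_onsets_s=dem_onsets)
    obs_trace = PupilTrace(data=obs_raw, fs=fs, blink_onsets_s=obs_onsets)

    aoi_names = list(DEFAULT_AOIS) + ["elsewhere"]
    rows = []
    for tr in schedule.trials:
        # force fixation boundaries at the bias-window edges so the window is
        # covered exactly
        cuts = [tr.onset_s, tr.onset_s + bias_window[0],
                tr.onset_s + bias_window[1], tr.onset_s + schedule.cs_duration_s]
        for seg0, seg1 in zip(cuts, cuts[1:]):
            t = seg0
            in_bias = abs(seg0 - (tr.onset_s + bias_window[0])) < 1e-9
            while t < seg1 - 1e-9:
                dur = min(rng.uniform(0.15, 0.6), seg1 - t)
                if tr.cs_type == "CS+" and in_bias and rng.uniform() < hand_bias:
                    label = "hand"
                else:
                    label = aoi_names[rng.integers(len(aoi_names))]
                if label == "elsewhere":
                    while True:
                        x = rng.uniform(SCREEN.x0, SCREEN.x1)
                        y = rng.uniform(SCREEN.y0, SCREEN.y1)
                        if not any(r.contains(x, y)
                                   for r in DEFAULT_AOIS.values()):
                            break
                else:
                    rect = DEFAULT_AOIS[label]
                    x = rng.uniform(rect.x0, rect.x1 - 1e-6)
                    y = rng.uniform(rect.y0, rect.y1 - 1e-6)
                rows.append({"start_s": t, "end_s": t + dur, "x": x, "y": y})
                t += dur
    stream = FixationStream(events=pd.DataFrame(rows))
    return dem_trace, obs_trace, stream
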