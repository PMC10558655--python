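"""Peripheral physiology: skin-conductance trial scoring, pupil preprocessing,
area-of-interest fixation proportions, and eye-to-eye pupillary coupling.

Scoring conventions follow the standard threat-conditioning literature: SCR is
the largest base-to-peak amplitude 0.5-4.5 s after CS onset (z-scored within
subject); the pupil response is the 0-5.5 s mean, baseline-corrected by the
0.5 s preceding onset; fixation time per AOI is normalized to total on-screen
fixation time; eye-to-eye coupling applies the same circular correlation used
for brain-to-brain coupling to the slow phase of the two pupil traces.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal, stats

from .spectral import Band, band_phase, bandpass

__all__ = [
    "Rect", "SCREEN", "DEFAULT_AOIS", "FixationStream", "PupilTrace",
    "score_scr", "preprocess_pupil", "pupil_trial_response",
    "fixation_proportion", "eye_coupling",
]


class Rect(NamedTuple):
    """Axis-aligned rectangle in screen pixels, (x0, y0) top-left inclusive."""
    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x, y):
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)


SCREEN = Rect(0, 0, 1920, 1080)

#: Three rectangular areas of interest on the demonstrator video: the CS image
#: on the projector screen, the demonstrator's face, and the right hand wired to
#: the nerve stimulator. Mutually non-overlapping; "elsewhere" is any on-screen
#: point outside all three.
DEFAULT_AOIS = {
    "stimulus": Rect(760, 60, 1160, 360),
    "face": Rect(840, 420, 1080, 660),
    "hand": Rect(1250, 700, 1600, 1000),
}

AOI_LABELS = ("hand", "face", "stimulus", "elsewhere")


@dataclass
class FixationStream:
    """Fixation events as a DataFrame with columns start_s, end_s, x, y."""
    events: pd.DataFrame
    screen: Rect = SCREEN

    def __post_init__(self):
        ev = self.events
        if np.any(ev["end_s"].to_numpy() <= ev["start_s"].to_numpy()):
            raise ValueError("fixation events must have end_s > start_s")

    def to_tsv(self, path):
        self.events.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, screen: Rect = SCREEN):
        return cls(pd.read_csv(path, sep="\t"), screen=screen)


@dataclass
class PupilTrace:
    """Pupil diameter trace; ``usable`` is False when blinks dominate."""
    data: np.ndarray
    fs: float
    blink_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    usable: bool = True
    preprocessed: bool = False


def _trial_slice(onset_s, lo, hi, fs, n):
    i0 = int(round((onset_s + lo) * fs))
    i1 = int(round((onset_s + hi) * fs))
    if i0 < 0 or i1 > n:
        return None
    return slice(i0, i1)


def score_scr(trace: np.ndarray, fs: float, schedule) -> pd.DataFrame:
    """Per-trial z-scored SCR amplitudes.

    The conductance trace is band-filtered to 0.1-1 Hz; each trial's raw score
    is the largest base-to-peak excursion in the 0.5-4.5 s post-onset window
    (base = value at window start), floored at zero, then z-transformed across
    trials within the subject.
    """
    trace = np.asarray(trace, dtype=float)
    if fs < 10:
        raise ValueError("SCR sampling rate must be >= 10 Hz")
    band = Band("scr", 0.1, 1.0)
    filt = bandpass(trace, fs, band, order=2)
    rows = []
    n = len(filt)
    for i, tr in enumerate(schedule.trials):
        sl = _trial_slice(tr.onset_s, 0.5, 4.5, fs, n)
        if sl is None:
            warnings.warn(f"trial {i} window outside recording; dropped")
            continue
        seg = filt[sl]
        amp = max(float(np.max(seg - seg[0])), 0.0)
        rows.append({"trial": i, "cs_type": tr.cs_type, "us": tr.us,
                     "amplitude": amp})
    df = pd.DataFrame(rows)
    sd = df["amplitude"].std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        warnings.warn("zero-variance SCR amplitudes; z-scores set to 0")
        df["scr_z"] = 0.0
    else:
        df["scr_z"] = (df["amplitude"] - df["amplitude"].mean()) / sd
    return df


def _gamma_kernel(fs: float, span_s: float = 2.0, shape: float = 2.0,
                  scale: float = 0.35) -> np.ndarray:
    t = np.arange(0.0, span_s, 1.0 / fs)
    k = stats.gamma.pdf(t, a=shape, scale=scale)
    return k / k.max()


def preprocess_pupil(trace: PupilTrace, saccade_onsets_s=None,
                     out_fs: float = 100.0) -> PupilTrace:
    """Standard pupillometry cleanup.

    Blink gaps (NaN runs) are linearly interpolated; blink- and saccade-locked
    transients are regressed out on a canonical gamma kernel (0-2 s span)
    time-locked to each event; the trace is then band-passed 0.01-10 Hz,
    z-transformed, and resampled to ``out_fs`` (default 100 Hz).

    A trace with more than 50% blinked samples is returned flagged unusable.
    """
    x = np.asarray(trace.data, dtype=float).copy()
    fs = trace.fs
    nan_mask = ~np.isfinite(x)
    frac = nan_mask.mean()
    usable = frac <= 0.5
    if not usable:
        warnings.warn("more than 50% of samples blinked; subject flagged unusable")
    if nan_mask.any():
        idx = np.arange(len(x))
        x[nan_mask] = np.interp(idx[nan_mask], idx[~nan_mask], x[~nan_mask])

    # regress out event-locked transients (blink + optional saccade kernels)
    events = [np.asarray(trace.blink_onsets_s, dtype=float)]
    if saccade_onsets_s is not None:
        events.append(np.asarray(saccade_onsets_s, dtype=float))
    kernel = _gamma_kernel(fs)
    cols = [np.ones(len(x))]
    for ev in events:
        ev = ev[(ev >= 0) & (ev * fs < len(x))]
        if len(ev) == 0:
            continue
        impulses = np.zeros(len(x))
        impulses[np.round(ev * fs).astype(int)] = 1.0
        reg = signal.fftconvolve(impulses, kernel)[:len(x)]
        cols.append(reg)
    if len(cols) > 1:
        design = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        fitted = design[:, 1:] @ beta[1:]
        x = x - fitted

    # band-pass 0.01-10 Hz, zero phase
    hi = min(10.0, 0.45 * fs)
    sos = signal.butter(2, [0.01, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)

    sd = x.std()
    if sd < 1e-8:
        warnings.warn("zero-variance pupil trace after filtering")
        z = np.zeros_like(x)
    else:
        z = (x - x.mean()) / sd

    from fractions import Fraction
    frac_ratio = Fraction(out_fs / fs).limit_denominator(1000)
    z = signal.resample_poly(z, frac_ratio.numerator, frac_ratio.denominator)
    return PupilTrace(data=z, fs=out_fs, blink_onsets_s=trace.blink_onsets_s,
                      usable=usable, preprocessed=True)


def pupil_trial_response(trace: PupilTrace, schedule) -> pd.DataFrame:
    """Per-trial pupil response: mean over 0-5.5 s minus mean over -0.5-0 s."""
    x = trace.data
    fs = trace.fs
    rows = []
    for i, tr in enumerate(schedule.trials):
        task = _trial_slice(tr.onset_s, 0.0, 5.5, fs, len(x))
        base = _trial_slice(tr.onset_s, -0.5, 0.0, fs, len(x))
        if task is None or base is None:
            warnings.warn(f"trial {i} window outside recording; dropped")
            continue
        rows.append({"trial": i, "cs_type": tr.cs_type, "us": tr.us,
                     "pupil_response": float(x[task].mean() - x[base].mean())})
    return pd.DataFrame(rows)


def _assign_aoi(x, y, aois: dict, screen: Rect):
    if not screen.contains(x, y):
        return None
    for name, rect in aois.items():
        if rect.contains(x, y):
            return name
    return "elsewhere"


def fixation_proportion(stream: FixationStream, schedule,
                        window: tuple[float, float] = (4.7, 5.5),
                        aois: dict | None = None) -> pd.DataFrame:
    """Per-trial dwell-time proportion in each AOI within a post-onset window.

    Fixations straddling the window edges are clipped to the window; the
    denominator is total on-screen fixation time in the window, so the four
    proportions (hand, face, stimulus, elsewhere) sum to one. Trials without
    any on-screen fixation in the window are flagged and excluded (NaN).
    """
    aois = DEFAULT_AOIS if aois is None else aois
    ev = stream.events
    starts = ev["start_s"].to_numpy()
    ends = ev["end_s"].to_numpy()
    xs = ev["x"].to_numpy()
    ys = ev["y"].to_numpy()
    rows = []
    for i, tr in enumerate(schedule.trials):
        w0, w1 = tr.onset_s + window[0], tr.onset_s + window[1]
        lo = np.maximum(starts, w0)
        hi = np.minimum(ends, w1)
        dur = np.clip(hi - lo, 0.0, None)
        dwell = dict.fromkeys(AOI_LABELS, 0.0)
        for d, x, y in zip(dur, xs, ys):
            if d <= 0:
                continue
            label = _assign_aoi(x, y, aois, stream.screen)
            if label is not None:
                dwell[label] += d
        total = sum(dwell.values())
        row = {"trial": i, "cs_type": tr.cs_type}
        if total <= 0:
            row.update(dict.fromkeys(AOI_LABELS, np.nan))
            row["valid"] = False
        else:
            row.update({k: v / total for k, v in dwell.items()})
            row["valid"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def eye_coupling(dem: PupilTrace, obs: PupilTrace, schedule,
                 window: tuple[float, float] = (0.0, 5.5),
                 band: Band | None = None) -> pd.DataFrame:
    """Per-trial eye-to-eye pupillary coupling (circular correlation).

    Both preprocessed traces are reduced to slow instantaneous phase (0.1-4 Hz
    Hilbert phase by default) and the same circular correlation statistic used
    for brain-to-brain coupling is evaluated per trial window, Fisher-z
    transformed and folded to ``z_abs``.
    """
    from .btbc import DegenerateInputError, ccorr, normalize

    if dem.fs != obs.fs:
        raise ValueError("traces must share sampling rate")
    band = band or Band("pupil", 0.1, 4.0)
    ph_d = band_phase(dem.data, dem.fs, band).phase
    ph_o = band_phase(obs.data, obs.fs, band).phase
    fs = dem.fs
    n = min(len(ph_d), len(ph_o))
    rows = []
    for i, tr in enumerate(schedule.trials):
        sl = _trial_slice(tr.onset_s, window[0], window[1], fs, n)
        if sl is None:
            warnings.warn(f"trial {i} window outside recording; dropped")
            continue
        try:
            r = ccorr(ph_d[sl], ph_o[sl])
        except DegenerateInputError:
            warnings.warn(f"trial {i} degenerate phase; dropped")
            continue
        rows.append({"trial": i, "cs_type": tr.cs_type, "ccorr_raw": r,
                     "z_abs": normalize(r)})
    return pd.DataFrame(rows)


def aois_to_json(aois: dict, path):
    with open(path, "w") as fh:
        json.dump({k: list(v) for k, v in aois.items()}, fh, indent=1)
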