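"""Continuous-EEG conditioning and the EMG trial-metrics chain.

EEG side: a zero-phase windowed-sinc FIR band-pass (1-90 Hz) combined with a
46-54 Hz band-stop against line noise, then cue-locked epoching into 2 s
windows (-0.5 to 1.5 s, 512 samples at 256 Hz).

EMG side: per-trial rectification as absolute deviation from the trial mean,
a zero-phase second-order Butterworth low-pass envelope whose design cutoff is
raised by 25% (20 -> 25 Hz) so the *double-pass* response lands its -3 dB
point at 20 Hz, max-normalization, and a threshold onset/offset rule
(baseline mean + 3 SD sustained for >= 25 ms) replacing visual marking.
Trials without a supra-threshold run, or whose envelope peak is below 5x the
baseline SD, are dropped ("no clear EMG peak").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EMGTraces, EpochedEEG
from .montage import Montage

__all__ = [
    "bandpass_notch",
    "epoch",
    "emg_rectify",
    "emg_envelope",
    "emg_onset_duration",
    "process_emg",
    "EMGTrialMetrics",
    "EPOCH_WINDOW",
]

logger = logging.getLogger(__name__)

EPOCH_WINDOW = (-0.5, 1.5)
EMG_SEGMENT = 1.5  # seconds of post-cue EMG used for rectification/envelope


# ---------------------------------------------------------------------------
# EEG filtering and epoching
# ---------------------------------------------------------------------------

def _fir_kernel(fs: float, l_freq: float, h_freq: float,
                notch: tuple[float, float]) -> np.ndarray:
    """Combined band-pass + band-stop windowed-sinc kernel (Hamming).

    Orders are derived from the transition bandwidths and the sampling rate
    (Hamming rule of thumb: taps ~ 3.3 fs / transition width).
    """
    def taps(trans_bw: float) -> int:
        n = int(np.ceil(3.3 * fs / trans_bw))
        return n + 1 if n % 2 == 0 else n  # odd length -> type-I linear phase

    trans_lo = max(l_freq * 0.5, 0.5)
    trans_hi = min(10.0, max(2.0, 0.96 * fs / 2 - h_freq))
    bp = signal.firwin(
        taps(min(trans_lo, trans_hi)), [l_freq, h_freq],
        pass_zero=False, fs=fs, window="hamming",
    )
    bs = signal.firwin(
        taps(2.0), list(notch), pass_zero=True, fs=fs, window="hamming",
    )
    return np.convolve(bp, bs)


def bandpass_notch(
    raw: np.ndarray,
    fs: float,
    l_freq: float = 1.0,
    h_freq: float = 90.0,
    notch: tuple[float, float] = (46.0, 54.0),
) -> np.ndarray:
    """Zero-phase FIR band-pass with a line-noise band-stop.

    ``raw`` is (channels, samples) or (samples,) continuous EEG. Applied
    forward-backward, so the effective magnitude response is squared and
    there is no group delay. If ``fs`` cannot support the requested upper
    edge, the edge falls back to 0.45*fs with a warning.
    """
    if fs < 192:
        raise ValueError("sampling rate must be at least 192 Hz")
    if h_freq >= 0.96 * fs / 2:
        h_eff = 0.45 * fs
        msg = f"upper edge {h_freq} Hz infeasible at fs={fs}; using {h_eff:.1f} Hz"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        h_freq = h_eff
    kern = _fir_kernel(fs, l_freq, h_freq, notch)
    x = np.atleast_2d(np.asarray(raw, dtype=float))
    padlen = min(3 * len(kern), x.shape[-1] - 1)
    out = signal.filtfilt(kern, [1.0], x, axis=-1, padlen=padlen)
    return out[0] if np.ndim(raw) == 1 else out


def epoch(
    continuous: np.ndarray,
    fs: float,
    cue_times: np.ndarray,
    montage: Montage,
    window: tuple[float, float] = EPOCH_WINDOW,
) -> EpochedEEG:
    """Segment continuous EEG into cue-locked epochs.

    The cue lands exactly on sample index ``-window[0]*fs`` (128 at 256 Hz).
    Cues without ``window[0]`` of history or ``window[1]`` of future are
    dropped and logged; surviving trials keep their original cue indices as
    ``trial_ids``.
    """
    continuous = np.asarray(continuous, dtype=float)
    n_samp = continuous.shape[-1]
    pre = int(round(-window[0] * fs))
    post = int(round(window[1] * fs))
    epochs, kept = [], []
    for i, cue in enumerate(np.asarray(cue_times, dtype=float)):
        c = int(round(cue * fs))
        if c - pre < 0 or c + post > n_samp:
            logger.info("dropping cue %d at t=%.3f s: too close to recording edge", i, cue)
            continue
        epochs.append(continuous[:, c - pre:c + post])
        kept.append(i)
    if not epochs:
        raise ValueError("no cue survived epoching")
    times = (np.arange(pre + post) - pre) / fs
    return EpochedEEG(np.stack(epochs), fs, times, montage, trial_ids=np.array(kept))


# ---------------------------------------------------------------------------
# EMG chain
# ---------------------------------------------------------------------------

@dataclass
class EMGTrialMetrics:
    """Onset (the reaction time), contraction duration, peak, keep flag."""

    trial_id: int
    onset: float | None        # s relative to cue
    duration: float | None     # s
    envelope_peak: float       # normalized units, 1.0 for the session max
    kept: bool


def emg_rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification about the trial mean: |x - mean(x)|.

    Elementwise along the last axis; invariant to any constant offset. An
    all-constant trace rectifies to zeros (handled downstream, not an error).
    """
    x = np.asarray(x, dtype=float)
    return np.abs(x - x.mean(axis=-1, keepdims=True))


def emg_envelope(rectified: np.ndarray, fs: float, cutoff: float = 20.0,
                 normalize: bool = True) -> np.ndarray:
    """Smoothed EMG envelope via a zero-phase 2nd-order Butterworth low-pass.

    The design cutoff is ``cutoff * 1.25``: one forward-backward pass through
    a 2nd-order Butterworth squares the magnitude response, which moves the
    -3 dB point of the double-pass response down to ``25 * (2^0.5 - 1)^0.25
    ~ 20.06 Hz`` — i.e. the 25% adjustment makes the *effective* -3 dB
    frequency land at the desired cutoff. Output is divided by its maximum
    (per trace) unless the trace is all zero.
    """
    rect = np.asarray(rectified, dtype=float)
    sos = signal.butter(2, cutoff * 1.25, btype="low", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, rect, axis=-1)
    if normalize:
        peak = np.abs(env).max(axis=-1, keepdims=True)
        env = np.divide(env, peak, out=np.zeros_like(env), where=peak > 0)
    return env


def emg_onset_duration(
    envelope: np.ndarray,
    fs: float,
    times: np.ndarray,
    trial_id: int = 0,
    baseline_window: tuple[float, float] = (EPOCH_WINDOW[0], 0.0),
    n_sd: float = 3.0,
    min_run: float = 0.025,
    peak_sd_ratio: float = 5.0,
) -> EMGTrialMetrics:
    """Threshold onset/offset rule on a normalized envelope.

    Onset: first post-cue time the envelope exceeds (pre-cue baseline mean +
    ``n_sd`` * baseline SD) for at least ``min_run`` seconds. Offset: last
    supra-threshold sample of the trial. ``kept`` is False when no such run
    exists or the envelope peak is below ``peak_sd_ratio`` baseline SDs above
    the baseline mean (no clear EMG peak).
    """
    env = np.asarray(envelope, dtype=float)
    times = np.asarray(times, dtype=float)
    base_mask = (times >= baseline_window[0]) & (times < baseline_window[1])
    if not base_mask.any():
        raise ValueError("empty pre-cue baseline window")
    base = env[base_mask]
    mu, sd = base.mean(), base.std()
    peak = env.max()
    if sd <= 0 or peak <= 0:
        return EMGTrialMetrics(trial_id, None, None, float(peak), False)
    thresh = mu + n_sd * sd
    post = times >= 0.0
    supra = (env > thresh) & post
    min_len = max(1, int(round(min_run * fs)))
    onset_idx = _first_run(supra, min_len)
    clear_peak = (peak - mu) >= peak_sd_ratio * sd
    if onset_idx is None or not clear_peak:
        return EMGTrialMetrics(trial_id, None, None, float(peak), False)
    offset_idx = np.flatnonzero(supra)[-1]
    onset = float(times[onset_idx])
    duration = float(times[offset_idx] - times[onset_idx])
    return EMGTrialMetrics(trial_id, onset, duration, float(peak), True)


def _first_run(mask: np.ndarray, min_len: int) -> int | None:
    """Index of the first True-run of length >= min_len, else None."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return None
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    for s, e in zip(starts, ends):
        if idx[e] - idx[s] + 1 >= min_len:
            return int(idx[s])
    return None


def process_emg(
    emg: EMGTraces,
    segment: float = EMG_SEGMENT,
    **onset_kwargs,
) -> list[EMGTrialMetrics]:
    """Full per-trial EMG chain: rectify, envelope, normalize, onset/duration.

    Rectification and the envelope run on the ``segment``-second post-cue
    window; the pre-cue part of the trace is processed identically but used
    only for the baseline statistics of the threshold rule. The session-wide
    envelope maximum is the normalizer, so a kept session has max 1.
    """
    t = emg.times
    seg_mask = t < segment  # keep pre-cue for baseline, truncate post-segment
    x = emg.data[:, seg_mask]
    # rectification mean comes from the 1.5 s post-cue segment; the pre-cue
    # part is carried through only to supply baseline statistics
    post_mean = emg.data[:, (t >= 0) & seg_mask].mean(axis=-1, keepdims=True)
    rect = np.abs(x - post_mean)
    env = emg_envelope(rect, emg.fs, normalize=False)
    session_peak = np.abs(env).max()
    if session_peak > 0:
        env = env / session_peak
    return [
        emg_onset_duration(env[i], emg.fs, t[seg_mask],
                           trial_id=int(emg.trial_ids[i]), **onset_kwargs)
        for i in range(emg.n_trials)
    ]
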