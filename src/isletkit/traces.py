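"""Trace filtering, binarization and per-cell signaling parameters.

Input fluorescence traces (one column per cell) are band-pass filtered
(fast-sampled "mouse" mode) or high-pass filtered (slow-sampled "human"
mode) with a zero-phase Butterworth filter, smoothed by adjacent
averaging, binarized by a robust amplitude threshold, and reduced to
per-cell signaling parameters: relative active time, mean oscillation
frequency, mean oscillation duration and stimulus response time.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal as _sig

logger = logging.getLogger(__name__)

Mode = Literal["scatter", "grid"]

#: Default band-pass corner frequencies (Hz) for 10 Hz recordings.
DEFAULT_BAND_HZ = (0.035, 1.5)
#: Default high-pass corner frequency (Hz) for 0.33 Hz recordings.
DEFAULT_HIGHPASS_HZ = 0.0075
#: Default binarization amplitude threshold (fraction of robust amplitude).
DEFAULT_THETA_AMP = 0.3


class InvalidCutoffError(ValueError):
    """Filter cutoff outside (0, Nyquist)."""


@dataclass
class TraceSet:
    """Per-cell fluorescence time series with geometry and acquisition metadata.

    Parameters
    ----------
    values : ndarray, shape (n_frames, n_cells)
        Fluorescence (arbitrary units).
    time_s : ndarray, shape (n_frames,)
        Frame timestamps in seconds, strictly increasing and uniform.
    positions : ndarray, shape (n_cells, 2)
        Cell centroid coordinates in micrometres.
    sampling_hz : float
        Acquisition rate.
    stim_onset_s : float
        Time of the stimulation step.
    mode : {"scatter", "grid"}
        Scattered cell centroids vs. a regular 15 um sub-region mesh.
    """

    values: np.ndarray
    time_s: np.ndarray
    positions: np.ndarray
    sampling_hz: float
    stim_onset_s: float
    mode: Mode = "scatter"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a (n_frames, n_cells) matrix")
        if self.time_s.shape != (self.values.shape[0],):
            raise ValueError("time_s length must match number of frames")
        if self.positions.shape != (self.values.shape[1], 2):
            raise ValueError("positions must be (n_cells, 2)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite entries")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        dt = np.diff(self.time_s)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-6):
            raise ValueError("timestamps must be strictly increasing and uniform")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "TraceSet":
        """Copy of this trace set with ``values`` replaced (same shape)."""
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class BinaryActivity:
    """Binarized activity: 0/1 state matrix plus per-cell onset/offset times.

    ``onsets[i]``/``offsets[i]`` list the 0->1 and 1->0 transition times of
    cell *i* in seconds; they alternate, starting with an onset, and each
    onset precedes its offset.
    """

    states: np.ndarray
    time_s: np.ndarray
    onsets: list[np.ndarray]
    offsets: list[np.ndarray]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be 0/1")
        for i, (on, off) in enumerate(zip(self.onsets, self.offsets)):
            if len(on) != len(off) or np.any(np.asarray(on) >= np.asarray(off)):
                raise ValueError(f"cell {i}: onsets/offsets inconsistent")

    @property
    def n_cells(self) -> int:
        return self.states.shape[1]

    @classmethod
    def from_states(cls, states: np.ndarray, time_s: np.ndarray) -> "BinaryActivity":
        """Derive onset/offset event times from a 0/1 state matrix.

        A run that is still active at the last frame is closed one frame
        step after the recording ends.
        """
        states = np.asarray(states).astype(np.int8)
        time_s = np.asarray(time_s, dtype=float)
        dt = float(time_s[1] - time_s[0]) if len(time_s) > 1 else 1.0
        onsets, offsets = [], []
        for i in range(states.shape[1]):
            on_idx, off_idx = _run_bounds(states[:, i])
            on_t = time_s[on_idx]
            off_t = np.where(
                off_idx < len(time_s), time_s[np.minimum(off_idx, len(time_s) - 1)],
                time_s[-1] + dt,
            )
            onsets.append(on_t)
            offsets.append(off_t)
        return cls(states=states, time_s=time_s, onsets=onsets, offsets=offsets)


@dataclass
class SignalingParams:
    """Per-cell signaling parameters over an analysis window.

    ``dur_s`` is NaN for cells with no oscillation in the window (undefined,
    not zero). ``response_time_s`` is NaN for non-responders.
    """

    active_time: np.ndarray
    freq_hz: np.ndarray
    dur_s: np.ndarray
    response_time_s: np.ndarray
    first_responder: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if np.any((self.active_time < 0) | (self.active_time > 1)):
            raise ValueError("active_time must lie in [0, 1]")
        if np.any(self.freq_hz < 0):
            raise ValueError("freq_hz must be non-negative")


def _run_bounds(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and stop (exclusive) frame indices of runs of 1s."""
    padded = np.concatenate(([0], x, [0]))
    d = np.diff(padded)
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1)


def _sos_filtfilt(values: np.ndarray, sos: np.ndarray) -> np.ndarray:
    # padlen capped so short traces remain filterable
    padlen = min(3 * (2 * sos.shape[0] + 1) * 10, values.shape[0] - 1)
    return _sig.sosfiltfilt(sos, values, axis=0, padlen=padlen)


def bandpass_zero_lag(ts: TraceSet, f_lo: float = DEFAULT_BAND_HZ[0],
                      f_hi: float = DEFAULT_BAND_HZ[1], order: int = 4) -> TraceSet:
    """Zero-phase Butterworth band-pass (forward-backward filtering).

    Removes baseline drift and the DC component while preserving peak
    timing (zero lag).
    """
    nyq = ts.sampling_hz / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise InvalidCutoffError(
            f"require 0 < f_lo < f_hi < Nyquist ({nyq:g} Hz); got [{f_lo}, {f_hi}]")
    sos = _sig.butter(order, [f_lo, f_hi], btype="bandpass", fs=ts.sampling_hz,
                      output="sos")
    return ts.with_values(_sos_filtfilt(ts.values, sos))


def highpass_zero_lag(ts: TraceSet, f_c: float = DEFAULT_HIGHPASS_HZ,
                      order: int = 4) -> TraceSet:
    """Zero-phase Butterworth high-pass; strongly attenuates slow drifts."""
    nyq = ts.sampling_hz / 2.0
    if not (0 < f_c < nyq):
        raise InvalidCutoffError(f"require 0 < f_c < Nyquist ({nyq:g} Hz); got {f_c}")
    sos = _sig.butter(order, f_c, btype="highpass", fs=ts.sampling_hz, output="sos")
    return ts.with_values(_sos_filtfilt(ts.values, sos))


def smooth_adjacent(ts: TraceSet, window: int = 5) -> TraceSet:
    """Centered moving average with shrinking windows at the edges.

    ``window`` must be odd; ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return ts.with_values(ts.values.copy())
    half = window // 2
    csum = np.cumsum(np.vstack([np.zeros((1, ts.n_cells)), ts.values]), axis=0)
    n = ts.n_frames
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return ts.with_values(out)


def binarize(ts_filtered: TraceSet, theta_amp: float = DEFAULT_THETA_AMP,
             min_dur_s: float | None = None) -> BinaryActivity:
    """Binarize filtered/smoothed traces by a robust amplitude threshold.

    A cell is active where its signal exceeds ``median + theta_amp *
    (p95 - median)``.  Active runs shorter than ``min_dur_s`` are removed,
    then gaps shorter than ``min_dur_s / 2`` are bridged.  Cells with zero
    robust amplitude are marked inactive with a warning.
    """
    if not 0 < theta_amp < 1:
        raise ValueError("theta_amp must lie in (0, 1)")
    if min_dur_s is None:
        min_dur_s = 3.0 / ts_filtered.sampling_hz
    min_frames = max(1, int(round(min_dur_s * ts_filtered.sampling_hz)))
    gap_frames = max(1, int(round(min_dur_s * ts_filtered.sampling_hz / 2.0)))

    v = ts_filtered.values
    med = np.median(v, axis=0)
    amp = np.percentile(v, 95, axis=0) - med
    states = np.zeros(v.shape, dtype=np.int8)
    flat = amp <= 1e-12
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} flat cell(s) marked inactive (zero robust amplitude)",
            stacklevel=2)
    active = v > (med + theta_amp * amp)
    active[:, flat] = False
    for i in range(v.shape[1]):
        col = active[:, i].astype(np.int8)
        col = _drop_short_runs(col, min_frames)
        col = _bridge_short_gaps(col, gap_frames)
        states[:, i] = col
    return BinaryActivity.from_states(states, ts_filtered.time_s)


def _drop_short_runs(col: np.ndarray, min_frames: int) -> np.ndarray:
    on, off = _run_bounds(col)
    for s, e in zip(on, off):
        if e - s < min_frames:
            col[s:e] = 0
    return col


def _bridge_short_gaps(col: np.ndarray, gap_frames: int) -> np.ndarray:
    on, off = _run_bounds(col)
    for k in range(len(on) - 1):
        if on[k + 1] - off[k] < gap_frames:
            col[off[k]:on[k + 1]] = 1
    return col


def signaling_params(ba: BinaryActivity, window: tuple[float, float],
                     stim_onset_s: float | None = None,
                     response_time_s: np.ndarray | None = None) -> SignalingParams:
    """Per-cell active time, oscillation frequency and mean duration.

    ``active_time`` is the fraction of window frames spent active;
    ``freq_hz`` counts onsets inside the window divided by its length;
    ``dur_s`` averages offset-onset over oscillations starting inside the
    window (NaN when there are none).
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must satisfy t0 < t1")
    in_win = (ba.time_s >= t0) & (ba.time_s < t1)
    if not in_win.any():
        raise ValueError("analysis window contains no frames")
    n = ba.n_cells
    active_time = ba.states[in_win].mean(axis=0)
    freq = np.empty(n)
    dur = np.full(n, np.nan)
    for i in range(n):
        sel = (ba.onsets[i] >= t0) & (ba.onsets[i] < t1)
        freq[i] = sel.sum() / (t1 - t0)
        if sel.any():
            dur[i] = float(np.mean(ba.offsets[i][sel] - ba.onsets[i][sel]))
    if response_time_s is None:
        response_time_s = np.full(n, np.nan)
    return SignalingParams(active_time=active_time, freq_hz=freq, dur_s=dur,
                           response_time_s=np.asarray(response_time_s, dtype=float))


def detect_response_time(ts: TraceSet, stim_onset_s: float | None = None,
                         k_sd: float = 3.0, hold_s: float = 2.0,
                         baseline_s: float = 30.0,
                         smooth_window: int | None = None) -> np.ndarray:
    """Per-cell delay (s) from stimulation to the first sustained rise.

    The raw trace is smoothed by adjacent averaging; the response time is
    the first post-stimulus time at which the smoothed signal stays above
    ``baseline median + k_sd * baseline SD`` for at least ``hold_s``.
    Returns NaN for cells that never cross (non-responders).
    """
    stim = ts.stim_onset_s if stim_onset_s is None else stim_onset_s
    if not (ts.time_s[0] <= stim <= ts.time_s[-1]):
        raise ValueError("stim_onset_s outside the recording")
    if stim - ts.time_s[0] < baseline_s:
        raise ValueError(f"need >= {baseline_s:g} s of pre-stimulus baseline")
    if smooth_window is None:
        smooth_window = max(1, int(round(0.5 * ts.sampling_hz)) | 1)
    sm = smooth_adjacent(ts, smooth_window).values
    base = (ts.time_s >= stim - baseline_s) & (ts.time_s < stim)
    thr = np.median(sm[base], axis=0) + k_sd * np.std(sm[base], axis=0)
    hold = max(1, int(round(hold_s * ts.sampling_hz)))
    post = ts.time_s > stim
    out = np.full(ts.n_cells, np.nan)
    for i in range(ts.n_cells):
        above = (sm[:, i] > thr[i]) & post
        on, off = _run_bounds(above.astype(np.int8))
        for s, e in zip(on, off):
            if e - s >= hold:
                out[i] = ts.time_s[s] - stim
                break
    return out


def top_sextile(scores: np.ndarray, largest: bool = True,
                eligible: np.ndarray | None = None) -> np.ndarray:
    """Flag the top ceil(N/6) cells by score (ties broken by cell index).

    ``largest=False`` selects the smallest scores. NaN scores and cells
    outside ``eligible`` are never flagged; N counts all cells.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    k = math.ceil(n / 6)
    ok = np.isfinite(scores)
    if eligible is not None:
        ok &= np.asarray(eligible, dtype=bool)
    if not ok.any():
        raise ValueError("no eligible cells to rank")
    key = scores.copy()
    if largest:
        key[~ok] = -np.inf
        order = np.lexsort((np.arange(n), -key))
    else:
        key[~ok] = np.inf
        order = np.lexsort((np.arange(n), key))
    chosen = order[:k]
    chosen = chosen[ok[chosen]]
    flags = np.zeros(n, dtype=bool)
    flags[chosen] = True
    return flags


def first_responders(params: SignalingParams) -> np.ndarray:
    """Flag the earliest-responding sextile (ceil(N/6) cells) as first responders."""
    rt = params.response_time_s
    if not np.isfinite(rt).any():
        raise ValueError("all cells are non-responders")
    return top_sextile(rt, largest=False)
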