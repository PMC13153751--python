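"""Sensor-stream cleaning and event windowing.

The inertial pipeline is: (1) regrid to a uniform 60 Hz time base with
per-channel linear interpolation of missing values, (2) zero-phase
low-pass filtering at 20 Hz, (3) extraction of the three event windows
around each input event — the 10 frames immediately before it, the
average value at the event time, and the 10 frames immediately after.

Filtering is done on the full stream before windowing.  The 20 Hz cutoff
at a 60 Hz rate sits at 2/3 of Nyquist, so the Butterworth design is
realized as second-order sections for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from gripsense.errors import DataError
from gripsense.session import SENSOR_CHANNELS, InertialStream

NOMINAL_RATE_HZ = 60.0


@dataclass
class EventWindows:
    """Pre / during / post sensor windows around one input event.

    ``pre`` and ``post`` are (10, 9) channel matrices (rows in time
    order); ``during`` is the (9,) average over a one-frame-wide interval
    centered on the anchor.  ``pre_padded`` / ``post_padded`` count frames
    that had to be synthesized by repeating the terminal frame when the
    stream did not extend far enough.
    """

    pre: np.ndarray
    during: np.ndarray
    post: np.ndarray
    anchor_t: float
    pre_padded: int = 0
    post_padded: int = 0

WINDOW_FRAMES = 10


def interpolate_missing(stream: InertialStream,
                        fs: float = NOMINAL_RATE_HZ) -> InertialStream:
    """Regrid to uniform ``fs`` and linearly interpolate missing values.

    Interior NaNs (and dropped frames, which appear as grid gaps) are
    filled per channel by linear interpolation; values before the first or
    after the last valid sample are extended with the nearest valid value.
    Idempotent on already-clean uniform streams.
    """
    if len(stream) < 2:
        raise DataError("inertial stream needs at least 2 frames to interpolate")
    t0, t1 = float(stream.t[0]), float(stream.t[-1])
    n = int(round((t1 - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    src = stream.matrix()
    out = np.empty((n, src.shape[1]))
    for c in range(src.shape[1]):
        valid = np.isfinite(src[:, c])
        if valid.sum() < 2:
            raise DataError(
                f"channel {SENSOR_CHANNELS[c]} has fewer than 2 valid frames")
        out[:, c] = np.interp(grid, stream.t[valid], src[valid, c])
    return InertialStream.from_matrix(grid, out)


def lowpass(stream: InertialStream, cutoff: float = 20.0,
            fs: float = NOMINAL_RATE_HZ, order: int = 4) -> InertialStream:
    """Zero-phase Butterworth low-pass, applied forward-backward per channel."""
    src = stream.matrix()
    if not np.all(np.isfinite(src)):
        raise DataError("lowpass requires a gap-free stream; interpolate first")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if len(stream) <= padlen:
        raise DataError(
            f"stream of {len(stream)} frames too short for zero-phase "
            f"filtering; need more than {padlen} frames")
    out = signal.sosfiltfilt(sos, src, axis=0)
    return InertialStream.from_matrix(stream.t.copy(), out)


def extract_windows(stream: InertialStream, anchor_t: float,
                    fs: float = NOMINAL_RATE_HZ) -> EventWindows:
    """The 10-frame pre window, during-input average, and 10-frame post window.

    ``pre`` holds the 10 frames with the largest t strictly below the
    anchor, ``post`` the 10 with the smallest t strictly above it; a side
    with fewer than 10 available frames is padded by repeating its
    terminal frame, and the pad counts are recorded.  ``during`` averages
    frames within half a frame period (1/(2 fs)) of the anchor, falling
    back to the nearest frame if that interval is empty.
    """
    if len(stream) == 0:
        raise DataError("cannot window an empty stream")
    m = stream.matrix()
    t = stream.t

    i_pre = np.nonzero(t < anchor_t)[0]
    i_post = np.nonzero(t > anchor_t)[0]

    pre_rows = m[i_pre[-WINDOW_FRAMES:]] if i_pre.size else np.empty((0, m.shape[1]))
    post_rows = m[i_post[:WINDOW_FRAMES]] if i_post.size else np.empty((0, m.shape[1]))

    def pad(rows: np.ndarray, at_start: bool) -> tuple[np.ndarray, int]:
        missing = WINDOW_FRAMES - rows.shape[0]
        if missing <= 0:
            return rows, 0
        if rows.shape[0] == 0:
            # no frames on this side at all: repeat the stream's edge frame
            edge = m[0] if at_start else m[-1]
            return np.tile(edge, (WINDOW_FRAMES, 1)), missing
        edge = rows[0] if at_start else rows[-1]
        fill = np.tile(edge, (missing, 1))
        return (np.vstack([fill, rows]) if at_start
                else np.vstack([rows, fill])), missing

    pre, n_pre_pad = pad(pre_rows, at_start=True)
    post, n_post_pad = pad(post_rows, at_start=False)

    half = 1.0 / (2.0 * fs)
    near = np.abs(t - anchor_t) <= half + 1e-12
    if near.any():
        during = m[near].mean(axis=0)
    else:
        during = m[np.argmin(np.abs(t - anchor_t))].copy()

    return EventWindows(pre=pre, during=during, post=post, anchor_t=anchor_t,
                        pre_padded=n_pre_pad, post_padded=n_post_pad)


def preprocess_stream(stream: InertialStream, cutoff: float = 20.0,
                      fs: float = NOMINAL_RATE_HZ, order: int = 4
                      ) -> InertialStream:
    """interpolate_missing followed by lowpass — the standard pipeline."""
    return lowpass(interpolate_missing(stream, fs=fs), cutoff=cutoff,
                   fs=fs, order=order)
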