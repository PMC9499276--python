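"""Task event detection.

SLS: the movement onset is the first instant where a trailing 10-sample
moving SD of the tibia pitch exceeds twice the SD of the initial
1000-sample static interval (both sides carry the same presentation
scaling, so the factor cancels); peak flexion is the pitch maximum; the
task end is the first return of the pitch into a band around its onset
value.

CHT: take-offs are the first crossings of the |angular velocity|
derivative below −0.6 rad/s²; each landing is the first local maximum of
the |acceleration| derivative (jerk) above 7 m/s³ after its take-off.  A
refractory period after each detected event resolves multiple crossings
within one hop.  Both derivative signals may be pre-smoothed by a centred
moving average: smoothing is required for noisy data (the raw derivative
noise floor at 500 Hz exceeds both thresholds) and biases the take-off
crossing early by roughly half the smoothing support; the defaults keep
that bias under 10 ms.  Noise-free signals can be segmented with
``smooth=1`` (no smoothing), which recovers events to within one sample.

CMJ: the end of the unweighting phase is the first inflection point
(zero-crossing of the smoothed second derivative) of the vertical GRF
after the force drops below body weight by an onset band; flight starts
when the force falls to the flight threshold (force plates carry a noise
floor, so "zero" is implemented as ≤ 5 N by default).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (InvalidConfigError, NoFlightError, NoMovementError,
                     TooShortWindowError, UnbalancedEventsError)
from .types import GrfRecording, ImuRecording, OrientationSeries, TaskEvents

__all__ = ["moving_sd", "segment_sls", "segment_cht", "segment_cmj"]


def moving_sd(x, window: int) -> np.ndarray:
    """Trailing moving sample SD.

    Element ``i`` is the SD of ``x[i-window+1 : i+1]``; the first
    ``window-1`` elements are filled with the first valid value.
    """
    x = np.asarray(x, dtype=float)
    if window < 2:
        raise InvalidConfigError(f"window must be >= 2, got {window}")
    if window > len(x):
        raise TooShortWindowError(
            f"window {window} exceeds signal length {len(x)}")
    out = pd.Series(x).rolling(window).std(ddof=1).to_numpy()
    out[:window - 1] = out[window - 1]
    return out


def _smooth(x, window: int) -> np.ndarray:
    """Centred moving average with reflected edges; window 1 = identity."""
    if window <= 1:
        return np.asarray(x, dtype=float)
    if window % 2 == 0:
        window += 1
    h = window // 2
    xp = np.pad(np.asarray(x, dtype=float), h, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(xp, kernel, mode="valid")


def segment_sls(pitch, fs: float, *, window: int = 10,
                static_samples: int = 1000, start_factor: float = 2.0,
                scale: float = 10.0, return_band_factor: float = 2.0,
                ) -> TaskEvents:
    """Segment a single-leg squat from the tibia pitch signal (degrees).

    ``scale`` multiplies both the moving SD and the static threshold (a
    presentation factor — it cancels in the comparison and is kept only to
    mirror the protocol's published form).
    """
    pitch = np.asarray(pitch, dtype=float)
    if len(pitch) <= static_samples:
        raise TooShortWindowError(
            f"signal has {len(pitch)} samples; needs more than the "
            f"{static_samples}-sample static interval")
    sd_static = float(np.std(pitch[:static_samples], ddof=1))
    sigma = moving_sd(pitch, window) * scale
    above = sigma > start_factor * (sd_static * scale)
    if not above.any():
        raise NoMovementError(
            "moving SD never exceeded the static threshold "
            f"({start_factor} × {sd_static * scale:.3g})")
    i_start = int(np.argmax(above))
    i_epe = int(np.argmax(pitch))
    if i_epe <= i_start:
        raise NoMovementError(
            "pitch maximum precedes the detected onset; no squat present")
    band = return_band_factor * sd_static
    returned = np.nonzero(pitch[i_epe + 1:] <= pitch[i_start] + band)[0]
    if len(returned):
        i_end = int(i_epe + 1 + returned[0])
    else:
        warnings.warn("pitch never returned to its initial value; "
                      "reporting the last sample as the task end",
                      stacklevel=2)
        i_end = len(pitch) - 1
    return TaskEvents(task="SLS", fs=fs, i_start=i_start, i_epe=i_epe,
                      i_end=i_end)


def segment_cht(foot_rec: ImuRecording,
                foot_orient: OrientationSeries | None = None, *,
                to_threshold: float = -0.6, la_threshold: float = 7.0,
                refractory: float = 0.2, t_risk: float = 0.1,
                gyro_smooth: int = 9, acc_smooth: int = 81) -> TaskEvents:
    """Detect take-offs, landings and risk windows of a triple hop.

    Operates on vector norms of the (bias-corrected) foot gyroscope and
    accelerometer, which are rotation invariant — the orientation series,
    when provided, is accepted for interface compatibility but not needed.

    Landing detection is two-stage: a candidate is the first local maximum
    of the heavily smoothed jerk above threshold (robust against the
    derivative noise floor), then the landing index is refined to the raw
    jerk maximum in a forward window spanning the smoothing support — the
    physical jerk peak exceeds the raw noise by orders of magnitude, so the
    refinement is sample-accurate and free of the smoothing lag.
    """
    fs = foot_rec.fs
    dt = 1.0 / fs
    n = len(foot_rec)
    gn = _smooth(np.linalg.norm(foot_rec.gyro, axis=1), gyro_smooth)
    an_raw = np.linalg.norm(foot_rec.acc, axis=1)
    an = _smooth(an_raw, acc_smooth)
    dg = np.gradient(gn, dt)
    jerk = np.gradient(an, dt)
    jerk_raw = np.gradient(an_raw, dt)

    refr = int(round(refractory * fs))
    to_idx, la_idx = [], []
    cursor = 0
    while True:
        below = np.nonzero(dg[cursor:] < to_threshold)[0]
        if len(below) == 0:
            break
        i_to = cursor + int(below[0])
        to_idx.append(i_to)
        # landing: first local maximum of the jerk above threshold after TO
        i_la = None
        for i in range(i_to + 1, n - 1):
            if (jerk[i] > la_threshold and jerk[i] > jerk[i - 1]
                    and jerk[i] >= jerk[i + 1]):
                stop = min(n, i + max(acc_smooth, 2))
                i_la = i + int(np.argmax(jerk_raw[i:stop]))
                break
        if i_la is None:
            raise UnbalancedEventsError(
                f"{len(to_idx)} take-off(s) but only {len(la_idx)} "
                f"landing(s) detected; no jerk peak above "
                f"{la_threshold} m/s³ after the take-off at sample {i_to}",
                takeoffs=to_idx, landings=la_idx)
        la_idx.append(i_la)
        cursor = i_la + refr
        if cursor >= n:
            break

    w = int(round(t_risk * fs))
    windows = []
    for la in la_idx:
        stop = la + w
        if stop > n:
            warnings.warn("risk window truncated at the end of the "
                          "recording", stacklevel=2)
            stop = n
        windows.append((la, stop))
    return TaskEvents(task="CHT", fs=fs, to=to_idx, la=la_idx,
                      risk_windows=windows)


def segment_cmj(grf: GrfRecording, *, quiet_duration: float = 0.5,
                flight_threshold: float = 5.0, onset_band: float = 50.0,
                smooth_window: int = 11, d2_window: int = 151):
    """Segment a countermovement jump from the vertical GRF.

    The second derivative used for the inflection rule is estimated by a
    cubic Savitzky–Golay fit over ``d2_window`` samples, which keeps the
    plate-noise amplification of double differentiation well below the
    curvature scale of the unweighting dip.

    Returns ``(events, net_force)`` where ``net_force`` is the
    weight-subtracted force over ``[i_unweight_end, i_flight_start)`` in
    newtons.
    """
    fs = grf.fs
    dt = 1.0 / fs
    nq = int(round(quiet_duration * fs))
    bw = float(grf.grfv[:nq].mean())
    sm = _smooth(grf.grfv, smooth_window)
    d2 = sps.savgol_filter(grf.grfv, d2_window, 3, deriv=2, delta=dt)

    onset = np.nonzero(sm < bw - onset_band)[0]
    if len(onset) == 0:
        raise NoFlightError(
            "force never dropped below body weight minus the onset band; "
            "no countermovement present")
    i_onset = int(onset[0])
    # first concave-up -> concave-down transition after the onset: the
    # point of steepest force rise, where the vertical velocity crosses
    # zero and from which the net-force integral equals the take-off
    # momentum
    down = (d2[i_onset:-1] > 0) & (d2[i_onset + 1:] <= 0)
    flips = np.nonzero(down)[0]
    if len(flips) == 0:
        raise NoFlightError("no inflection point after the unweighting "
                            "onset")
    i_ue = int(i_onset + 1 + flips[0])

    flight = np.nonzero(grf.grfv[i_ue:] <= flight_threshold)[0]
    if len(flight) == 0:
        raise NoFlightError(
            f"force never reached the {flight_threshold} N flight "
            "threshold")
    i_fs = int(i_ue + flight[0])

    events = TaskEvents(task="CMJ", fs=fs, i_unweight_end=i_ue,
                        i_flight_start=i_fs)
    net_force = grf.grfv[i_ue:i_fs] - bw
    return events, net_force
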