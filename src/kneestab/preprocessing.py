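"""Raw-signal conditioning: gyroscope bias removal and orientation fusion.

The orientation estimator is a quaternion error-state complementary filter:
the gyroscope is integrated sample-by-sample, with proportional feedback of
two vector errors — the mismatch between the measured (normalized)
acceleration and the predicted gravity direction, weighted by ``k1`` (1/s),
and the heading component of the magnetometer mismatch, weighted by ``k2``
(1/s).  ``k1``/``k2`` thus express the confidence placed in accelerometer
and magnetometer against gyro integration; the defaults (2.33 and 7.44) are
the gains used throughout the knee-stability protocol.

The initial orientation is computed deterministically by a TRIAD fit of the
mean accelerometer and magnetometer vectors over the initial still window,
so there is no gyro drift at t = 0 and ``pitch_y(0) = 0`` for a still start.

Sign convention (declared, since the pitch sign is otherwise ambiguous):
``pitch_y`` is the rotation about the sensor y-axis relative to the initial
posture, positive for knee flexion (the tibia-mounted sensor inclining
forward).  An inverted mounting of the y-axis may be declared via
``ImuRecording.y_flipped``, which restores the positive-flexion convention.
"""
from __future__ import annotations

import warnings

import numpy as np

from .errors import (InitializationError, TooShortWindowError,
                     WrongSensorError)
from .types import G, ImuRecording, OrientationSeries

__all__ = ["remove_gyro_bias", "estimate_orientation", "tibia_pitch",
           "triad_init"]


def remove_gyro_bias(rec: ImuRecording, still_window=(0, 1000),
                     stillness_threshold: float = np.deg2rad(2.0),
                     ) -> ImuRecording:
    """Subtract the per-axis mean gyroscope reading over a still window.

    Parameters
    ----------
    still_window : (start, stop) sample-index range at the beginning of the
        recording during which the sensor was verified still.
    stillness_threshold : rad/s. If the gyro SD over the window exceeds this,
        a warning (not an error) is issued with the measured SD.

    Returns a new recording; acceleration and magnetometer are untouched.
    """
    start, stop = int(still_window[0]), int(still_window[1])
    if stop - start < 100:
        raise TooShortWindowError(
            f"still window has {stop - start} samples; need >= 100")
    seg = rec.gyro[start:stop]
    sd = seg.std(axis=0, ddof=1)
    if np.any(sd > stillness_threshold):
        warnings.warn(
            "gyro stillness check failed: per-axis SD = "
            f"{np.array2string(sd, precision=5)} rad/s exceeds "
            f"{stillness_threshold:.5f} rad/s", stacklevel=2)
    bias = seg.mean(axis=0)
    return ImuRecording(t=rec.t.copy(), acc=rec.acc.copy(),
                        gyro=rec.gyro - bias, mag=rec.mag.copy(),
                        fs=rec.fs, location=rec.location,
                        y_flipped=rec.y_flipped)


def triad_init(acc_mean: np.ndarray, mag_mean: np.ndarray) -> np.ndarray:
    """Sensor-to-global rotation from mean still accelerometer/magnetometer.

    The global frame has z up and x along the horizontal projection of the
    magnetic field.  Raises if the acceleration norm is not gravitational
    (>50% off g) or the magnetic field is parallel to gravity.
    """
    na = np.linalg.norm(acc_mean)
    if not 0.5 * G <= na <= 1.5 * G:
        raise InitializationError(
            f"still-window acceleration norm {na:.2f} m/s² deviates more "
            f"than 50% from g; sensor not still or not calibrated")
    z_b = acc_mean / na
    y_raw = np.cross(z_b, mag_mean)
    ny = np.linalg.norm(y_raw)
    if ny < 1e-9 * np.linalg.norm(mag_mean):
        raise InitializationError(
            "magnetic field parallel to gravity; heading unobservable")
    y_b = y_raw / ny
    x_b = np.cross(y_b, z_b)
    # rows are the body-frame axes that map to global x, y, z
    return np.array([x_b, y_b, z_b])


def _quat_mul(p, q):
    w1, x1, y1, z1 = p
    w2, x2, y2, z2 = q
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _quat_from_rotvec(v):
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]])
    axis = v / angle
    s = np.sin(0.5 * angle)
    return np.array([np.cos(0.5 * angle), s * axis[0], s * axis[1],
                     s * axis[2]])


def _quat_to_mat(q):
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _mat_to_quat(R):
    w = 0.5 * np.sqrt(max(0.0, 1.0 + R[0, 0] + R[1, 1] + R[2, 2]))
    if w > 1e-8:
        x = (R[2, 1] - R[1, 2]) / (4 * w)
        y = (R[0, 2] - R[2, 0]) / (4 * w)
        z = (R[1, 0] - R[0, 1]) / (4 * w)
        return np.array([w, x, y, z])
    # fall back on the dominant diagonal element
    i = int(np.argmax(np.diag(R)))
    j, k = (i + 1) % 3, (i + 2) % 3
    s = np.sqrt(max(1e-12, 1.0 + R[i, i] - R[j, j] - R[k, k]))
    q = np.empty(4)
    q[0] = (R[k, j] - R[j, k]) / (2 * s)
    q[1 + i] = 0.5 * s
    q[1 + j] = (R[j, i] + R[i, j]) / (2 * s)
    q[1 + k] = (R[k, i] + R[i, k]) / (2 * s)
    return q


def estimate_orientation(rec: ImuRecording, k1: float = 2.33,
                         k2: float = 7.44, init_window: int | None = None,
                         init_rotation: np.ndarray | None = None,
                         ) -> OrientationSeries:
    """Run the complementary filter over a (bias-corrected) recording.

    Parameters
    ----------
    k1, k2 : proportional feedback gains (1/s) for the gravity and heading
        corrections.  ``k1 = k2 = 0`` reduces to pure gyro integration.
    init_window : number of initial still samples used for the TRIAD
        initialisation (default: one second of data).
    init_rotation : optional sensor-to-global rotation overriding the TRIAD
        fit (used e.g. to study convergence from a deliberately wrong start).
    """
    n = len(rec)
    dt = 1.0 / rec.fs
    if init_window is None:
        init_window = min(n, int(round(rec.fs)))
    acc0 = rec.acc[:init_window].mean(axis=0)
    mag0 = rec.mag[:init_window].mean(axis=0)
    R0 = triad_init(acc0, mag0) if init_rotation is None else \
        np.asarray(init_rotation, dtype=float)
    # global-frame magnetic reference consistent with the initial fit
    m0 = mag0 / np.linalg.norm(mag0)
    b_ref = R0 @ m0

    q = _mat_to_quat(R0)
    e_z = np.array([0.0, 0.0, 1.0])
    rotations = np.empty((n, 3, 3))
    global_acc = np.empty((n, 3))
    pitch = np.empty(n)
    R_init = R0.copy()

    for i in range(n):
        R = _quat_to_mat(q)
        omega = rec.gyro[i].copy()
        if k1 != 0.0 or k2 != 0.0:
            a = rec.acc[i]
            na = np.sqrt(a[0] * a[0] + a[1] * a[1] + a[2] * a[2])
            if na > 1e-9 and k1 != 0.0:
                v_g = R.T @ e_z
                omega += k1 * np.cross(a / na, v_g)
            m = rec.mag[i]
            nm = np.sqrt(m[0] * m[0] + m[1] * m[1] + m[2] * m[2])
            if nm > 1e-9 and k2 != 0.0:
                v_g = R.T @ e_z
                v_m = R.T @ b_ref
                e_m = np.cross(m / nm, v_m)
                # restrict the magnetometer to heading (yaw) correction
                omega += k2 * np.dot(e_m, v_g) * v_g
        rotations[i] = R
        global_acc[i] = R @ rec.acc[i]
        R_rel = R_init.T @ R
        pitch[i] = np.degrees(np.arctan2(R_rel[0, 2], R_rel[0, 0]))
        q = _quat_mul(q, _quat_from_rotvec(omega * dt))
        q /= np.linalg.norm(q)

    if rec.y_flipped:
        pitch = -pitch
    return OrientationSeries(t=rec.t.copy(), pitch_y=pitch,
                             global_acc=global_acc, rotations=rotations,
                             fs=rec.fs, location=rec.location, k1=k1, k2=k2)


def tibia_pitch(series: OrientationSeries) -> np.ndarray:
    """Knee-flexion angle signal (degrees) from a tibia-mounted sensor."""
    if series.location != "tibia":
        raise WrongSensorError(
            f"tibia pitch requested from a {series.location!r} recording")
    return series.pitch_y
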