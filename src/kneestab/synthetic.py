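"""Synthetic IMU and force-plate signal generator.

The generator produces physiologically shaped signals with known ground
truth so every downstream stage (fusion, segmentation, features,
reliability) is verifiable without recorded data.  It emulates

* single-leg-squat (SLS) trials: a raised-cosine knee-flexion excursion of
  the tibia sensor (smooth descent to a peak and return, zero end
  velocities), with full rotational consistency — gyroscope, gravity and
  lever-arm motion acceleration, and magnetometer are all generated from
  the same analytic rotation;
* crossover-hop (CHT) trials: triple-hop signal-magnitude morphology on the
  foot and tibia sensors — the angular-velocity magnitude falls sharply only
  at take-offs, and each landing injects a rapid acceleration rise whose
  jerk peak marks the landing instant;
* countermovement-jump (CMJ) vertical ground-reaction-force traces built
  from a cubic net-acceleration profile solved so that force reaches zero
  exactly at take-off, take-off velocity equals √(2·g·h), and the body's
  vertical velocity is zero exactly at the single inflection point of the
  unweighting curve (so integrating net force from that instant reproduces
  the impulse–momentum identity);
* feature cohorts with a prescribed between/within-subject variance
  structure, hence a known true intraclass correlation
  σ_b²/(σ_b²+σ_w²), for reliability-recovery experiments.

All randomness flows through explicitly passed seeds; identical
configuration and seed give bit-identical output.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal as sps

from .errors import InvalidConfigError
from .types import FeatureRecord, G, GroundTruth, GrfRecording, ImuRecording

__all__ = ["SimConfig", "HopParams", "simulate_sls", "simulate_cht",
           "simulate_cmj_grf", "simulate_cohort", "DEFAULT_COHORT_PARAMS"]


#: cohort variance structure: parameter -> (cohort mean, between-subject SD,
#: within-subject SD).  Values follow the magnitudes typical of healthy
#: soccer players on these tasks (tibia/foot sensors, °/s and m/s² scales).
DEFAULT_COHORT_PARAMS = {
    # between/within split chosen so σ_b²/(σ_b²+σ_w²) reproduces typical
    # test-retest ICCs of 0.6-0.8 at the printed cohort SDs
    "T_tot":      (2.2, 1.1 * np.sqrt(0.66), 1.1 * np.sqrt(0.34)),
    "RMSa_leg":   (0.6, 0.2 * np.sqrt(0.64), 0.2 * np.sqrt(0.36)),
    "RMSw_leg":   (28.6, 5.6 * np.sqrt(0.66), 5.6 * np.sqrt(0.34)),
    "wpeak_leg":  (74.5, 22.8 * np.sqrt(0.60), 22.8 * np.sqrt(0.40)),
    "SP":         (192.3, 70.3 * np.sqrt(0.60), 70.3 * np.sqrt(0.40)),
}


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults reproduce the protocol's acquisition setup: two MIMUs at
    500 Hz (±16 g, ±2000 °/s, ±4800 µT), force plates at 1000 Hz, three
    repetitions per condition, seventeen subjects.  Noise SDs are
    datasheet-typical white-noise levels for this sensor class at the full
    500 Hz bandwidth; the gyroscope carries a constant per-axis bias.
    """

    sampling_rate_imu: float = 500.0
    sampling_rate_grf: float = 1000.0
    gyro_bias: tuple = (0.01, -0.02, 0.005)       # rad/s
    noise_sd_acc: float = 0.02                    # m/s²
    noise_sd_gyro: float = 0.002                  # rad/s
    noise_sd_mag: float = 0.3                     # µT
    noise_sd_grf: float = 2.0                     # N
    n_subjects: int = 17
    n_trials: int = 3
    between_subject_sd: dict = field(default_factory=dict)
    within_subject_sd: dict = field(default_factory=dict)
    cohort_means: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate_imu <= 0 or self.sampling_rate_grf <= 0:
            raise InvalidConfigError("sampling rates must be > 0")
        for name in ("noise_sd_acc", "noise_sd_gyro", "noise_sd_mag",
                     "noise_sd_grf"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.n_trials < 2:
            raise InvalidConfigError(
                "n_trials must be >= 2 for reliability analysis")
        if not self.between_subject_sd:
            self.between_subject_sd = {
                k: v[1] for k, v in DEFAULT_COHORT_PARAMS.items()}
        if not self.within_subject_sd:
            self.within_subject_sd = {
                k: v[2] for k, v in DEFAULT_COHORT_PARAMS.items()}
        if not self.cohort_means:
            self.cohort_means = {
                k: v[0] for k, v in DEFAULT_COHORT_PARAMS.items()}


# earth magnetic field in the global frame (x horizontal, z up), µT
B_EARTH = np.array([22.0, 0.0, -42.0])


def _rng(config: SimConfig, seed):
    return np.random.default_rng(config.seed if seed is None else seed)


def _band_limited(rng, n, fs, sd, fc=3.0):
    """Smooth (low-pass filtered) noise rescaled to a target SD."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n + 400)
    b, a = sps.butter(2, fc / (fs / 2.0))
    x = sps.filtfilt(b, a, white)[200:200 + n]
    s = x.std()
    return x * (sd / s) if s > 0 else np.zeros(n)


def _transition_profile(t, segments, y0):
    """Piecewise raised-cosine profile.

    ``segments`` is a list of (t_start, t_end, y_target): the profile moves
    smoothly from its current level to ``y_target`` over [t_start, t_end]
    and holds the level in between.  Segments must be ordered and disjoint.
    """
    y = np.full_like(t, float(y0))
    level = float(y0)
    prev_end = -np.inf
    for (ts, te, yt) in segments:
        if te <= ts:
            raise InvalidConfigError("transition with non-positive duration")
        if ts < prev_end:
            raise InvalidConfigError(
                "overlapping signal transitions; phase durations too short "
                f"(segment starting at {ts:.3f}s overlaps previous)")
        prev_end = te
        m = (t >= ts) & (t < te)
        u = (t[m] - ts) / (te - ts)
        y[m] = level + (yt - level) * 0.5 * (1 - np.cos(np.pi * u))
        y[t >= te] = yt
        level = yt
    return y


# --------------------------------------------------------------------------
# single leg squat
# --------------------------------------------------------------------------

#: tibia sensor initial orientation (sensor x up, y medio-lateral);
#: columns are the body axes expressed in the global frame
_R0_TIBIA = np.array([[0.0, 0.0, -1.0],
                      [0.0, 1.0, 0.0],
                      [1.0, 0.0, 0.0]])


def simulate_sls(config: SimConfig, subject_scale: float = 1.0,
                 seed: int | None = None, *, peak_angle_deg: float = 75.0,
                 movement_duration: float = 4.4, still_duration: float = 2.5,
                 tail_duration: float = 1.0, lever_arm: float = 0.15,
                 sway_sd=(0.5, 0.15)):
    """Simulate one single-leg-squat trial.

    Returns ``(tibia, foot, ground_truth)``.  The tibia pitch trajectory is
    a raised cosine from 0 to ``peak_angle_deg * subject_scale`` and back
    over ``movement_duration`` seconds; ground truth records the movement
    onset (SLS_start), the peak-flexion instant (EPe) and the return to the
    initial posture (SLS_end).  ``sway_sd`` sets the medio-lateral /
    antero-posterior postural-sway acceleration SDs (m/s²) active during
    the movement.
    """
    fs = config.sampling_rate_imu
    if still_duration * fs < 1000:
        raise InvalidConfigError(
            f"still period of {still_duration} s at {fs} Hz is shorter than "
            "the 1000 samples required by the static-threshold rule")
    rng = _rng(config, seed)
    t0 = round(still_duration * fs) / fs
    T = round(movement_duration * fs) / fs
    n = int(round((still_duration + movement_duration + tail_duration) * fs))
    t = np.arange(n) / fs
    A = np.deg2rad(peak_angle_deg * subject_scale)

    u = t - t0
    inside = (u >= 0) & (u <= T)
    theta = np.where(inside, A / 2 * (1 - np.cos(2 * np.pi * u / T)), 0.0)
    dtheta = np.where(inside, A * np.pi / T * np.sin(2 * np.pi * u / T), 0.0)
    ddtheta = np.where(
        inside, 2 * A * np.pi ** 2 / T ** 2 * np.cos(2 * np.pi * u / T), 0.0)

    c, s = np.cos(theta), np.sin(theta)
    # lever-arm specific force: sensor at `lever_arm` m from the knee joint
    # along the tibia; p(t) = r*(sinθ, 0, cosθ) in the global frame
    pxx = lever_arm * (ddtheta * c - dtheta ** 2 * s)
    pzz = lever_arm * (-ddtheta * s - dtheta ** 2 * c)
    fg_x, fg_z = pxx, pzz + G          # add gravity reaction (global frame)
    # body frame: v_b = Ry(θ)^T R0^T v_g ; R0^T (x,y,z) = (z, y, -x)
    bx0, bz0 = fg_z, -fg_x
    acc = np.column_stack([c * bx0 - s * bz0,
                           np.zeros(n),
                           s * bx0 + c * bz0])
    # postural sway acceleration on the tibia transverse plane (y, z),
    # ramped in and out with the movement
    env = np.where(inside, np.sin(np.pi * np.clip(u / T, 0, 1)) ** 2, 0.0)
    acc[:, 1] += env * _band_limited(rng, n, fs, sway_sd[0] * subject_scale)
    acc[:, 2] += env * _band_limited(rng, n, fs, sway_sd[1] * subject_scale)

    gyro = np.column_stack([np.zeros(n), dtheta, np.zeros(n)])
    # body-frame magnetic field: Ry(θ)^T R0^T B
    mbx0, mby0, mbz0 = B_EARTH[2], B_EARTH[1], -B_EARTH[0]
    mag = np.column_stack([c * mbx0 - s * mbz0,
                           np.full(n, mby0),
                           s * mbx0 + c * mbz0])

    bias = np.asarray(config.gyro_bias, dtype=float)
    gyro = gyro + bias + rng.normal(0, config.noise_sd_gyro, (n, 3))
    acc = acc + rng.normal(0, config.noise_sd_acc, (n, 3))
    mag = mag + rng.normal(0, config.noise_sd_mag, (n, 3))
    tibia = ImuRecording(t=t, acc=acc, gyro=gyro, mag=mag, fs=fs,
                         location="tibia")

    # foot sensor: flat on the ground, x horizontal, z up; small residual
    # sway only
    facc = np.column_stack([np.zeros(n), np.zeros(n), np.full(n, G)])
    facc[:, 1] += env * _band_limited(rng, n, fs, 0.15 * subject_scale)
    facc[:, 2] += env * _band_limited(rng, n, fs, 0.05 * subject_scale)
    facc += rng.normal(0, config.noise_sd_acc, (n, 3))
    fgyro = np.tile(bias, (n, 1)) + rng.normal(
        0, config.noise_sd_gyro, (n, 3))
    fmag = np.tile(B_EARTH, (n, 1)) + rng.normal(
        0, config.noise_sd_mag, (n, 3))
    foot = ImuRecording(t=t, acc=facc, gyro=fgyro, mag=fmag, fs=fs,
                        location="foot")

    gt = GroundTruth(
        event_times={"SLS_start": t0, "EPe": t0 + T / 2, "SLS_end": t0 + T},
        true_parameter_values={
            "peak_angle_deg": peak_angle_deg * subject_scale,
            "T_tot": T / 2,
            "wpeak_leg": np.degrees(A * np.pi / T),
        })
    return tibia, foot, gt


# --------------------------------------------------------------------------
# crossover hop test
# --------------------------------------------------------------------------

@dataclass
class HopParams:
    """Per-hop flight/contact durations (s) for the triple hop."""

    flights: tuple = (0.30, 0.30, 0.30)
    contacts: tuple = (0.40, 0.40)     # contacts between consecutive hops

    def __post_init__(self):
        if len(self.flights) != 3 or len(self.contacts) != 2:
            raise InvalidConfigError("CHT needs 3 flights and 2 contacts")
        if min(self.flights) <= 0 or min(self.contacts) <= 0:
            raise InvalidConfigError("hop durations must be positive")


def _cht_channel(t, fs, to_times, la_times, *, push, flight, land, stance,
                 base, t_edge, t_land_rise, t_land_fall):
    """|signal| profile for one CHT angular-velocity-like channel."""
    segs = []
    for i, (to, la) in enumerate(zip(to_times, la_times)):
        segs.append((to - 0.25, to, push))           # push-off ramp-up
        segs.append((to, to + t_edge, flight))       # sharp fall at TO
        segs.append((la, la + t_land_rise, land))    # landing bump
        segs.append((la + t_land_rise, la + t_land_fall, stance))
    return _transition_profile(t, segs, base)


def simulate_cht(config: SimConfig, hop_params: HopParams | None = None,
                 seed: int | None = None, *, subject_scale: float = 1.0,
                 still_duration: float = 2.5, tail_duration: float = 1.0,
                 land_acc_peak: float = 120.0, land_gyro_peak: float = 20.0,
                 push_gyro: float = 8.0, to_edge_duration: float = 0.04,
                 hop_distance_mean: float = 4.9):
    """Simulate one crossover-hop trial.  Returns (foot, tibia, gt).

    Event morphology follows the operational definitions used for
    segmentation: the foot |angular velocity| rises during each push-off
    and falls sharply at take-off (the first −0.6 rad/s² crossing of its
    derivative marks TO); each landing injects a rapid acceleration-norm
    rise whose jerk peak (≫ 7 m/s³) marks LA.  Ground truth stores the
    analytic TO crossings and LA jerk-peak times.

    The generator reproduces the magnitude morphology of the signals; it
    does not enforce full 3-D rigid-body consistency between channels
    (segmentation and the risk-window features operate on vector norms,
    which are rotation invariant).
    """
    hp = hop_params or HopParams()
    fs = config.sampling_rate_imu
    rng = _rng(config, seed)

    t_to1 = round((still_duration + 0.5) * fs) / fs
    to_times, la_times = [], []
    cursor = t_to1
    for i in range(3):
        to_times.append(cursor)
        la = cursor + hp.flights[i]
        la_times.append(la)
        if i < 2:
            cursor = la + hp.contacts[i]
    total = la_times[-1] + tail_duration
    n = int(round(total * fs))
    t = np.arange(n) / fs

    # landing bump rise starts t_rise/2 before the nominal landing so the
    # analytic jerk peak falls at the landing, snapped to the sample grid
    t_rise = round(0.028 * fs) / fs
    la_grid = [round((la - t_rise / 2) * fs) / fs for la in la_times]

    omega_flight, omega_stance, omega_base = 2.0, 2.0, 0.05
    gy = _cht_channel(
        t, fs, to_times, la_grid, push=push_gyro * subject_scale,
        flight=omega_flight, land=land_gyro_peak * subject_scale,
        stance=omega_stance, base=omega_base, t_edge=to_edge_duration,
        t_land_rise=0.02, t_land_fall=0.12)

    acc_flight = 0.5
    az = _cht_channel(
        t, fs, to_times, la_grid, push=2.5 * G, flight=acc_flight,
        land=land_acc_peak * subject_scale, stance=G, base=G,
        t_edge=0.05, t_land_rise=t_rise, t_land_fall=0.10)

    bias = np.asarray(config.gyro_bias, dtype=float)
    gyro = np.column_stack([np.zeros(n), gy, np.zeros(n)]) + bias \
        + rng.normal(0, config.noise_sd_gyro, (n, 3))
    acc = np.column_stack([np.zeros(n), np.zeros(n), az]) \
        + rng.normal(0, config.noise_sd_acc, (n, 3))
    mag = np.tile(B_EARTH, (n, 1)) + rng.normal(
        0, config.noise_sd_mag, (n, 3))
    foot = ImuRecording(t=t, acc=acc, gyro=gyro, mag=mag, fs=fs,
                        location="foot")

    # tibia: same event times, attenuated impacts, no detector-cleanliness
    # constraints; add a damped post-landing oscillation for realism
    gy_t = _cht_channel(
        t, fs, to_times, la_grid, push=5.0 * subject_scale, flight=1.5,
        land=14.0 * subject_scale, stance=1.5, base=omega_base,
        t_edge=to_edge_duration, t_land_rise=0.02, t_land_fall=0.12)
    az_t = _cht_channel(
        t, fs, to_times, la_grid, push=2.0 * G, flight=acc_flight,
        land=80.0 * subject_scale, stance=G, base=G,
        t_edge=0.05, t_land_rise=t_rise, t_land_fall=0.10)
    for la in la_grid:
        m = (t >= la) & (t < la + 0.1)
        uu = t[m] - la
        az_t[m] += 25.0 * np.exp(-uu / 0.03) * np.sin(2 * np.pi * 30 * uu)
    gyro_t = np.column_stack([np.zeros(n), gy_t, np.zeros(n)]) + bias \
        + rng.normal(0, config.noise_sd_gyro, (n, 3))
    acc_t = np.column_stack([np.zeros(n), np.zeros(n), az_t]) \
        + rng.normal(0, config.noise_sd_acc, (n, 3))
    mag_t = np.tile(B_EARTH, (n, 1)) + rng.normal(
        0, config.noise_sd_mag, (n, 3))
    tibia = ImuRecording(t=t, acc=acc_t, gyro=gyro_t, mag=mag_t, fs=fs,
                         location="tibia")

    # analytic TO: the raised-cosine fall from `push` to `flight` over
    # t_edge crosses a derivative of −0.6 rad/s² at
    # u* = (T/π)·asin(0.6·2T/(ΔΩ·π)) after the fall start
    d_om = (push_gyro * subject_scale - omega_flight)
    ustar = (to_edge_duration / np.pi) * np.arcsin(
        min(1.0, 0.6 * 2 * to_edge_duration / (d_om * np.pi)))
    events = {}
    for i in range(3):
        events[f"TO{i + 1}"] = to_times[i] + ustar
        events[f"LA{i + 1}"] = la_grid[i] + t_rise / 2
    hop_distance = hop_distance_mean * subject_scale + rng.normal(0, 0.25)
    gt = GroundTruth(
        event_times=events,
        true_parameter_values={
            "FT2": events["LA2"] - events["TO2"],
            "CT2": events["TO3"] - events["LA2"],
            "T_tot": events["LA3"] - events["TO1"],
            "wpeak_foot": np.degrees(land_gyro_peak * subject_scale),
            "hop_distance": hop_distance,
        })
    return foot, tibia, gt


# --------------------------------------------------------------------------
# countermovement jump
# --------------------------------------------------------------------------

def _solve_cmj_cubic(v_to, T):
    """Coefficients of a(τ)=c1·τ+c2·τ²+c3·τ³ on [0, T] such that
    a(T) = −g (force zero at take-off), v(T) = v_to, and v = 0 exactly at
    the inflection point τ_i = −c2/(3·c3) of the force curve."""
    def eqs(c):
        c1, c2, c3 = c
        aT = c1 * T + c2 * T ** 2 + c3 * T ** 3
        vT = c1 * T ** 2 / 2 + c2 * T ** 3 / 3 + c3 * T ** 4 / 4
        ti = -c2 / (3 * c3)
        vi = c1 * ti ** 2 / 2 + c2 * ti ** 3 / 3 + c3 * ti ** 4 / 4
        return [aT + G, vT - v_to, vi]
    scale = v_to / 2.42
    guess = np.array([-36.8, 240.8 * scale, -262.6 * scale])
    sol, info, ier, msg = optimize.fsolve(eqs, guess, full_output=True)
    if ier != 1:
        raise InvalidConfigError(f"CMJ profile solve failed: {msg}")
    c1, c2, c3 = sol
    ti = -c2 / (3 * c3)
    if not (c2 > 0 and c3 < 0 and 0 < ti < T):
        raise InvalidConfigError("CMJ profile solve produced invalid shape")
    tau = np.linspace(0, T, 4001)
    a = c1 * tau + c2 * tau ** 2 + c3 * tau ** 3
    if a.min() < -G - 1e-6:
        raise InvalidConfigError("CMJ profile implies negative force")
    return sol, ti


def simulate_cmj_grf(config: SimConfig, body_mass: float = 74.0,
                     jump_height: float = 0.30, seed: int | None = None, *,
                     quiet_duration: float = 1.0, movement_duration: float = 0.8,
                     tail_duration: float = 1.0):
    """Simulate one CMJ vertical ground-reaction-force trace.

    Ground truth stores the unweighting-phase end (the first inflection
    point of the force curve, where the vertical velocity is zero by
    construction), the flight start, and the analytic net impulse
    ``m·√(2·g·h)``.
    """
    if body_mass <= 0 or jump_height <= 0:
        raise InvalidConfigError("body_mass and jump_height must be > 0")
    v_to = np.sqrt(2 * G * jump_height)
    if v_to > 5.0:
        warnings.warn(
            f"jump height {jump_height} m implies take-off velocity "
            f"{v_to:.2f} m/s, beyond the plausible range", stacklevel=2)
    fs = config.sampling_rate_grf
    rng = _rng(config, seed)
    (c1, c2, c3), ti = _solve_cmj_cubic(v_to, movement_duration)

    t0 = round(quiet_duration * fs) / fs
    t_to = t0 + movement_duration
    t_flight = 2 * v_to / G
    t_la = t_to + t_flight
    total = t_la + tail_duration
    n = int(round(total * fs))
    t = np.arange(n) / fs
    bw = body_mass * G

    grf = np.full(n, bw)
    m_move = (t >= t0) & (t < t_to)
    tau = t[m_move] - t0
    grf[m_move] = body_mass * (
        G + c1 * tau + c2 * tau ** 2 + c3 * tau ** 3)
    grf[(t >= t_to) & (t < t_la)] = 0.0
    # landing: sharp rise to ~4 BW, then settle back to body weight
    m_land = t >= t_la
    tl = t[m_land] - t_la
    spike = 4.0 * bw * np.exp(-tl / 0.06) * np.clip(tl / 0.015, 0, 1)
    grf[m_land] = np.minimum(spike + bw * np.clip(tl / 0.3, 0, 1), 6 * bw)

    grf = grf + rng.normal(0, config.noise_sd_grf, n)
    np.clip(grf, 0.0, None, out=grf)
    # flight must read an exact zero: the plate is unloaded
    grf[(t >= t_to + 0.01) & (t < t_la - 0.01)] = 0.0

    rec = GrfRecording(t=t, grfv=grf, fs=fs, body_mass=body_mass)
    gt = GroundTruth(
        event_times={"unweight_end": t0 + ti, "flight_start": t_to,
                     "landing": t_la},
        true_parameter_values={
            "net_impulse": body_mass * v_to,
            "takeoff_velocity": v_to,
            "AUC_F": v_to,
            "F_max": body_mass * G
            + body_mass * max(c1 * x + c2 * x ** 2 + c3 * x ** 3
                              for x in np.linspace(0, movement_duration, 2001)),
        })
    return rec, gt


# --------------------------------------------------------------------------
# feature cohorts with known variance components
# --------------------------------------------------------------------------

def simulate_cohort(config: SimConfig, task: str = "SLS"):
    """Draw a cohort of FeatureRecords with known variance components.

    Per parameter p: subject means are N(μ_p, σ_b²); trial values are
    N(subject mean, σ_w²); the true single-measure ICC is
    σ_b²/(σ_b²+σ_w²).  Records are tagged subject × limb × trial; both
    limbs share the variance structure with independent draws.

    Returns ``(records, ground_truth)`` where
    ``ground_truth.true_parameter_values`` maps ``"<param>.icc"`` to the
    true ICC (and ``ground_truth.true_icc`` is set when all parameters
    share one value).
    """
    params = sorted(set(config.between_subject_sd) & set(config.within_subject_sd))
    if not params:
        raise InvalidConfigError("no parameters with both σ_b and σ_w set")
    rng = np.random.default_rng(config.seed)
    if config.n_subjects > 1 and all(
            config.between_subject_sd[p] == 0 and config.within_subject_sd[p] == 0
            for p in params):
        warnings.warn("degenerate variance structure: σ_b = σ_w = 0",
                      stacklevel=2)

    records = []
    iccs = {}
    for p in params:
        sb = config.between_subject_sd[p]
        sw = config.within_subject_sd[p]
        tot = sb ** 2 + sw ** 2
        iccs[f"{p}.icc"] = sb ** 2 / tot if tot > 0 else np.nan
    for s in range(config.n_subjects):
        for limb in ("dominant", "non-dominant"):
            means = {p: config.cohort_means.get(p, 0.0)
                     + rng.normal(0, config.between_subject_sd[p])
                     for p in params}
            for trial in range(config.n_trials):
                vals = {p: means[p]
                        + rng.normal(0, config.within_subject_sd[p])
                        for p in params}
                records.append(FeatureRecord(
                    subject=f"S{s:03d}", limb=limb, task=task,
                    trial=trial, values=vals))
    unique = {round(v, 12) for v in iccs.values() if not np.isnan(v)}
    gt = GroundTruth(
        true_parameter_values=iccs,
        true_icc=unique.pop() if len(unique) == 1 else None)
    return records, gt
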