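"""Per-trial stability parameters.

All parameters are computed on vector magnitudes of the tri-axial signals
(one value per sensor, matching the single-valued entries of the clinical
tables).  Angular rates are reported in °/s; accelerations in m/s².

Task windows
------------
SLS: parameters are computed on the eccentric phase only, the window from
the movement onset to peak flexion.  Acceleration parameters (RMS, sway
path, sway area) are computed on the gravity-removed signal: the per-sample
body-frame gravity predicted by the orientation estimate is subtracted, so
the residual reflects postural accelerations rather than the ~9.81 m/s²
static component.

CHT: parameters come from the second hop only — the 100 ms risk window
after its landing for the RMS/peak parameters, and the event times for the
temporal parameters (flight = landing minus preceding take-off; contact =
take-off minus preceding landing; total duration = first take-off to last
landing).  Acceleration parameters use the raw (bias-free, body-frame)
signal, impact-dominated so gravity is negligible.

CMJ: the maximum net vertical force and the net impulse normalised by body
mass (units m/s — equal to the take-off velocity by the impulse–momentum
theorem) over the window from the end of the unweighting phase to the
start of flight.

The sway area is the area of the prediction ellipse enclosing (about) 90%
of the acceleration trajectory on the tibia transverse (y–z) plane; its
semi-axes are √(q·λᵢ) with λᵢ the sample-covariance eigenvalues and q the
coverage quantile — by default the small-sample form
q = 2(N−1)/(N−2)·F₀.₉₀(2, N−2), which converges to the χ²₂ quantile
(4.60517 at 90%) for large N.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (DegenerateEllipseError, EmptyInputError,
                     InsufficientHopsError)
from .types import (FeatureRecord, G, GrfRecording, ImuRecording,
                    OrientationSeries, TaskEvents)

__all__ = ["rms_norm", "peak_norm", "sway_path", "prediction_ellipse",
           "EllipseFit", "extract_sls_features", "extract_cht_features",
           "extract_cmj_features"]


def _norms(sig, window):
    sig = np.asarray(sig, dtype=float)[window]
    if sig.size == 0:
        raise EmptyInputError("empty window")
    return np.linalg.norm(sig, axis=1)


def rms_norm(sig, window=slice(None)) -> float:
    """Root mean square of the vector magnitude over a window."""
    n = _norms(sig, window)
    return float(np.sqrt(np.mean(n ** 2)))


def peak_norm(sig, window=slice(None)) -> float:
    """Maximum vector magnitude over a window."""
    return float(_norms(sig, window).max())


def sway_path(acc_yz) -> float:
    """Total length of a planar trajectory (sum of consecutive distances)."""
    pts = np.asarray(acc_yz, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise EmptyInputError("sway path needs at least 2 planar points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@dataclass
class EllipseFit:
    """Coverage ellipse of a planar point cloud."""

    a: float          # semi-major axis
    b: float          # semi-minor axis
    area: float       # π·a·b
    ecc: float        # √(1 − b²/a²)
    center: np.ndarray
    q: float          # coverage quantile applied to the eigenvalues


def prediction_ellipse(points, coverage: float = 0.90,
                       method: str = "f") -> EllipseFit:
    """Fit the prediction ellipse enclosing ≈``coverage`` of the points.

    ``method="f"`` uses the small-sample quantile
    2(N−1)/(N−2)·F(coverage; 2, N−2); ``method="chi2"`` uses the asymptotic
    χ²₂ quantile.  Raises :class:`DegenerateEllipseError` (carrying
    ``ecc = 1``) for rank-deficient point clouds.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise EmptyInputError("ellipse fit needs >= 3 planar points")
    n = len(pts)
    center = pts.mean(axis=0)
    cov = np.cov(pts.T, ddof=1)
    lam, _ = np.linalg.eigh(cov)
    if lam[1] <= 0 or lam[0] / lam[1] < 1e-12:
        raise DegenerateEllipseError(
            "points are (numerically) collinear; ellipse degenerates to a "
            "line", ecc=1.0)
    if method == "f":
        q = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(coverage, 2, n - 2)
    elif method == "chi2":
        q = stats.chi2.ppf(coverage, 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    b, a = np.sqrt(q * lam)      # eigh returns ascending eigenvalues
    return EllipseFit(a=float(a), b=float(b), area=float(np.pi * a * b),
                      ecc=float(np.sqrt(1.0 - (b * b) / (a * a))),
                      center=center, q=float(q))


def _gravity_removed(rec: ImuRecording, orient: OrientationSeries):
    """Subtract the orientation-predicted body-frame gravity vector."""
    grav_body = orient.rotations[:, 2, :] * G      # R.T @ (0,0,G) per sample
    return rec.acc - grav_body


def extract_sls_features(tibia: ImuRecording, foot: ImuRecording,
                         orient: OrientationSeries, ev: TaskEvents, *,
                         foot_orient: OrientationSeries | None = None,
                         ellipse_coverage: float = 0.90,
                         subject: str = "S000", limb: str = "dominant",
                         trial: int = 0) -> FeatureRecord:
    """Single-leg-squat parameters over the eccentric phase."""
    for name, rec in (("tibia", tibia), ("foot", foot)):
        if rec is None:
            raise EmptyInputError(f"missing sensor stream: {name}")
    if orient is None:
        raise EmptyInputError("missing sensor stream: tibia orientation")
    w = slice(ev.i_start, ev.i_epe + 1)
    fs = tibia.fs

    acc_leg = _gravity_removed(tibia, orient)
    if foot_orient is not None:
        acc_foot = _gravity_removed(foot, foot_orient)
    else:
        # foot assumed (near-)static during the squat: remove the window
        # mean instead of an orientation-tracked gravity vector
        acc_foot = foot.acc - foot.acc[w].mean(axis=0)

    yz = acc_leg[w][:, 1:3]
    try:
        ell = prediction_ellipse(yz, coverage=ellipse_coverage)
        sa, sa_ecc = ell.area, ell.ecc
    except DegenerateEllipseError as e:
        warnings.warn(f"degenerate sway ellipse: {e}", stacklevel=2)
        sa, sa_ecc = np.nan, e.ecc
    values = {
        "T_tot": (ev.i_epe - ev.i_start) / fs,
        "RMSa_foot": rms_norm(acc_foot, w),
        "RMSa_leg": rms_norm(acc_leg, w),
        "RMSw_foot": np.degrees(rms_norm(foot.gyro, w)),
        "RMSw_leg": np.degrees(rms_norm(tibia.gyro, w)),
        "wpeak_foot": np.degrees(peak_norm(foot.gyro, w)),
        "wpeak_leg": np.degrees(peak_norm(tibia.gyro, w)),
        "SP": sway_path(yz),
        "SA": sa,
        "SAecc": sa_ecc,
    }
    return FeatureRecord(subject=subject, limb=limb, task="SLS", trial=trial,
                         values=values)


def extract_cht_features(foot: ImuRecording, tibia: ImuRecording,
                         orient: OrientationSeries | None,
                         ev: TaskEvents, hop_distance: float | None = None,
                         *, subject: str = "S000", limb: str = "dominant",
                         trial: int = 0) -> FeatureRecord:
    """Crossover-hop parameters: second hop only, risk-window statistics."""
    for name, rec in (("foot", foot), ("tibia", tibia)):
        if rec is None:
            raise EmptyInputError(f"missing sensor stream: {name}")
    if len(ev.to) < 2 or len(ev.la) < 2:
        raise InsufficientHopsError(
            f"need at least 2 complete hops, got {len(ev.to)} take-off(s) "
            f"and {len(ev.la)} landing(s)")
    fs = foot.fs
    ft = (ev.la[1] - ev.to[1]) / fs
    ct = (ev.to[2] - ev.la[1]) / fs if len(ev.to) >= 3 else np.nan
    t_tot = (ev.la[-1] - ev.to[0]) / fs
    w = slice(*ev.risk_windows[1])

    values = {
        "T_tot": t_tot,
        "FT": ft,
        "CT": ct,
        "RMSa_foot": rms_norm(foot.acc, w),
        "RMSa_leg": rms_norm(tibia.acc, w),
        "RMSw_foot": np.degrees(rms_norm(foot.gyro, w)),
        "RMSw_leg": np.degrees(rms_norm(tibia.gyro, w)),
        "wpeak_foot": np.degrees(peak_norm(foot.gyro, w)),
        "wpeak_leg": np.degrees(peak_norm(tibia.gyro, w)),
    }
    if hop_distance is not None:
        values["hop_distance"] = float(hop_distance)
    return FeatureRecord(subject=subject, limb=limb, task="CHT", trial=trial,
                         values=values)


def extract_cmj_features(grf: GrfRecording, ev: TaskEvents, *,
                         quiet_duration: float = 0.5, subject: str = "S000",
                         limb: str = "dominant", trial: int = 0,
                         ) -> FeatureRecord:
    """CMJ force parameters: F_max (N) and mass-normalised net impulse."""
    i0, i1 = ev.i_unweight_end, ev.i_flight_start
    if i0 is None or i1 is None or i1 <= i0:
        raise EmptyInputError("empty CMJ window")
    bw = float(grf.grfv[:int(round(quiet_duration * grf.fs))].mean())
    net = grf.grfv[i0:i1] - bw
    values = {
        "F_max": float(grf.grfv[i0:i1].max()),
        "AUC_F": float(np.trapezoid(net, dx=1.0 / grf.fs) / grf.body_mass),
    }
    return FeatureRecord(subject=subject, limb=limb, task="CMJ", trial=trial,
                         values=values)
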