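"""Elastic wing deformation from trailing-edge landmark deflections.

The three leading-edge landmarks define a rigid wing plane per frame; the
four trailing-edge vein tips (RP, MP, CuA, AA) deflect perpendicular to it.
Deflections are normalized by wing length R and signed positive toward the
instantaneous motion direction of the wing — the pressure side, which is
the side the trailing edge of a flexible flapping wing bows toward.

Mid-stroke values (flapping angle crossing the midpoint of its reversal
extremes) summarize each half-stroke; a power law ``beta = a * Fv**b`` links
deflection to the vertical force the animal must produce, and ``l**3 / beta``
serves as a chord-corrected flexural-stiffness proxy for comparing wings of
different chord length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .kinematics import WingKinematics, body_frame, find_reversals
from .recording import FlightRecording, TRAILING_EDGE_LABELS

__all__ = [
    "WingPlane",
    "DeflectionSeries",
    "AllometricFit",
    "fit_wing_plane",
    "te_deflection",
    "deflection_series",
    "midstroke_values",
    "spanwise_profile",
    "AllometricPowerLaw",
    "fit_allometry",
    "stiffness_proxy",
]


@dataclass
class WingPlane:
    """Rigid leading-edge plane with its pressure-side-oriented unit normal."""

    anchor_point: np.ndarray
    unit_normal: np.ndarray

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.anchor_point) @ self.unit_normal


@dataclass
class DeflectionSeries:
    """Signed, wing-length-normalized trailing-edge deflection time series."""

    times: np.ndarray
    deflections: dict[str, np.ndarray]
    wing_length_R: float
    midstroke_down: dict[str, float] | None = None
    midstroke_up: dict[str, float] | None = None


@dataclass
class AllometricFit:
    """Power-law fit beta = a * Fv**b on log-transformed data."""

    coefficient_a: float
    exponent_b: float
    ci95_b: tuple[float, float]
    r2: float
    n: int


def fit_wing_plane(
    wb: np.ndarray, mj: np.ndarray, wt: np.ndarray, motion_direction: np.ndarray
) -> WingPlane:
    """Plane through the three leading-edge points, normal oriented so that
    ``normal . motion_direction >= 0`` (toward the pressure side)."""
    wb, mj, wt = (np.asarray(p, float) for p in (wb, mj, wt))
    m = np.asarray(motion_direction, float)
    if np.linalg.norm(m) == 0:
        raise ValueError("zero motion direction: cannot orient the wing plane")
    normal = np.cross(mj - wb, wt - wb)
    nn = np.linalg.norm(normal)
    scale = max(np.linalg.norm(mj - wb), np.linalg.norm(wt - wb))
    if scale == 0 or nn < 1e-12 * scale**2:
        raise ValueError("collinear leading-edge points: wing plane undefined")
    normal /= nn
    if normal @ m < 0:
        normal = -normal
    return WingPlane(anchor_point=wb.copy(), unit_normal=normal)


def te_deflection(
    plane: WingPlane, te_points: dict[str, np.ndarray], R: float
) -> dict[str, float]:
    """Per-landmark signed perpendicular distance to the wing plane over R."""
    if R <= 0:
        raise ValueError("wing length R must be positive")
    missing = [l for l in TRAILING_EDGE_LABELS if l not in te_points]
    if missing:
        raise ValueError(f"missing trailing-edge landmarks: {missing}")
    return {
        label: float(plane.signed_distance(np.asarray(te_points[label], float))[0] / R)
        for label in TRAILING_EDGE_LABELS
    }


def deflection_series(
    recording: FlightRecording,
    R: float | None = None,
    min_speed_frac: float = 1e-6,
) -> DeflectionSeries:
    """Signed normalized deflections of all four TE landmarks per frame.

    Everything is computed in the per-frame body frame built from the thorax
    triad, so the result is invariant to rigid motion of the whole scene.
    The plane normal is oriented by the central-difference velocity of the
    TE-landmark centroid; when the wing is nearly still (speed below
    ``min_speed_frac * R`` per frame, i.e. at stroke reversals), the
    orientation is frozen from the previous frame.
    """
    n = recording.n_frames
    thorax = np.stack(
        [recording.thorax_points[l] for l in ("th1", "th2", "th3")], axis=1
    )
    le = {l: np.empty((n, 3)) for l in ("wb", "mj", "wt")}
    te = {l: np.empty((n, 3)) for l in TRAILING_EDGE_LABELS}
    for i in range(n):
        frame = body_frame(thorax[i])
        for l in le:
            le[l][i] = frame.to_body(recording.wing_points[l][i])
        for l in te:
            te[l][i] = frame.to_body(recording.wing_points[l][i])

    if R is None:
        R = float(np.linalg.norm(le["wt"] - le["wb"], axis=1).mean())
    if R <= 0:
        raise ValueError("wing length R must be positive")

    centroid = np.mean([te[l] for l in TRAILING_EDGE_LABELS], axis=0)
    vel = np.gradient(centroid, recording.times, axis=0)
    dt = float(np.mean(np.diff(recording.times)))
    speed_floor = min_speed_frac * R / dt

    out = {l: np.empty(n) for l in TRAILING_EDGE_LABELS}
    prev_normal = None
    for i in range(n):
        m = vel[i]
        if np.linalg.norm(m) < speed_floor and prev_normal is not None:
            raw = np.cross(le["mj"][i] - le["wb"][i], le["wt"][i] - le["wb"][i])
            raw /= np.linalg.norm(raw)
            if raw @ prev_normal < 0:
                raw = -raw
            plane = WingPlane(anchor_point=le["wb"][i], unit_normal=raw)
        else:
            if np.linalg.norm(m) == 0:
                m = np.array([0.0, 0.0, 1.0])
            plane = fit_wing_plane(le["wb"][i], le["mj"][i], le["wt"][i], m)
        prev_normal = plane.unit_normal
        for l in TRAILING_EDGE_LABELS:
            out[l][i] = plane.signed_distance(te[l][i])[0] / R
    return DeflectionSeries(times=recording.times, deflections=out, wing_length_R=R)


def _interp(times: np.ndarray, series: np.ndarray, t: float) -> float:
    return float(np.interp(t, times, series))


def midstroke_values(
    kin: WingKinematics, defl: DeflectionSeries
) -> tuple[dict[str, float], dict[str, float]]:
    """Deflection of each TE landmark at mid-stroke, per half-stroke class.

    Mid-stroke is where the flapping angle crosses the midpoint of the two
    reversal extremes bounding the half-stroke; the deflection series is
    linearly interpolated there. Values are averaged over cycles and
    returned as ``(midstroke_down, midstroke_up)`` where the downstroke is
    the half-stroke with increasing flapping angle (sweep toward the
    forward-inclined in-plane stroke axis).
    """
    rev_t, rev_a, senses = find_reversals(kin.times, kin.flapping)
    if rev_t.size < 2:
        raise ValueError("no complete half-stroke between reversals")
    down: dict[str, list[float]] = {l: [] for l in defl.deflections}
    up: dict[str, list[float]] = {l: [] for l in defl.deflections}
    for k in range(rev_t.size - 1):
        mid = 0.5 * (rev_a[k] + rev_a[k + 1])
        mask = (kin.times >= rev_t[k]) & (kin.times <= rev_t[k + 1])
        t_half = kin.times[mask]
        a_half = kin.flapping[mask]
        if t_half.size < 2:
            continue
        increasing = senses[k] == -1  # from a minimum up to a maximum
        sgn = 1.0 if increasing else -1.0
        # first crossing of the midpoint within the half-stroke
        diff = sgn * (a_half - mid)
        idx = np.nonzero(diff[:-1] * diff[1:] <= 0)[0]
        if idx.size == 0:
            continue
        i = idx[0]
        if a_half[i + 1] == a_half[i]:
            t_cross = t_half[i]
        else:
            t_cross = t_half[i] + (mid - a_half[i]) / (a_half[i + 1] - a_half[i]) * (
                t_half[i + 1] - t_half[i]
            )
        bucket = down if increasing else up
        for label, series in defl.deflections.items():
            bucket[label].append(_interp(defl.times, series, float(t_cross)))
    if not any(down.values()) and not any(up.values()):
        raise ValueError("no complete half-stroke contained a mid-stroke crossing")
    mean = lambda xs: float(np.mean(xs)) if xs else float("nan")
    defl.midstroke_down = {l: mean(v) for l, v in down.items()}
    defl.midstroke_up = {l: mean(v) for l, v in up.items()}
    return defl.midstroke_down, defl.midstroke_up


def spanwise_profile(
    defl_at_midstroke: np.ndarray, landmark_span_positions: np.ndarray
) -> PchipInterpolator:
    """Monotone-preserving (PCHIP) interpolation of chord-wise deflection
    versus span position. Passes through the landmark values exactly and
    reproduces linear inputs exactly."""
    r = np.asarray(landmark_span_positions, float)
    v = np.asarray(defl_at_midstroke, float)
    if r.size < 2:
        raise ValueError("need at least two landmarks to interpolate")
    if np.unique(r).size != r.size:
        raise ValueError("duplicated span positions")
    order = np.argsort(r)
    return PchipInterpolator(r[order], v[order])


class AllometricPowerLaw(RegressorMixin, BaseEstimator):
    """Power-law regression ``beta = a * Fv**b`` via OLS on log-log data.

    Fitted attributes: ``coefficient_a_``, ``exponent_b_``, ``ci95_b_``
    (t-based 95% interval on the exponent), ``r2_``, ``n_``.
    """

    def __init__(self, ci_level: float = 0.95):
        self.ci_level = ci_level

    def fit(self, X, y):
        Fv = np.asarray(X, float).reshape(-1)
        beta = np.asarray(y, float).reshape(-1)
        if Fv.size != beta.size or Fv.size < 3:
            raise ValueError("need at least three paired (Fv, beta) observations")
        if np.any(Fv <= 0) or np.any(beta <= 0):
            raise ValueError("log transform undefined: Fv and beta must be positive")
        res = stats.linregress(np.log(Fv), np.log(beta))
        n = Fv.size
        tcrit = stats.t.ppf(0.5 + self.ci_level / 2, df=n - 2)
        half = tcrit * res.stderr if n > 2 else np.inf
        self.exponent_b_ = float(res.slope)
        self.coefficient_a_ = float(np.exp(res.intercept))
        self.ci95_b_ = (self.exponent_b_ - half, self.exponent_b_ + half)
        self.r2_ = float(res.rvalue**2)
        self.n_ = int(n)
        return self

    def predict(self, X):
        check_is_fitted(self, "exponent_b_")
        Fv = np.asarray(X, float).reshape(-1)
        return self.coefficient_a_ * Fv**self.exponent_b_


def fit_allometry(Fv: np.ndarray, beta: np.ndarray) -> AllometricFit:
    """OLS of ln(beta) on ln(Fv); returns a = exp(intercept), b = slope and
    a t-based 95% confidence interval on b."""
    est = AllometricPowerLaw().fit(Fv, beta)
    return AllometricFit(
        coefficient_a=est.coefficient_a_,
        exponent_b=est.exponent_b_,
        ci95_b=est.ci95_b_,
        r2=est.r2_,
        n=est.n_,
    )


def stiffness_proxy(chord_l: float, beta: float) -> float:
    """Chord-corrected flexural-stiffness proxy l**3 / beta.

    Under equal load, flexural stiffness scales with the cube of the local
    chord over the measured deflection, so equal proxies under equal force
    imply equal EI."""
    if chord_l <= 0:
        raise ValueError("chord length must be positive")
    if beta <= 0:
        raise ValueError("undeflected — proxy undefined" if beta == 0 else "beta must be positive")
    return float(chord_l**3 / beta)
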