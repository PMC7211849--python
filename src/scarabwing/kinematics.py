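"""Wing-flapping kinematics reconstructed from landmark trajectories.

The body frame is built from three thorax points; wing motion is then
described by three time-varying angles measured against a stroke plane:

* **flapping** — azimuth of the base-to-tip (``wb``→``wt``) axis projected
  into the stroke plane,
* **deviation** — elevation of that axis out of the stroke plane,
* **incidence** — rotation of the wing plane about the base-to-tip axis,
  measured from the stroke plane.

The stroke plane is the best-fit (total-least-squares) plane of the wing-tip
path relative to the body; its inclination from horizontal is the stroke
plane angle. Scalar flight descriptors — wingbeat frequency from stroke
reversals, advance ratio ``J = V / (2 Φ f R)`` and the vertical force
``Fv = m (g + a_v)`` an animal must produce to sustain its observed vertical
acceleration — round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import FlightRecording, LEADING_EDGE_LABELS

GRAVITY = 9.81  # m s^-2

__all__ = [
    "BodyFrame",
    "WingKinematics",
    "FlightState",
    "body_frame",
    "wing_angles",
    "stroke_plane",
    "wingbeat_frequency",
    "find_reversals",
    "advance_ratio",
    "vertical_force",
    "stroke_plane_basis",
]


@dataclass
class BodyFrame:
    """Right-handed orthonormal body triad.

    ``axes`` rows are the longitudinal (x), lateral (y) and dorsoventral (z)
    unit vectors expressed in world coordinates, so ``axes @ (p - origin)``
    maps a world point into body coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray

    def to_body(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.origin) @ self.axes.T


@dataclass
class WingKinematics:
    """Reconstructed flapping kinematics (angles in degrees)."""

    times: np.ndarray
    flapping: np.ndarray
    deviation: np.ndarray
    incidence: np.ndarray
    stroke_plane_angle: float
    reversal_times: np.ndarray
    frequency: float
    flagged_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("flapping", "deviation", "incidence"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} series contains non-finite values")
        if np.any(np.diff(self.reversal_times) <= 0):
            raise ValueError("reversal_times must be strictly increasing")


@dataclass
class FlightState:
    """Whole-body flight descriptors for one recording."""

    body_mass_m: float  # kg
    flight_velocity: np.ndarray  # m/s, world frame
    vertical_acceleration: float  # m/s^2
    gravity_g: float = GRAVITY
    vertical_force_Fv: float = field(init=False)
    advance_ratio_J: float | None = None

    def __post_init__(self) -> None:
        self.vertical_force_Fv = self.body_mass_m * (
            self.gravity_g + self.vertical_acceleration
        )


def _unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / n


def body_frame(thorax_points: np.ndarray) -> BodyFrame:
    """Orthonormal right-handed frame from three non-collinear thorax points.

    x is the unit vector from point 1 to point 2 (longitudinal), z is the
    normal of the thorax triangle (dorsal) and y = z × x (lateral).
    Equivariant: rotating the inputs by Q rotates the axes by Q.
    """
    p = np.asarray(thorax_points, dtype=float)
    if p.shape != (3, 3):
        raise ValueError("expected three 3D thorax points")
    u = p[1] - p[0]
    v = p[2] - p[0]
    cross = np.cross(u, v)
    scale = max(np.linalg.norm(u), np.linalg.norm(v))
    if scale == 0 or np.linalg.norm(cross) < 1e-9 * scale**2:
        raise ValueError("degenerate thorax triad: points collinear or coincident")
    x = u / np.linalg.norm(u)
    z = cross / np.linalg.norm(cross)
    y = np.cross(z, x)
    return BodyFrame(origin=p[0].copy(), axes=np.stack([x, y, z]))


def stroke_plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-plane axes (s1, s2) and unit normal n for a stroke plane.

    s2 is the projection of the body lateral axis into the plane (the
    direction the spread wing points at zero flapping angle); s1 = s2 × n
    completes a right-handed set. The normal is oriented dorsally
    (non-negative z component in body coordinates).
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    if n[2] < 0 or (n[2] == 0 and n[0] < 0):
        n = -n
    y = np.array([0.0, 1.0, 0.0])
    s2 = y - (y @ n) * n
    norm = np.linalg.norm(s2)
    if norm < 1e-12:
        raise ValueError("stroke plane normal parallel to lateral axis")
    s2 /= norm
    s1 = np.cross(s2, n)
    return s1, s2, n


def _stroke_plane_normal_from_angle(angle_deg: float) -> np.ndarray:
    g = np.deg2rad(angle_deg)
    return np.array([np.sin(g), 0.0, np.cos(g)])


def _tls_plane_normal(points: np.ndarray) -> np.ndarray:
    """Smallest principal axis of mean-centred points (total least squares)."""
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt[-1]


def find_reversals(
    times: np.ndarray, angle: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stroke reversals of an angle series with sub-frame refinement.

    Reversals are sign changes of the centred-difference angular velocity;
    each is refined by the vertex of a parabola through the three samples
    around the discrete extremum. Returns ``(rev_times, rev_values, senses)``
    with sense +1 for maxima and -1 for minima.
    """
    t = np.asarray(times, float)
    a = np.asarray(angle, float)
    v = np.gradient(a, t)
    idx = np.nonzero(v[:-1] * v[1:] < 0)[0]
    if idx.size == 0:
        raise ValueError("no reversals: angle series is monotone or constant")
    rev_t, rev_a, senses = [], [], []
    for i in idx:
        sense = 1 if v[i] > 0 else -1
        j = i if sense * a[i] >= sense * a[i + 1] else i + 1
        j = min(max(j, 1), len(a) - 2)
        # parabola through (t[j-1], t[j], t[j+1])
        tt = t[j - 1 : j + 2] - t[j]
        yy = a[j - 1 : j + 2]
        coef = np.polyfit(tt, yy, 2)
        if coef[0] == 0:
            tv, av = t[j], a[j]
        else:
            dt = -coef[1] / (2 * coef[0])
            dt = float(np.clip(dt, tt[0], tt[-1]))
            tv = t[j] + dt
            av = float(np.polyval(coef, dt))
        rev_t.append(tv)
        rev_a.append(av)
        senses.append(sense)
    rev_t = np.array(rev_t)
    rev_a = np.array(rev_a)
    senses = np.array(senses)
    # merge same-sense neighbours (can arise from noise): keep the extremer
    keep = [0]
    for k in range(1, len(rev_t)):
        if senses[k] == senses[keep[-1]]:
            if senses[k] * rev_a[k] > senses[k] * rev_a[keep[-1]]:
                keep[-1] = k
        else:
            keep.append(k)
    keep = np.array(keep)
    return rev_t[keep], rev_a[keep], senses[keep]


def wingbeat_frequency(kin: "WingKinematics | tuple[np.ndarray, np.ndarray]") -> float:
    """Wingbeat frequency as full cycles per elapsed time between the first
    and last same-sense stroke reversal."""
    if isinstance(kin, WingKinematics):
        times, angle = kin.times, kin.flapping
    else:
        times, angle = kin
    rev_t, _, senses = find_reversals(np.asarray(times), np.asarray(angle))
    best = None
    for sense in (1, -1):
        rt = rev_t[senses == sense]
        if rt.size >= 2:
            f = (rt.size - 1) / (rt[-1] - rt[0])
            if best is None or rt.size > best[1]:
                best = (f, rt.size)
    if best is None:
        raise ValueError("need at least two same-sense reversals for a frequency")
    return float(best[0])


def stroke_plane(kin: WingKinematics, tip_trajectory: np.ndarray) -> float:
    """Stroke-plane angle (deg from horizontal) of a tip path.

    The tip path (body coordinates) is split into full cycles between
    successive same-sense reversals; each cycle gets a total-least-squares
    plane fit and the per-cycle inclinations are averaged. The inclination
    is the angle between the plane and horizontal, in [0, 90] degrees.
    """
    tip = np.asarray(tip_trajectory, float)
    rev_t, _, senses = find_reversals(kin.times, kin.flapping)
    sense = 1 if np.count_nonzero(senses == 1) >= 2 else -1
    rt = rev_t[senses == sense]
    if rt.size < 2:
        raise ValueError("need at least one full cycle for a stroke plane")
    angles = []
    for t0, t1 in zip(rt[:-1], rt[1:]):
        mask = (kin.times >= t0) & (kin.times <= t1)
        if np.count_nonzero(mask) < 3:
            continue
        n = _tls_plane_normal(tip[mask])
        angles.append(np.degrees(np.arccos(min(1.0, abs(n[2])))))
    if not angles:
        raise ValueError("no cycle contained enough frames for a plane fit")
    return float(np.mean(angles))


def wing_angles(
    recording: FlightRecording,
    stroke_plane_angle: float | None = None,
    degenerate_tol: float = 1e-9,
) -> WingKinematics:
    """Reconstruct flapping, deviation and incidence from a recording.

    All wing points are first expressed in the per-frame body frame built
    from the thorax triad, making every output invariant to rigid motion of
    the whole scene. The stroke-plane basis is either derived from an
    explicitly supplied inclination angle or estimated as the total-least-
    squares plane of the full base-to-tip path.

    On noise-free synthetic input whose deviation is measured against the
    same plane, the recovered series invert the generator exactly.
    """
    for label in LEADING_EDGE_LABELS:
        if label not in recording.wing_points:
            raise ValueError(f"missing leading-edge landmark {label!r}")
    n_frames = recording.n_frames
    wb = np.empty((n_frames, 3))
    mj = np.empty((n_frames, 3))
    wt = np.empty((n_frames, 3))
    thorax = np.stack(
        [recording.thorax_points[l] for l in ("th1", "th2", "th3")], axis=1
    )
    for i in range(n_frames):
        frame = body_frame(thorax[i])
        wb[i] = frame.to_body(recording.wing_points["wb"][i])
        mj[i] = frame.to_body(recording.wing_points["mj"][i])
        wt[i] = frame.to_body(recording.wing_points["wt"][i])

    span = wt - wb
    R = float(np.linalg.norm(span, axis=1).mean())
    d = _unit(span)

    flagged: list[int] = []
    le = np.cross(mj - wb, wt - wb)
    le_area = 0.5 * np.linalg.norm(le, axis=1)
    flagged = list(np.nonzero(le_area < degenerate_tol * R**2)[0])

    if stroke_plane_angle is None:
        normal = _tls_plane_normal(span)
    else:
        normal = _stroke_plane_normal_from_angle(stroke_plane_angle)
    s1, s2, n = stroke_plane_basis(normal)

    a1 = d @ s1
    a2 = d @ s2
    a3 = np.clip(d @ n, -1.0, 1.0)
    flapping = np.degrees(np.arctan2(a1, a2))
    deviation = np.degrees(np.arcsin(a3))

    # chord direction from the marginal joint, incidence about the span axis
    q = mj - wb
    chord = q - (np.sum(q * d, axis=1, keepdims=True)) * d
    chord = _unit(chord)
    u0 = _unit(np.cross(np.broadcast_to(n, d.shape), d))
    w0 = np.cross(d, u0)
    incidence = np.degrees(
        np.arctan2(np.sum(chord * w0, axis=1), np.sum(chord * u0, axis=1))
    )

    rev_t, _, _ = find_reversals(recording.times, flapping)
    freq = wingbeat_frequency((recording.times, flapping))
    kin = WingKinematics(
        times=recording.times,
        flapping=flapping,
        deviation=deviation,
        incidence=incidence,
        stroke_plane_angle=0.0,
        reversal_times=rev_t,
        frequency=freq,
        flagged_frames=flagged,
    )
    if stroke_plane_angle is None:
        kin.stroke_plane_angle = stroke_plane(kin, span)
    else:
        kin.stroke_plane_angle = float(stroke_plane_angle)
    return kin


def advance_ratio(flight_speed: float, Phi: float, f: float, R: float) -> float:
    """Advance ratio J = V / (2 Φ f R).

    ``Phi`` is the peak-to-peak stroke amplitude in radians, so the
    denominator is the mean wingtip flapping speed. J well below 0.1 marks
    the hovering regime.
    """
    denom = 2.0 * Phi * f * R
    if denom <= 0:
        raise ValueError("stroke amplitude, frequency and wing length must be > 0")
    if flight_speed < 0:
        raise ValueError("flight speed must be non-negative")
    return float(flight_speed / denom)


def vertical_force(m: float, a_v: float, g: float = GRAVITY) -> float:
    """Vertical force Fv = m (g + a_v) required to sustain vertical
    acceleration ``a_v`` (m/s^2) at body mass ``m`` (kg). Exact arithmetic;
    a negative result is returned as computed."""
    if m <= 0:
        raise ValueError("body mass must be positive")
    return float(m * (g + a_v))
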