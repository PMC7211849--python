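"""Synthetic data generators with known ground truth.

Four forward models mirror the measurements of the beetle-flight study
design this package analyses:

* :func:`simulate_flight` — a flapping wing whose three leading-edge
  landmarks move rigidly with commanded flapping/deviation/incidence
  angles while four trailing-edge landmarks additionally deflect
  perpendicular to the wing plane, toward the instantaneous motion
  direction, peaking at mid-stroke and vanishing at stroke reversals;
* :func:`simulate_shape_radiation` — 25-landmark wing shapes evolving by
  Brownian motion along a phylogeny, with optional clade-specific offsets
  and per-specimen digitization noise;
* :func:`simulate_bending` — point-load cantilever bending
  ``F = k EI beta / l**3`` with multiplicative measurement noise;
* :func:`simulate_allometry` — deflection-versus-vertical-force samples
  from the power law ``beta = a * Fv**b`` with log-normal scatter.

Every generator takes an explicit seed and draws from its own
``numpy.random.Generator`` stream; identical seeds give bit-identical
output. Default parameter values reflect the measured study conditions:
wingbeat frequencies near 109–118 Hz, stroke-plane angles near 30–34
degrees, wing lengths of 14–25 mm, body masses of 0.2–0.9 g, and a
deflection allometry near beta = 0.038 Fv^0.43.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import dendropy
import numpy as np
import pandas as pd

from .bending import bending_force
from .morphometrics import ShapeSet
from .phylo import load_tree
from .recording import FlightRecording, TRAILING_EDGE_LABELS

__all__ = [
    "FlightSimParams",
    "ShapeRadiationParams",
    "ShapeRadiation",
    "simulate_flight",
    "simulate_shape_radiation",
    "simulate_bending",
    "simulate_allometry",
    "default_incidence_profile",
    "default_ancestral_shape",
]

# span-wise / chord-wise landmark positions as fractions of wing length R.
# The marginal joint sits just aft of the leading-edge spar at mid-span;
# trailing-edge vein tips run from distal (RP) to proximal (AA).
DEFAULT_LANDMARK_POSITIONS: dict[str, tuple[float, float]] = {
    "wb": (0.0, 0.0),
    "mj": (0.55, 0.20),
    "wt": (1.0, 0.0),
    "RP": (0.85, 0.22),
    "MP": (0.65, 0.32),
    "CuA": (0.45, 0.38),
    "AA": (0.25, 0.35),
}

# normalized mid-stroke deflection amplitudes; CuA deflects most, as seen
# in free flight
DEFAULT_TE_AMPLITUDES: dict[str, float] = {
    "RP": 0.05,
    "MP": 0.09,
    "CuA": 0.12,
    "AA": 0.10,
}


def default_incidence_profile(phase: np.ndarray) -> np.ndarray:
    """Incidence (deg) versus cycle phase (rad): mid-stroke pitch of 45 deg
    modulated smoothly over the cycle."""
    return 45.0 + 25.0 * np.cos(phase)


@dataclass
class FlightSimParams:
    """Commanded kinematics and wing layout for one synthetic flight."""

    wing_length_R: float = 20.0  # mm
    frequency_f: float = 118.0  # Hz
    stroke_amplitude_Phi: float = 120.0  # deg, peak-to-peak
    stroke_plane_angle: float = 34.0  # deg from horizontal
    deviation_amplitude: float = 0.0  # deg
    incidence_profile: Callable[[np.ndarray], np.ndarray] | None = None
    te_deflection_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TE_AMPLITUDES)
    )
    te_chord_positions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            k: DEFAULT_LANDMARK_POSITIONS[k] for k in TRAILING_EDGE_LABELS
        }
    )
    body_velocity: tuple[float, float, float] = (0.2, 0.0, 0.3)  # m/s
    body_vertical_acceleration: float = 0.0  # m/s^2
    body_mass: float = 0.5  # g
    n_cycles: int = 3
    frame_rate: float = 5000.0  # Hz
    noise_sigma: float = 0.0  # mm, per coordinate
    seed: int = 0

    def validate(self) -> None:
        if self.wing_length_R <= 0:
            raise ValueError("wing length must be positive")
        if self.frequency_f <= 0:
            raise ValueError("frequency must be positive")
        if self.frame_rate < 20 * self.frequency_f:
            raise ValueError("undersampled: frame_rate must be >= 20 * frequency")
        if self.stroke_amplitude_Phi < 0 or self.deviation_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        for label, amp in self.te_deflection_amplitudes.items():
            if not 0 <= amp <= 0.5:
                raise ValueError(
                    f"TE amplitude for {label} must be in [0, 0.5], got {amp}"
                )


def simulate_flight(params: FlightSimParams) -> FlightRecording:
    """Forward model of a flapping-flight recording.

    The wing base, marginal joint and wing tip move rigidly with the
    commanded angle series; trailing-edge landmarks are additionally
    displaced along the wing-plane normal by their commanded amplitude
    times ``|cos(stroke phase)|`` (peak at mid-stroke, zero at reversals),
    signed toward the instantaneous wing-motion direction. The thorax is a
    rigid triad translated by the integrated body velocity. Gaussian noise
    is added to every stored coordinate last.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    R = params.wing_length_R
    f = params.frequency_f
    omega = 2 * np.pi * f
    duration = params.n_cycles / f
    n = int(np.floor(duration * params.frame_rate)) + 1
    t = np.arange(n) / params.frame_rate

    A = np.deg2rad(params.stroke_amplitude_Phi) / 2
    phi = A * np.sin(omega * t)
    theta = np.deg2rad(params.deviation_amplitude) * np.sin(2 * omega * t)
    profile = params.incidence_profile or default_incidence_profile
    alpha = np.deg2rad(np.asarray(profile(np.mod(omega * t, 2 * np.pi)), float))

    g = np.deg2rad(params.stroke_plane_angle)
    s1 = np.array([np.cos(g), 0.0, -np.sin(g)])
    s2 = np.array([0.0, 1.0, 0.0])
    nrm = np.cross(s1, s2)

    d = (
        np.cos(theta)[:, None] * (np.sin(phi)[:, None] * s1 + np.cos(phi)[:, None] * s2)
        + np.sin(theta)[:, None] * nrm
    )
    u0 = np.cross(np.broadcast_to(nrm, d.shape), d)
    u0 /= np.linalg.norm(u0, axis=1, keepdims=True)
    w0 = np.cross(d, u0)
    chord = np.cos(alpha)[:, None] * u0 + np.sin(alpha)[:, None] * w0
    n_wing = np.cross(d, chord)

    # body translation (mm): steady velocity plus vertical acceleration
    v = np.asarray(params.body_velocity, float) * 1000.0
    accel = np.array([0.0, 0.0, params.body_vertical_acceleration * 1000.0])
    origin = v * t[:, None] + 0.5 * accel * t[:, None] ** 2
    thorax = {
        "th1": origin.copy(),
        "th2": origin + np.array([3.0, 0.0, 0.0]),
        "th3": origin + np.array([0.0, 3.0, 0.0]),
    }
    base = origin + np.array([0.0, 5.0, 2.0])

    wing: dict[str, np.ndarray] = {}
    for label in ("wb", "mj", "wt"):
        s, c = DEFAULT_LANDMARK_POSITIONS[label]
        wing[label] = base + R * (s * d + c * chord)

    # motion direction: velocity of the rigid wing at the TE region
    tip = base + R * d
    tip_vel = np.gradient(tip, t, axis=0)
    sign = np.sign(np.sum(tip_vel * n_wing, axis=1))
    sign[sign == 0] = 1.0
    prof = np.abs(np.cos(omega * t))
    truth_deflection: dict[str, np.ndarray] = {}
    for label in TRAILING_EDGE_LABELS:
        s, c = params.te_chord_positions[label]
        amp = params.te_deflection_amplitudes.get(label, 0.0)
        defl = amp * prof
        wing[label] = base + R * (s * d + c * chord) + (R * defl * sign)[:, None] * n_wing
        truth_deflection[label] = defl

    if params.noise_sigma > 0:
        for store in (thorax, wing):
            for label in store:
                store[label] = store[label] + rng.normal(
                    0.0, params.noise_sigma, size=store[label].shape
                )

    truth = {
        "times": t,
        "flapping_deg": np.degrees(phi),
        "deviation_deg": np.degrees(theta),
        "incidence_deg": np.degrees(alpha),
        "deflection_normalized": truth_deflection,
        "deflection_sign": sign,
        "stroke_plane_angle_deg": params.stroke_plane_angle,
        "frequency_hz": f,
        "te_amplitudes": dict(params.te_deflection_amplitudes),
        "wing_length_R_mm": R,
    }
    return FlightRecording(
        times=t, thorax_points=thorax, wing_points=wing, ground_truth=truth
    )


def default_ancestral_shape() -> np.ndarray:
    """A 25-landmark wing-like template: 13 points along a cambered leading
    arc and 12 along the trailing margin of an elliptical planform."""
    top = np.linspace(0, np.pi, 13)
    bot = np.linspace(np.pi, 2 * np.pi, 14)[1:-1]
    ang = np.concatenate([top, bot])
    pts = np.column_stack([2.0 * np.cos(ang), 0.8 * np.sin(ang)])
    pts[len(top):, 1] *= 0.6  # flatter trailing edge
    return pts


@dataclass
class ShapeRadiationParams:
    """Brownian-motion radiation of wing shapes on a phylogeny."""

    tree: "dendropy.Tree | str"
    ancestral_shape: np.ndarray = field(default_factory=default_ancestral_shape)
    bm_rate_sigma2: float = 1e-4  # squared shape units per branch-length unit
    clade_offsets: dict[str, np.ndarray] | None = None
    n_specimens_per_species: int = 10
    digitization_noise: float = 0.01  # coordinate s.d.
    seed: int = 0


@dataclass
class ShapeRadiation:
    shapes: ShapeSet
    species_means: dict[str, np.ndarray]  # label -> (25, 2) ground truth


def simulate_shape_radiation(params: ShapeRadiationParams) -> ShapeRadiation:
    """Evolve each landmark coordinate as independent Brownian motion along
    the tree; clade offsets (keyed by internal-node or tip label) are added
    at the named node and inherited by its descendants. Specimens are the
    species mean plus isotropic digitization noise."""
    tree = load_tree(params.tree)
    anc = np.asarray(params.ancestral_shape, float)
    if anc.ndim != 2 or anc.shape[1] != 2:
        raise ValueError("ancestral shape must be (k, 2)")
    if anc.shape[0] != 25:
        raise ValueError("ancestral shape must have 25 landmarks")
    if params.n_specimens_per_species < 1:
        raise ValueError("need at least one specimen per species")
    rng = np.random.default_rng(params.seed)
    p = anc.size
    sigma2 = params.bm_rate_sigma2
    offsets = params.clade_offsets or {}

    values: dict[dendropy.Node, np.ndarray] = {}
    species_means: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            val = anc.reshape(-1).copy()
        else:
            edge = node.edge.length
            if edge is None:
                raise ValueError("tree has a branch without a length")
            if edge < 0:
                raise ValueError("negative branch length")
            step = (
                rng.normal(0.0, np.sqrt(sigma2 * edge), size=p)
                if sigma2 * edge > 0
                else np.zeros(p)
            )
            val = values[node.parent_node] + step
        label = node.taxon.label if node.taxon else getattr(node, "label", None)
        if label is not None and label in offsets:
            val = val + np.asarray(offsets[label], float).reshape(-1)
        values[node] = val
        if node.is_leaf():
            if node.taxon is None:
                raise ValueError("all tips must be labelled")
            species_means[node.taxon.label] = val.reshape(anc.shape)

    configs, ids, labels = [], [], []
    for lab in sorted(species_means):
        mean = species_means[lab]
        for j in range(params.n_specimens_per_species):
            noise = (
                rng.normal(0.0, params.digitization_noise, size=mean.shape)
                if params.digitization_noise > 0
                else 0.0
            )
            configs.append(mean + noise)
            ids.append(f"{lab}_{j + 1}")
            labels.append(lab)
    shapes = ShapeSet(
        configurations=np.stack(configs), specimen_ids=ids, species_labels=labels
    )
    return ShapeRadiation(shapes=shapes, species_means=species_means)


def simulate_bending(
    EI: float,
    l: float,
    k: float = 3.0,
    displacement: float = 1e-3,
    noise_cv: float = 0.0,
    seed: int | None = None,
    n_replicates: int = 1,
    point_id: int = 1,
    side: str = "dorsal",
    support: str = "WB",
) -> pd.DataFrame:
    """Measured forces for pressing a cantilever wing down ``displacement``
    metres at distance ``l`` from the support: F = k EI beta / l**3, with
    multiplicative Gaussian noise of coefficient of variation ``noise_cv``.
    Returns one row per replicate with the standard bending-table columns.
    """
    if l <= 0:
        raise ValueError("distance l must be positive")
    if EI <= 0 or displacement <= 0:
        raise ValueError("EI and displacement must be positive")
    F = bending_force(EI, l, displacement, k)
    rng = np.random.default_rng(seed)
    forces = F * (
        1.0 + noise_cv * rng.standard_normal(n_replicates)
        if noise_cv > 0
        else np.ones(n_replicates)
    )
    return pd.DataFrame(
        {
            "point_id": point_id,
            "side": side,
            "support": support,
            "force_N": forces,
            "displacement_m": displacement,
            "distance_l_m": l,
        }
    )


def simulate_allometry(
    a: float = 0.038,
    b: float = 0.43,
    Fv_range: tuple[float, float] = (0.002, 0.009),
    n: int = 34,
    log_noise_sigma: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Deflection-versus-vertical-force table from beta = a * Fv**b.

    Fv is spaced geometrically over ``Fv_range`` (the vertical forces
    implied by 0.2–0.9 g beetles near hover); log-normal noise of s.d.
    ``log_noise_sigma`` perturbs beta. With zero noise the points lie
    exactly on the power law.
    """
    if a <= 0:
        raise ValueError("coefficient a must be positive")
    if min(Fv_range) <= 0:
        raise ValueError("Fv range must be positive")
    if n < 3:
        raise ValueError("need at least three points")
    rng = np.random.default_rng(seed)
    Fv = np.geomspace(Fv_range[0], Fv_range[1], n)
    beta = a * Fv**b
    if log_noise_sigma > 0:
        beta = beta * np.exp(rng.normal(0.0, log_noise_sigma, size=n))
    return pd.DataFrame({"Fv_N": Fv, "beta": beta})
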