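"""Static point-load bending: flexural stiffness and experiment contrasts.

A wing clamped at its base behaves as a cantilever: pressing it down a
fixed displacement beta at distance l from the support requires a force
``F = k EI beta / l**3`` (k = 3 for an end-loaded uniform beam), so
``EI = F l**3 / (k beta)``. The experimental design crosses six load points
with the pressing side (dorsal/ventral) and the support condition (wing
base only, WB, versus wing base plus leading edge, WBLE); the contrasts
below summarize the side and support effects per point, and a permutation
test provides a distribution-free two-group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BendingRecord",
    "StiffnessEstimate",
    "flexural_stiffness",
    "bending_force",
    "side_asymmetry",
    "support_effect",
    "permutation_contrast",
    "flag_low_forces",
    "SIDE_DORSAL",
    "SIDE_VENTRAL",
]

SIDE_DORSAL = "dorsal"
SIDE_VENTRAL = "ventral"
_SIDE_CODES = {1: SIDE_DORSAL, 2: SIDE_VENTRAL, SIDE_DORSAL: SIDE_DORSAL, SIDE_VENTRAL: SIDE_VENTRAL}
_SUPPORTS = ("WB", "WBLE")


@dataclass
class BendingRecord:
    """One force–displacement measurement on the six-point wing layout."""

    point_id: int
    side: str
    support: str
    force_F: float  # N
    displacement_beta: float  # m (protocol constant 1 mm)
    distance_l: float  # m from support to load point

    def __post_init__(self) -> None:
        if self.point_id not in range(1, 7):
            raise ValueError("point_id must be in 1..6")
        self.side = _SIDE_CODES[self.side]
        if self.support not in _SUPPORTS:
            raise ValueError(f"support must be one of {_SUPPORTS}")
        if self.force_F < 0:
            raise ValueError("force must be non-negative")
        if self.displacement_beta <= 0:
            raise ValueError("displacement must be positive")


@dataclass
class StiffnessEstimate:
    EI: float  # N m^2
    k: float = 3.0

    def __post_init__(self) -> None:
        if self.EI <= 0:
            raise ValueError("EI must be positive")


def flexural_stiffness(F: float, l: float, beta: float, k: float = 3.0) -> float:
    """EI = F l**3 / (k beta), inverting the cantilever deflection relation."""
    if min(F, l, beta, k) <= 0:
        raise ValueError("F, l, beta and k must all be positive")
    return float(F * l**3 / (k * beta))


def bending_force(EI: float, l: float, beta: float, k: float = 3.0) -> float:
    """Force needed to impose deflection beta at distance l: F = k EI beta / l**3."""
    if min(EI, l, beta, k) <= 0:
        raise ValueError("EI, l, beta and k must all be positive")
    return float(k * EI * beta / l**3)


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "point_id": [r.point_id for r in records],
                "side": [r.side for r in records],
                "support": [r.support for r in records],
                "force_N": [r.force_F for r in records],
            }
        )
    df["side"] = df["side"].map(_SIDE_CODES)
    return df


def _paired_difference(records, pair_col: str, pos: str, neg: str, within: str) -> pd.DataFrame:
    df = _records_frame(records)
    cell = df.groupby(["point_id", within, pair_col])["force_N"].mean().unstack(pair_col)
    missing = [
        (int(p), w, lvl)
        for (p, w), row in cell.iterrows()
        for lvl in (pos, neg)
        if lvl not in cell.columns or pd.isna(row.get(lvl))
    ]
    if missing:
        raise ValueError(f"unmatched {pair_col} pairs for cells: {missing}")
    out = (cell[pos] - cell[neg]).rename("force_difference_N").reset_index()
    return out


def side_asymmetry(records) -> pd.DataFrame:
    """Per-(point, support) dorsal-minus-ventral mean force difference.

    Zero for a wing equally stiff from both sides; negative where the
    ventral side resists the imposed displacement more strongly."""
    return _paired_difference(records, "side", SIDE_DORSAL, SIDE_VENTRAL, "support")


def support_effect(records) -> pd.DataFrame:
    """Per-(point, side) WBLE-minus-WB mean force difference.

    Positive values mean the extra leading-edge support stiffens the
    response (it removes span-wise bending and twist compliance)."""
    return _paired_difference(records, "support", "WBLE", "WB", "side")


def permutation_contrast(
    group_a, group_b, n_perm: int = 9999, seed: int | None = None
) -> tuple[float, float]:
    """Two-sided permutation test of the mean difference between two groups.

    Returns ``(p_value, observed_mean_difference)`` with the add-one
    correction ``p = (1 + #{|perm| >= |obs|}) / (1 + n_perm)``.
    """
    a = np.asarray(group_a, float).reshape(-1)
    b = np.asarray(group_b, float).reshape(-1)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if n_perm < 100:
        import logging

        logging.getLogger(__name__).warning(
            "n_perm=%d is low; p-value resolution will be coarse", n_perm
        )
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    obs = a.mean() - b.mean()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = perm[: a.size].mean() - perm[a.size :].mean()
        if abs(diff) >= abs(obs) - 1e-15:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(p), float(obs)


def flag_low_forces(records, floor: float = 1e-6) -> pd.DataFrame:
    """Mark measurements whose force falls below the load-cell floor (N).

    Flagged rows are kept, not dropped; downstream users decide."""
    df = _records_frame(records)
    df["below_floor"] = df["force_N"] < floor
    return df
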