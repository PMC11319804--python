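"""Patient-specific ventilation boundary conditions.

Per-lobe ventilation fractions are derived from paired FRC/TLC lobe
volumes: the difference in a lobe's volume between the two capacity levels,
relative to the total difference, is the fraction of tidal air moved by
that lobe.  Combined with a tidal breathing waveform and the outlet
surface areas of the resolved airway tree, the fractions become
time-dependent per-outlet flow profiles.  An *area-uniform* counterfactual
mode distributes flow by outlet area alone (the reduced-order analog of a
uniform pressure-outlet boundary condition), ignoring the patient's lobar
split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .synthetic import LungVolumes
from .tree import LOBES, AirwayTree, Lobe

__all__ = [
    "BreathingPattern",
    "LobarFractions",
    "OutletFlowProfiles",
    "lobar_fractions",
    "tidal_waveform",
    "outlet_flow_profiles",
]

MODES = ("patient_specific", "area_uniform")


@dataclass(frozen=True)
class BreathingPattern:
    """A periodic tidal breathing waveform.

    ``flow(t)`` is the mouth flow rate in L/s, positive during inhalation
    (the first half-cycle); its integral over one inspiratory phase equals
    the tidal volume.
    """

    vt_L: float
    period_s: float
    n_cycles: int
    flow: Callable[[np.ndarray | float], np.ndarray | float]

    @property
    def total_time(self) -> float:
        return self.n_cycles * self.period_s


@dataclass(frozen=True)
class LobarFractions:
    """Per-lobe ventilation proportions (non-negative, summing to 1)."""

    f: dict[Lobe, float]

    def __post_init__(self) -> None:
        vals = np.array([self.f[l] for l in LOBES])
        if np.any(vals < 0):
            raise ValueError("lobar fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"lobar fractions must sum to 1, got {vals.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.f[l] for l in LOBES])


@dataclass(frozen=True)
class OutletFlowProfiles:
    """Per-terminal-branch flow profiles Q_o(t) = w_o * Q(t).

    Because every outlet profile is proportional to the mouth waveform,
    the profiles are represented by static weights ``w_o`` (summing to 1)
    times the breathing pattern; ``flow(branch_id, t)`` evaluates Q_o in
    L/s.
    """

    weights: dict[str, float]
    pattern: BreathingPattern
    mode: str

    def flow(self, branch_id: str, t: np.ndarray | float) -> np.ndarray | float:
        return self.weights[branch_id] * self.pattern.flow(t)

    def to_frame(self, times: np.ndarray) -> pd.DataFrame:
        """Export as a long table: time_s, branch_id, Q_L_per_s."""
        recs = []
        for bid, w in self.weights.items():
            q = w * np.asarray(self.pattern.flow(times))
            recs.append(pd.DataFrame(
                {"time_s": times, "branch_id": bid, "Q_L_per_s": q}))
        return pd.concat(recs, ignore_index=True)


def lobar_fractions(volumes: LungVolumes) -> LobarFractions:
    """Ventilation fractions from FRC/TLC lobe volumes.

    f_l = (V_tlc,l - V_frc,l) / sum_m (V_tlc,m - V_frc,m)
    """
    deltas = {}
    for lobe in LOBES:
        d = volumes.v_tlc[lobe] - volumes.v_frc[lobe]
        if d <= 0:
            raise ValueError(
                f"lobe {lobe.value}: V_tlc must exceed V_frc (got delta {d})"
            )
        deltas[lobe] = d
    total = sum(deltas.values())
    return LobarFractions(f={l: deltas[l] / total for l in LOBES})


def tidal_waveform(vt_L: float, period_s: float, n_cycles: int = 1) -> BreathingPattern:
    """Sinusoidal tidal breathing: Q(t) = (pi*VT/T) * sin(2*pi*t/T), L/s.

    The amplitude pi*VT/T makes the inspiratory half-cycle integral equal
    the tidal volume VT exactly.
    """
    if vt_L <= 0 or period_s <= 0:
        raise ValueError("tidal volume and period must be > 0")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    peak = math.pi * vt_L / period_s
    omega = 2.0 * math.pi / period_s

    def flow(t):
        return peak * np.sin(omega * np.asarray(t, dtype=float))

    return BreathingPattern(vt_L=vt_L, period_s=period_s, n_cycles=n_cycles, flow=flow)


def outlet_flow_profiles(
    tree: AirwayTree,
    fractions: LobarFractions,
    pattern: BreathingPattern,
    mode: str = "patient_specific",
) -> OutletFlowProfiles:
    """Distribute the mouth waveform over the terminal outlets.

    patient_specific
        Each lobe receives its ventilation fraction of the mouth flow,
        split within the lobe proportionally to outlet area (uniform face
        velocity across a lobe's outlets).
    area_uniform
        Flow split over *all* outlets proportionally to area, ignoring the
        lobar fractions (uniform face velocity everywhere) -- the
        reduced-order analog of setting every outlet to the same pressure.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    terminals = tree.terminals()
    areas = {b.id: b.outlet_area for b in terminals}
    lobe_of = {b.id: b.lobe for b in terminals}
    if any(lb is None for lb in lobe_of.values()):
        raise ValueError("terminal branches must carry lobe labels")

    weights: dict[str, float] = {}
    if mode == "area_uniform":
        total = sum(areas.values())
        weights = {bid: a / total for bid, a in areas.items()}
    else:
        lobe_area: dict[Lobe, float] = {l: 0.0 for l in LOBES}
        for bid, a in areas.items():
            lobe_area[lobe_of[bid]] += a
        for lobe in LOBES:
            if fractions.f[lobe] > 0 and lobe_area[lobe] <= 0:
                raise ValueError(f"lobe {lobe.value} has zero total outlet area")
        for bid, a in areas.items():
            lobe = lobe_of[bid]
            weights[bid] = fractions.f[lobe] * a / lobe_area[lobe]
    return OutletFlowProfiles(weights=weights, pattern=pattern, mode=mode)
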