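"""Reduced-order branch-network flow.

Instead of solving the Reynolds-averaged Navier-Stokes equations on a 3D
mesh, the flow in each branch is reconstructed from continuity alone:
the flow rate of a branch is the sum of the outlet flows of all terminals
below it, so the trachea carries exactly the mouth waveform.  Each branch
then supplies the particle tracker with

* a mean axial velocity U = Q / (pi r^2),
* an axial velocity profile: parabolic (Poiseuille) when the branch
  Reynolds number is below the pipe transition value, plug flow above it,
* a turbulence-kinetic-energy surrogate k = 3/2 (I |U|)^2 built from the
  fully-developed-pipe turbulence-intensity correlation
  I = 0.16 Re^(-1/8) (laminar branches use a small residual intensity),

replacing the two-equation turbulence closure of a resolved CFD model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import AirwayTree, Branch
from .ventilation import BreathingPattern, OutletFlowProfiles

__all__ = [
    "FluidProperties",
    "BranchFlow",
    "FlowSolution",
    "solve_branch_flows",
    "local_axial_velocity",
    "turbulence_state",
    "RE_CRIT",
    "I_LAMINAR",
]

#: Pipe-flow transition Reynolds number; ties are treated as turbulent.
RE_CRIT = 2300.0
#: Residual turbulence intensity used below transition.
I_LAMINAR = 0.02


@dataclass(frozen=True)
class FluidProperties:
    """Carrier-gas density (kg/m^3) and dynamic viscosity (Pa s).

    Defaults are ambient air.
    """

    rho: float = 1.204
    mu: float = 1.81e-5

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("fluid density and viscosity must be > 0")


@dataclass(frozen=True)
class BranchFlow:
    """Time-dependent flow state of one branch.

    The flow is proportional to the mouth waveform: Q_b(t) = w_b * Q(t),
    with a static weight w_b in [0, 1] from continuity.
    """

    weight: float
    radius: float
    pattern: BreathingPattern
    fluid: FluidProperties

    def Q(self, t):
        """Flow rate, L/s (signed; positive = toward the periphery)."""
        return self.weight * self.pattern.flow(t)

    def U_mean(self, t):
        """Cross-section mean axial velocity, m/s (signed)."""
        return np.asarray(self.Q(t)) * 1e-3 / (math.pi * self.radius**2)

    def Re(self, t):
        """Branch Reynolds number (non-negative)."""
        u = np.abs(self.U_mean(t))
        return self.fluid.rho * u * 2.0 * self.radius / self.fluid.mu

    def I(self, t):
        """Turbulence intensity."""
        re = np.asarray(self.Re(t), dtype=float)
        re_safe = np.maximum(re, 1e-300)
        return np.where(re >= RE_CRIT, 0.16 * re_safe ** (-1.0 / 8.0), I_LAMINAR)

    def k(self, t):
        """Turbulence kinetic energy surrogate, m^2/s^2."""
        return 1.5 * (self.I(t) * np.abs(self.U_mean(t))) ** 2


class FlowSolution:
    """Per-branch flow states over an airway tree (mapping id -> BranchFlow)."""

    def __init__(self, tree: AirwayTree, weights: np.ndarray,
                 pattern: BreathingPattern, fluid: FluidProperties):
        self.tree = tree
        self.arrays = tree.arrays()
        self.weights = weights  # aligned with tree.arrays() order
        self.pattern = pattern
        self.fluid = fluid

    def __getitem__(self, branch_id: str) -> BranchFlow:
        i = self.arrays.index[branch_id]
        return BranchFlow(weight=float(self.weights[i]),
                          radius=float(self.arrays.radius[i]),
                          pattern=self.pattern, fluid=self.fluid)

    def to_frame(self, times: np.ndarray) -> pd.DataFrame:
        """Export as a long table: branch_id, t, Q, U_mean, Re, k."""
        recs = []
        for bid in self.arrays.ids:
            bf = self[bid]
            recs.append(pd.DataFrame({
                "branch_id": bid, "t": times,
                "Q_L_per_s": np.asarray(bf.Q(times)),
                "U_mean_m_per_s": np.asarray(bf.U_mean(times)),
                "Re": np.asarray(bf.Re(times)),
                "k_m2_per_s2": np.asarray(bf.k(times)),
            }))
        return pd.concat(recs, ignore_index=True)


def solve_branch_flows(
    tree: AirwayTree,
    outlets: OutletFlowProfiles,
    fluid: FluidProperties | None = None,
) -> FlowSolution:
    """Propagate outlet flows up the tree by continuity.

    Every branch's flow is the sum over its descendant outlets, so mass is
    conserved at every junction and the trachea carries the full mouth
    waveform.
    """
    fluid = fluid or FluidProperties()
    ta = tree.arrays()
    terminal_ids = {b.id for b in tree.terminals()}
    if set(outlets.weights) != terminal_ids:
        raise ValueError("outlet profiles do not match the tree's terminal branches")
    weights = np.zeros(len(ta.ids))
    for bid, w in outlets.weights.items():
        weights[ta.index[bid]] = w
    # accumulate children into parents in reverse BFS order
    for i in range(len(ta.ids) - 1, 0, -1):
        weights[ta.parent[i]] += weights[i]
    return FlowSolution(tree, weights, outlets.pattern, fluid)


def local_axial_velocity(branch: Branch, flow: BranchFlow,
                         radial_fraction, t) -> np.ndarray | float:
    """Axial fluid velocity at radial position eta in [0, 1].

    Laminar branches (Re < RE_CRIT) use the parabolic Poiseuille profile
    u(eta) = 2 U (1 - eta^2); turbulent branches use plug flow u = U.  The
    sign follows the flow direction.
    """
    eta = np.asarray(radial_fraction, dtype=float)
    if np.any(eta < 0) or np.any(eta > 1):
        raise ValueError("radial_fraction must lie in [0, 1]")
    u = np.asarray(flow.U_mean(t), dtype=float)
    re = np.asarray(flow.Re(t), dtype=float)
    res = np.where(re < RE_CRIT, 2.0 * u * (1.0 - eta**2), u)
    return res if res.ndim else float(res)


def turbulence_state(branch: Branch, flow: BranchFlow, t) -> float:
    """Turbulence kinetic energy surrogate k (m^2/s^2) of a branch at time t."""
    res = np.asarray(flow.k(t), dtype=float)
    return res if res.ndim else float(res)
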