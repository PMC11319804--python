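"""Spherical drag law with piecewise coefficients.

The drag coefficient of a spherical particle is modelled as

    C_D = a1 + a2/Re_p + a3/Re_p^2,

with (a1, a2, a3) depending on the particle Reynolds number band, after
Morsi & Alexander's classical fit.  The lowest band reduces exactly to
Stokes drag (C_D = 24/Re_p).  The drag force enters the particle momentum
balance as a relaxation rate

    beta = 18 mu / (rho_p d_p^2) * C_D Re_p / 24   [1/s],

which tends to the Stokes rate 18 mu / (rho_p d_p^2) = 1/tau_p as the slip
velocity vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .flow import FluidProperties

if TYPE_CHECKING:  # pragma: no cover
    from .transport import Particle

__all__ = [
    "DragBand",
    "DragModel",
    "MORSI_ALEXANDER",
    "drag_coefficient",
    "cd_re_over_24",
    "drag_factor",
    "stokes_rate",
]


@dataclass(frozen=True)
class DragBand:
    re_lo: float
    re_hi: float
    a1: float
    a2: float
    a3: float

    def cd(self, re):
        re = np.asarray(re, dtype=float)
        return self.a1 + self.a2 / re + self.a3 / re**2


@dataclass(frozen=True)
class DragModel:
    """Ordered Reynolds-number bands partitioning (0, Re_max].

    Band i applies on (re_lo, re_hi]; construction verifies the bands are
    contiguous and that C_D is continuous at every interior edge to within
    5% relative (guarding against transcription errors in the table).
    """

    bands: Sequence[DragBand]

    def __post_init__(self) -> None:
        bs = list(self.bands)
        if not bs:
            raise ValueError("drag model needs at least one band")
        for lo, hi in zip(bs[:-1], bs[1:]):
            if lo.re_hi != hi.re_lo:
                raise ValueError("drag bands must be contiguous")
            edge = lo.re_hi
            c_lo, c_hi = float(lo.cd(edge)), float(hi.cd(edge))
            if abs(c_lo - c_hi) > 0.05 * max(abs(c_lo), abs(c_hi)):
                raise ValueError(
                    f"drag coefficient discontinuous at Re={edge}: "
                    f"{c_lo} vs {c_hi}"
                )

    @property
    def re_max(self) -> float:
        return self.bands[-1].re_hi


#: Piecewise spherical-drag coefficients (Morsi & Alexander bands).
MORSI_ALEXANDER = DragModel(bands=(
    DragBand(0.0, 0.1, 0.0, 24.0, 0.0),
    DragBand(0.1, 1.0, 3.690, 22.73, 0.0903),
    DragBand(1.0, 10.0, 1.222, 29.1667, -3.8889),
    DragBand(10.0, 100.0, 0.6167, 46.50, -116.67),
    DragBand(100.0, 1000.0, 0.3644, 98.33, -2778.0),
    DragBand(1000.0, 5000.0, 0.357, 148.62, -47500.0),
    DragBand(5000.0, 10000.0, 0.46, -490.546, 578700.0),
    DragBand(10000.0, 50000.0, 0.5191, -1662.5, 5416700.0),
))


def drag_coefficient(re_p, model: DragModel = MORSI_ALEXANDER):
    """Evaluate C_D = a1 + a2/Re + a3/Re^2 in the band containing Re_p.

    ``re_p`` must be positive and at most the model's Re_max.
    """
    re = np.asarray(re_p, dtype=float)
    if np.any(re <= 0):
        raise ValueError("particle Reynolds number must be > 0")
    if np.any(re > model.re_max):
        raise ValueError(f"particle Reynolds number above model range {model.re_max}")
    out = np.empty_like(re)
    filled = np.zeros(re.shape, dtype=bool)
    for band in model.bands:
        m = (re > band.re_lo) & (re <= band.re_hi) & ~filled
        if np.any(m):
            out[m] = band.cd(re[m])
            filled[m] = True
    return out if out.ndim else float(out)


def cd_re_over_24(re_p, model: DragModel = MORSI_ALEXANDER):
    """C_D * Re_p / 24, the Stokes-normalised drag correction.

    Defined by continuity as 1 at Re_p = 0 (Stokes limit); clamps to the
    last band above Re_max (relevant only for pathological slip).
    """
    re = np.asarray(re_p, dtype=float)
    out = np.ones_like(re)
    pos = re > 0
    if np.any(pos):
        re_cl = np.minimum(re[pos], model.re_max)
        out[pos] = np.asarray(drag_coefficient(re_cl, model)) * re_cl / 24.0
    return out if out.ndim else float(out)


def stokes_rate(d_p: float, rho_p: float, fluid: FluidProperties) -> float:
    """Stokes relaxation rate 18 mu / (rho_p d_p^2) = 1/tau_p, 1/s."""
    return 18.0 * fluid.mu / (rho_p * d_p**2)


def drag_factor(
    particle: "Particle",
    u_fluid: np.ndarray,
    fluid: FluidProperties,
    model: DragModel = MORSI_ALEXANDER,
) -> float:
    """Drag relaxation rate beta = 18 mu/(rho_p d_p^2) * C_D Re_p/24, 1/s.

    Re_p is built from the slip speed |u_p - u_fluid|; zero slip is
    handled through the Stokes limit (C_D Re_p / 24 -> 1).
    """
    slip = float(np.linalg.norm(np.asarray(particle.u_p) - np.asarray(u_fluid)))
    re_p = fluid.rho * particle.d_p * slip / fluid.mu
    return stokes_rate(particle.d_p, particle.rho_p, fluid) * cd_re_over_24(re_p, model)
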