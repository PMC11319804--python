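"""Particle-size distributions for device-like aerosols.

Dry-powder and nebulised aerosols are conventionally characterised by a
mass-median aerodynamic diameter (MMAD) and geometric standard deviation
(GSD) of a lognormal distribution, plus the fine-particle fraction (FPF):
the mass fraction below a cutoff (community default 5 um).  Diameters are
drawn directly from the mass-weighted lognormal, ln d ~ N(ln MMAD,
(ln GSD)^2); no count-median conversion is applied because MMAD is what
device data report.  FPF is computed from samples as a report field, not
imposed as a constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SizeDistribution", "sample_diameters", "fine_particle_fraction"]


@dataclass(frozen=True)
class SizeDistribution:
    """Monodisperse or lognormal (MMAD/GSD) particle-size distribution.

    All diameters in metres. ``fpf_cutoff`` is used only for reporting.
    """

    kind: str = "monodisperse"
    d: float = 1.32e-6
    mmad: float = 1.51e-6
    gsd: float = 2.23
    fpf_cutoff: float = 5e-6

    def __post_init__(self) -> None:
        if self.kind not in ("monodisperse", "lognormal"):
            raise ValueError("kind must be 'monodisperse' or 'lognormal'")
        if self.kind == "monodisperse" and self.d <= 0:
            raise ValueError("monodisperse diameter must be > 0")
        if self.kind == "lognormal":
            if self.mmad <= 0:
                raise ValueError("MMAD must be > 0")
            if self.gsd <= 1.0:
                raise ValueError("GSD must be > 1")


def sample_diameters(dist: SizeDistribution, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` particle diameters (m) from the distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if dist.kind == "monodisperse":
        return np.full(n, dist.d)
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=math.log(dist.mmad), sigma=math.log(dist.gsd), size=n)


def fine_particle_fraction(diameters: np.ndarray, cutoff: float = 5e-6) -> float:
    """Fraction of sampled particles below the fine-particle cutoff."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("no diameters given")
    return float(np.mean(d < cutoff))
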