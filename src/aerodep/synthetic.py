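"""Synthetic patient inputs.

The real study derives its inputs from paired inspiratory/expiratory CT
scans (airway geometry, per-lobe FRC and TLC volumes) and from SPECT
imaging (reference deposition tables).  None of those are public, so this
module generates statistically controlled stand-ins: a regular airway tree
(:mod:`aerodep.tree`), per-lobe FRC/TLC volumes whose differences encode a
prescribed lobar ventilation split, a tidal breathing pattern, and a noisy
four-zone reference deposition table emulating a SPECT readout.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from .tree import LOBES, AirwayTree, Lobe, TreeParams, generate_airway_tree

if TYPE_CHECKING:  # pragma: no cover
    from .accounting import DepositionReport
    from .comparison import SpectReference
    from .ventilation import BreathingPattern

__all__ = [
    "LungVolumes",
    "SyntheticPatient",
    "generate_lung_volumes",
    "generate_reference_spect",
    "make_patient",
    "save_volumes",
    "load_volumes",
    "REPRESENTATIVE_LOBAR_SPLIT",
]

#: Representative lobar airflow split (fractions over RUL, RML, RLL, LUL,
#: LLL) of a published example asthma patient.
REPRESENTATIVE_LOBAR_SPLIT: dict[Lobe, float] = {
    Lobe.RUL: 0.1209,
    Lobe.RML: 0.0539,
    Lobe.RLL: 0.3517,
    Lobe.LUL: 0.1486,
    Lobe.LLL: 0.3247,
}

# typical resting shares of FRC across the five lobes (size, not ventilation)
_FRC_SHARES = {Lobe.RUL: 0.20, Lobe.RML: 0.09, Lobe.RLL: 0.26,
               Lobe.LUL: 0.21, Lobe.LLL: 0.24}


@dataclass(frozen=True)
class LungVolumes:
    """Per-lobe lung volumes (litres) at FRC and TLC.

    The per-lobe difference TLC - FRC is the air volume moved by that lobe
    over a full inspiration and sets its ventilation fraction.
    """

    v_frc: dict[Lobe, float]
    v_tlc: dict[Lobe, float]

    def __post_init__(self) -> None:
        for lobe in LOBES:
            frc = self.v_frc[lobe]
            tlc = self.v_tlc[lobe]
            if not (tlc > frc > 0.0):
                raise ValueError(
                    f"lobe {lobe.value}: require V_tlc > V_frc > 0, "
                    f"got V_frc={frc}, V_tlc={tlc}"
                )

    def delta(self, lobe: Lobe) -> float:
        return self.v_tlc[lobe] - self.v_frc[lobe]


@dataclass
class SyntheticPatient:
    """Bundle of all per-patient inputs to the deposition pipeline."""

    tree: AirwayTree
    volumes: LungVolumes
    pattern: "BreathingPattern"
    reference: "SpectReference | None" = None

    def __post_init__(self) -> None:
        if self.tree.lobes_present() != set(self.volumes.v_frc):
            raise ValueError("lobes in tree and volumes disagree")


def generate_lung_volumes(
    target_fractions: dict[Lobe, float],
    total_delta: float = 3.0,
    frc_total: float = 3.0,
    seed: int = 0,
) -> LungVolumes:
    """Generate per-lobe FRC/TLC volumes realizing given ventilation fractions.

    ``target_fractions`` must sum to 1; the per-lobe volume differences
    TLC - FRC are set to ``total_delta * fraction`` so the ventilation
    split round-trips exactly.  FRC is partitioned across lobes around
    typical resting shares, with a mild seed-controlled Dirichlet jitter
    (FRC partitioning does not affect the ventilation fractions).

    Parameters
    ----------
    total_delta : float
        Total inspired volume TLC - FRC over all lobes, litres.
    frc_total : float
        Total FRC, litres.
    """
    fr = np.array([target_fractions[l] for l in LOBES], dtype=float)
    if np.any(fr < 0):
        raise ValueError("lobar fractions must be non-negative")
    # percentage tables rounded to two decimals may sum to ~99.98%; accept
    # and renormalise (the round-trip identity holds on the normalised simplex)
    if abs(fr.sum() - 1.0) > 5e-3:
        raise ValueError(f"lobar fractions must sum to 1, got {fr.sum()!r}")
    fr = fr / fr.sum()
    if total_delta <= 0:
        raise ValueError("total_delta must be > 0")
    rng = np.random.default_rng(seed)
    shares = np.array([_FRC_SHARES[l] for l in LOBES])
    shares = rng.dirichlet(shares * 200.0)  # mild jitter around typical shares
    frc = frc_total * shares
    delta = total_delta * fr
    if np.any(delta <= 0):
        # a zero fraction would violate V_tlc > V_frc; nudge is not allowed,
        # report instead
        bad = [LOBES[i].value for i in np.flatnonzero(delta <= 0)]
        raise ValueError(f"zero ventilation fraction for lobe(s): {', '.join(bad)}")
    return LungVolumes(
        v_frc={l: float(frc[i]) for i, l in enumerate(LOBES)},
        v_tlc={l: float(frc[i] + delta[i]) for i, l in enumerate(LOBES)},
    )


def perturb_four_zone(vec: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Pre-normalization noise step of :func:`generate_reference_spect`.

    Adds independent zero-mean Gaussian perturbations (sd in percentage
    points) to a four-zone deposition vector and clips at zero.
    """
    noisy = vec + rng.normal(0.0, noise_sd, size=vec.shape) if noise_sd > 0 else vec.copy()
    return np.clip(noisy, 0.0, None)


def generate_reference_spect(
    report: "DepositionReport",
    noise_sd: float = 2.0,
    seed: int = 0,
) -> "SpectReference":
    """Emulate a SPECT-style four-zone lobar reference table.

    Takes the model's four-zone lobar vector (RUL+RML merged), perturbs
    each zone with independent zero-mean Gaussian noise of ``noise_sd``
    percentage points, clips at zero, and renormalizes to the original
    four-zone total, mimicking the count-normalized nature of a SPECT
    readout.
    """
    from .comparison import SpectReference, four_zone_vector

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    vec = four_zone_vector(report).to_numpy()
    rng = np.random.default_rng(seed)
    noisy = perturb_four_zone(vec, noise_sd, rng)
    total = vec.sum()
    if noisy.sum() > 0:
        noisy = noisy * (total / noisy.sum())
    return SpectReference(
        rul_rml=float(noisy[0]), rll=float(noisy[1]),
        lul=float(noisy[2]), lll=float(noisy[3]),
    )


def make_patient(
    fractions: dict[Lobe, float] | None = None,
    tree_params: TreeParams | None = None,
    vt_L: float = 0.5,
    period_s: float = 4.0,
    n_cycles: int = 1,
    seed: int = 0,
) -> SyntheticPatient:
    """Convenience constructor for a complete synthetic patient."""
    from .ventilation import tidal_waveform

    fractions = fractions or REPRESENTATIVE_LOBAR_SPLIT
    tree = generate_airway_tree(tree_params, seed=seed)
    volumes = generate_lung_volumes(fractions, seed=seed)
    pattern = tidal_waveform(vt_L, period_s, n_cycles=n_cycles)
    return SyntheticPatient(tree=tree, volumes=volumes, pattern=pattern)


def volumes_to_text(volumes: LungVolumes) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["lobe", "v_frc_L", "v_tlc_L"])
    for lobe in LOBES:
        w.writerow([lobe.value, repr(volumes.v_frc[lobe]), repr(volumes.v_tlc[lobe])])
    return buf.getvalue()


def volumes_from_text(text: str) -> LungVolumes:
    rows = list(csv.DictReader(io.StringIO(text)))
    v_frc = {Lobe(r["lobe"]): float(r["v_frc_L"]) for r in rows}
    v_tlc = {Lobe(r["lobe"]): float(r["v_tlc_L"]) for r in rows}
    if set(v_frc) != set(LOBES):
        raise ValueError("volumes table must contain exactly the five lobes")
    return LungVolumes(v_frc=v_frc, v_tlc=v_tlc)


def save_volumes(volumes: LungVolumes, path: str | Path) -> None:
    Path(path).write_text(volumes_to_text(volumes))


def load_volumes(path: str | Path) -> LungVolumes:
    return volumes_from_text(Path(path).read_text())
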