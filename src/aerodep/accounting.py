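"""Regional deposition dosimetry.

Particle fates are aggregated into percentages of delivered dose (%DD,
relative to the dose entering the mouth) by zone, lobe and airway
generation.  Aggregation rules:

* intrathoracic = distal + peripheral (the convention of SPECT lobar
  deposition tables; central deposition is reported separately);
* per-lobe totals combine the lobe's distal wall deposition and its
  peripheral (outlet-escape) dose, e.g. RUL = RUL_d + RUL_p;
* particles still airborne at simulation end are reported as their own
  ``suspended`` class, never folded into peripheral dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .tree import LOBES, Zone

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import SyntheticPatient
    from .transport import SimParams

__all__ = [
    "DepositionTally",
    "DepositionReport",
    "report",
    "generational_table",
    "convergence_study",
    "tally_from_cloud",
]


@dataclass
class DepositionTally:
    """Raw particle-fate counts.

    ``counts`` maps (zone, lobe-or-None, generation) to a deposition
    count; peripheral entries use the terminal branch's lobe and
    generation.  ``particles`` optionally carries the per-particle fate
    table (the exportable deposition point cloud).
    """

    counts: dict[tuple[str, str | None, int], int]
    exhaled: int
    suspended: int
    n_injected: int
    particles: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        total = sum(self.counts.values()) + self.exhaled + self.suspended
        if total != self.n_injected:
            raise ValueError(
                f"tally does not conserve particles: {total} != {self.n_injected}"
            )

    def zone_count(self, zone: str) -> int:
        return sum(c for (z, _, _), c in self.counts.items() if z == zone)

    def lobe_parts(self, lobe: str) -> tuple[int, int]:
        """(distal, peripheral) counts of one lobe."""
        d = sum(c for (z, l, _), c in self.counts.items()
                if l == lobe and z == Zone.DISTAL.value)
        p = sum(c for (z, l, _), c in self.counts.items()
                if l == lobe and z == Zone.PERIPHERAL.value)
        return d, p


@dataclass
class DepositionReport:
    """Regional deposition as percentages of delivered dose."""

    extrathoracic: float
    central: float
    distal: float
    peripheral: float
    intrathoracic: float
    lobar_distal: dict[str, float]
    lobar_peripheral: dict[str, float]
    lobar_total: dict[str, float]
    generations: dict[int, float]
    exhaled: float
    suspended: float
    n_injected: int

    def to_dict(self) -> dict:
        return {
            "n_injected": self.n_injected,
            "pct_dd": {
                "extrathoracic": self.extrathoracic,
                "central": self.central,
                "distal": self.distal,
                "peripheral": self.peripheral,
                "intrathoracic": self.intrathoracic,
                "exhaled": self.exhaled,
                "suspended": self.suspended,
            },
            "lobar_pct_dd": {l: self.lobar_total[l] for l in self.lobar_total},
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [("extrathoracic", self.extrathoracic),
                ("central", self.central),
                ("distal", self.distal),
                ("peripheral", self.peripheral),
                ("intrathoracic", self.intrathoracic),
                ("exhaled", self.exhaled),
                ("suspended", self.suspended)]
        rows += [(f"lobe_{l}", v) for l, v in self.lobar_total.items()]
        return pd.DataFrame(rows, columns=["region", "pct_dd"])


def report(tally: DepositionTally) -> DepositionReport:
    """Convert raw counts into a %DD regional deposition report."""
    if tally.n_injected == 0:
        raise ValueError("cannot report on an empty injection")
    scale = 100.0 / tally.n_injected
    ext = tally.zone_count(Zone.EXTRATHORACIC.value) * scale
    cen = tally.zone_count(Zone.CENTRAL.value) * scale
    dis = tally.zone_count(Zone.DISTAL.value) * scale
    per = tally.zone_count(Zone.PERIPHERAL.value) * scale
    lob_d, lob_p, lob_t = {}, {}, {}
    for lobe in LOBES:
        d, p = tally.lobe_parts(lobe.value)
        lob_d[lobe.value] = d * scale
        lob_p[lobe.value] = p * scale
        lob_t[lobe.value] = (d + p) * scale
    gens: dict[int, float] = {}
    for (z, _, g), c in tally.counts.items():
        if z in (Zone.CENTRAL.value, Zone.DISTAL.value):
            gens[g] = gens.get(g, 0.0) + c * scale
    return DepositionReport(
        extrathoracic=ext, central=cen, distal=dis, peripheral=per,
        intrathoracic=dis + per,
        lobar_distal=lob_d, lobar_peripheral=lob_p, lobar_total=lob_t,
        generations=dict(sorted(gens.items())),
        exhaled=tally.exhaled * scale,
        suspended=tally.suspended * scale,
        n_injected=tally.n_injected,
    )


def generational_table(tally: DepositionTally) -> pd.DataFrame:
    """%DD per airway generation, with peripheral as a terminal class.

    Rows cover generations 0..G for central/distal wall deposition plus a
    final ``peripheral`` row; the column total equals the central + distal
    + peripheral share of the dose.
    """
    rep = report(tally)
    max_gen = max(rep.generations) if rep.generations else 0
    rows = [(str(g), rep.generations.get(g, 0.0)) for g in range(max_gen + 1)]
    rows.append(("peripheral", rep.peripheral))
    return pd.DataFrame(rows, columns=["generation", "pct_dd"])


def tally_from_cloud(tree, cloud: pd.DataFrame) -> DepositionTally:
    """Rebuild a deposition tally from an exported particle fate table."""
    counts: dict[tuple[str, str | None, int], int] = {}
    exhaled = suspended = 0
    for branch_id, status_group in cloud.groupby("branch_id", observed=True):
        br = tree[branch_id]
        lobe = br.lobe.value if br.lobe is not None else None
        for status, grp in status_group.groupby("status", observed=True):
            c = len(grp)
            if c == 0:
                continue
            if status == "trapped":
                key = (br.zone.value, lobe, br.generation)
                counts[key] = counts.get(key, 0) + c
            elif status == "escaped":
                key = (Zone.PERIPHERAL.value, lobe, br.generation)
                counts[key] = counts.get(key, 0) + c
            elif status == "exhaled":
                exhaled += c
            else:
                suspended += c
    return DepositionTally(counts=counts, exhaled=exhaled, suspended=suspended,
                           n_injected=len(cloud))


def convergence_study(
    patient: "SyntheticPatient",
    particle_counts: list[int],
    params: "SimParams",
    mode: str = "patient_specific",
) -> pd.DataFrame:
    """Injection-count independence harness.

    Runs one simulation per particle count (seeds derived from the master
    seed) and tabulates intrathoracic/distal/peripheral %DD together with
    ``max_spread_above``: for each row, the largest max-min spread of any
    of the three zones over this and all larger counts.  Stability of the
    spread as the count grows indicates injection-count independence.
    """
    from dataclasses import replace as _replace

    from .transport import run_simulation

    if not particle_counts:
        raise ValueError("particle_counts must be non-empty")
    if sorted(particle_counts) != list(particle_counts):
        raise ValueError("particle_counts must be sorted ascending")
    ss = np.random.SeedSequence(params.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(particle_counts))]
    rows = []
    for n, seed in zip(particle_counts, seeds):
        p = _replace(params, n_particles=int(n), seed=seed)
        rep = report(run_simulation(patient, p, mode=mode))
        rows.append({"n": int(n), "intrathoracic": rep.intrathoracic,
                     "distal": rep.distal, "peripheral": rep.peripheral})
    df = pd.DataFrame(rows)
    spreads = []
    for i in range(len(df)):
        tail = df.iloc[i:][["intrathoracic", "distal", "peripheral"]]
        spreads.append(float((tail.max() - tail.min()).max()) if len(tail) > 1
                       else np.nan)
    df["max_spread_above"] = spreads
    return df
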