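"""Model-vs-SPECT comparison surface.

Low-dose SPECT/CT cannot resolve the horizontal fissure reliably, so the
right upper and middle lobes are merged and lobar deposition is compared
on four zones: RUL+RML, RLL, LUL, LLL, each expressed as a percentage of
the intrathoracic lobar dose (the four zones sum to 100).  The validation
statistic is the *mean absolute lobar difference*: the average of the four
per-zone absolute differences between model and reference, in percentage
points.  A cohort is summarised by averaging the per-patient means at
reporting precision (two decimals), matching published table arithmetic.

Scintigraphy-like projection images accumulate deposition sites along one
spatial axis onto a 2D grid.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .accounting import DepositionReport

__all__ = [
    "SpectReference",
    "ComparisonResult",
    "FOUR_ZONES",
    "four_zone_vector",
    "mean_difference",
    "cohort_mean",
    "projection_image",
    "deposition_coordinates",
    "load_reference",
    "save_reference",
]

FOUR_ZONES = ("RUL_RML", "RLL", "LUL", "LLL")


@dataclass(frozen=True)
class SpectReference:
    """Four-zone lobar deposition reference (percent of lobar dose)."""

    rul_rml: float
    rll: float
    lul: float
    lll: float

    def __post_init__(self) -> None:
        if min(self.rul_rml, self.rll, self.lul, self.lll) < 0:
            raise ValueError("reference percentages must be >= 0")

    def to_numpy(self) -> np.ndarray:
        return np.array([self.rul_rml, self.rll, self.lul, self.lll])

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_numpy(), index=list(FOUR_ZONES))


@dataclass(frozen=True)
class ComparisonResult:
    """Per-zone absolute differences and their mean, percentage points."""

    differences: pd.Series
    mean_difference: float

    def __post_init__(self) -> None:
        if abs(self.mean_difference - float(self.differences.mean())) > 1e-12:
            raise ValueError("mean_difference inconsistent with differences")


def four_zone_vector(report: DepositionReport, rescale_to: float = 100.0) -> pd.Series:
    """Merge RUL+RML and rescale the lobar totals to the reference convention.

    Returns a Series over (RUL_RML, RLL, LUL, LLL) summing to
    ``rescale_to`` (default 100, percent of intrathoracic lobar dose).
    """
    lt = report.lobar_total
    merged = np.array([lt["RUL"] + lt["RML"], lt["RLL"], lt["LUL"], lt["LLL"]])
    total = merged.sum()
    if total <= 0:
        raise ValueError("zero lobar deposition; cannot form four-zone vector")
    return pd.Series(merged * (rescale_to / total), index=list(FOUR_ZONES))


def _as_vec4(v) -> np.ndarray:
    if isinstance(v, SpectReference):
        arr = v.to_numpy()
    elif isinstance(v, pd.Series):
        arr = v.to_numpy(dtype=float)
    else:
        arr = np.asarray(v, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"expected a four-zone vector, got shape {arr.shape}")
    return arr


def mean_difference(model4, reference4) -> ComparisonResult:
    """Mean absolute lobar difference between two four-zone vectors."""
    m = _as_vec4(model4)
    r = _as_vec4(reference4)
    diffs = pd.Series(np.abs(m - r), index=list(FOUR_ZONES))
    return ComparisonResult(differences=diffs,
                            mean_difference=float(diffs.mean()))


def cohort_mean(results: Iterable[ComparisonResult | float], ndigits: int = 2) -> float:
    """Cohort-level mean of per-patient mean differences.

    Each per-patient value is first rounded to reporting precision
    (``ndigits`` decimals, as in published tables), then averaged exactly
    in decimal arithmetic so the result matches table arithmetic free of
    binary round-off; round the returned value to ``ndigits`` for display.
    """
    from decimal import ROUND_HALF_EVEN, Decimal

    vals = [r.mean_difference if isinstance(r, ComparisonResult) else float(r)
            for r in results]
    if not vals:
        raise ValueError("cohort_mean needs at least one result")
    q = Decimal(1).scaleb(-ndigits)
    dec = [Decimal(str(v)).quantize(q, rounding=ROUND_HALF_EVEN) for v in vals]
    return float(sum(dec) / len(dec))


def deposition_coordinates(tree, cloud: pd.DataFrame) -> np.ndarray:
    """3D positions (m) of deposited/escaped particles from branch frames.

    ``cloud`` is the per-particle fate table of a simulation; only rows
    with status ``trapped`` or ``escaped`` are mapped.
    """
    ta = tree.arrays()
    dep = cloud[cloud["status"].isin(["trapped", "escaped"])]
    if len(dep) == 0:
        return np.empty((0, 3))
    bi = np.array([ta.index[bid] for bid in dep["branch_id"]])
    s = dep["s"].to_numpy()
    r = dep["eta"].to_numpy() * ta.radius[bi]
    phi = dep["phi"].to_numpy()
    pos = (ta.origin[bi]
           + s[:, None] * ta.direction[bi]
           + (r * np.cos(phi))[:, None] * ta.e1[bi]
           + (r * np.sin(phi))[:, None] * ta.e2[bi])
    return pos


def projection_image(
    points: np.ndarray,
    axis: str = "y",
    grid: tuple[int, int] = (128, 128),
    extent: Sequence[float] | None = None,
) -> np.ndarray:
    """Accumulate deposition sites into a 2D grid along one axis.

    Emulates a planar scintigraphy view: counts are summed in the
    direction perpendicular to the image plane.  The grid total equals the
    number of points.

    Parameters
    ----------
    points : (N, 3) array
        Deposition coordinates.
    axis : {"x", "y", "z"}
        Projection (line-of-sight) axis.
    extent : (umin, umax, vmin, vmax), optional
        Image-plane bounds; defaults to the data bounding box.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
        raise ValueError("points must be a non-empty (N, 3) array")
    rows, cols = grid
    if rows <= 0 or cols <= 0:
        raise ValueError("grid dimensions must be positive")
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    keep = [i for i in range(3) if i != ax]
    u, v = pts[:, keep[0]], pts[:, keep[1]]
    if extent is None:
        pad = 1e-9
        extent = (u.min() - pad, u.max() + pad, v.min() - pad, v.max() + pad)
    umin, umax, vmin, vmax = extent
    if not (umax > umin and vmax > vmin):
        raise ValueError("degenerate projection extent")
    img, _, _ = np.histogram2d(u, v, bins=(rows, cols),
                               range=[[umin, umax], [vmin, vmax]])
    return img


def load_reference(path: str | Path) -> SpectReference:
    """Read a four-zone reference table (CSV header: zone,percent)."""
    rows = list(csv.DictReader(io.StringIO(Path(path).read_text())))
    vals = {r["zone"]: float(r["percent"]) for r in rows}
    missing = set(FOUR_ZONES) - set(vals)
    if missing:
        raise ValueError(f"reference table missing zones: {sorted(missing)}")
    return SpectReference(rul_rml=vals["RUL_RML"], rll=vals["RLL"],
                          lul=vals["LUL"], lll=vals["LLL"])


def save_reference(ref: SpectReference, path: str | Path) -> None:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["zone", "percent"])
    for zone, val in zip(FOUR_ZONES, ref.to_numpy()):
        w.writerow([zone, repr(float(val))])
    Path(path).write_text(buf.getvalue())
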