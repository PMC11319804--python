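"""Run configuration and the end-to-end pipeline.

Configuration is a structured YAML document; every physical quantity
carries its unit in the key name (``vt_L``, ``dt_s``, ...) to prevent unit
drift.  A pipeline run writes all stage outputs plus a manifest recording
the config hash, seed and package version; identical config and seed
produce byte-identical outputs (no clocks, no unseeded entropy).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .accounting import generational_table, report
from .comparison import four_zone_vector, load_reference, mean_difference
from .polydisperse import SizeDistribution, sample_diameters
from .synthetic import (
    REPRESENTATIVE_LOBAR_SPLIT,
    SyntheticPatient,
    load_volumes,
    save_volumes,
    generate_lung_volumes,
)
from .flow import FluidProperties
from .transport import SimParams, run_simulation
from .tree import Lobe, TreeParams, generate_airway_tree, save_tree
from .ventilation import MODES, tidal_waveform

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    tree: TreeParams = field(default_factory=TreeParams)
    volumes_file: str | None = None
    fractions: dict[str, float] | None = None
    total_delta_L: float = 3.0
    frc_total_L: float = 3.0
    vt_L: float = 0.5
    period_s: float = 4.0
    n_cycles: int = 1
    fluid: FluidProperties = field(default_factory=FluidProperties)
    dt_s: float = 5e-3
    n_particles: int = 50_000
    max_time_s: float | None = None
    turbulence: bool = True
    mode: str = "patient_specific"
    size: SizeDistribution = field(default_factory=SizeDistribution)
    reference_file: str | None = None
    outdir: str = "aerodep_out"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.volumes_file is not None and not Path(self.volumes_file).exists():
            raise ValueError(f"volumes file not found: {self.volumes_file}")
        if self.reference_file is not None and not Path(self.reference_file).exists():
            raise ValueError(f"reference file not found: {self.reference_file}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "seed" not in d:
            raise ValueError("config must set a seed explicitly")
        if "tree" in d:
            d["tree"] = TreeParams(**d["tree"])
        if "fluid" in d:
            d["fluid"] = FluidProperties(**d["fluid"])
        if "size" in d:
            d["size"] = SizeDistribution(**d["size"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the computation-relevant configuration (excludes outdir)."""
        d = self.to_dict()
        d.pop("outdir", None)
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _build_patient(cfg: RunConfig) -> SyntheticPatient:
    tree = generate_airway_tree(cfg.tree, seed=cfg.seed)
    if cfg.volumes_file is not None:
        volumes = load_volumes(cfg.volumes_file)
    else:
        fr = cfg.fractions or {l.value: f for l, f in REPRESENTATIVE_LOBAR_SPLIT.items()}
        volumes = generate_lung_volumes(
            {Lobe(k): v for k, v in fr.items()},
            total_delta=cfg.total_delta_L, frc_total=cfg.frc_total_L,
            seed=cfg.seed,
        )
    pattern = tidal_waveform(cfg.vt_L, cfg.period_s, n_cycles=cfg.n_cycles)
    return SyntheticPatient(tree=tree, volumes=volumes, pattern=pattern)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run generate -> ventilate -> transport -> report (-> compare).

    Writes tree, volumes, regional and generational reports, the particle
    fate table, an optional comparison result, and a manifest to
    ``cfg.outdir``.  Returns the in-memory artifact bundle.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # annotate failures with the stage
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrap

    patient = stage("generate")(lambda: _build_patient(cfg))
    save_tree(patient.tree, out / "tree.txt")
    save_volumes(patient.volumes, out / "volumes.csv")
    log.append(f"generate: {len(patient.tree)} branches, "
               f"{len(patient.tree.terminals())} outlets")

    params = SimParams(dt_s=cfg.dt_s, n_particles=cfg.n_particles, seed=cfg.seed,
                       max_time_s=cfg.max_time_s, turbulence=cfg.turbulence)
    diameters = None
    if cfg.size.kind == "lognormal":
        diameters = sample_diameters(cfg.size, cfg.n_particles, seed=cfg.seed)
    tally = stage("transport")(
        lambda: run_simulation(patient, params, mode=cfg.mode,
                               fluid=cfg.fluid, diameters=diameters))
    conserved = (sum(tally.counts.values()) + tally.exhaled + tally.suspended
                 == tally.n_injected)
    log.append(f"transport: n={tally.n_injected}, conservation_ok={conserved}")

    rep = stage("report")(lambda: report(tally))
    rep.to_frame().to_csv(out / "report.csv", index=False)
    (out / "report.yaml").write_text(yaml.safe_dump(rep.to_dict(), sort_keys=True))
    generational_table(tally).to_csv(out / "generational.csv", index=False)
    tally.particles.to_csv(out / "particles.csv", index=False)
    log.append(f"report: intrathoracic={rep.intrathoracic:.3f}%DD")

    bundle = {"patient": patient, "tally": tally, "report": rep}
    if cfg.reference_file is not None:
        ref = load_reference(cfg.reference_file)
        cmp_res = stage("compare")(
            lambda: mean_difference(four_zone_vector(rep), ref))
        (out / "comparison.yaml").write_text(yaml.safe_dump({
            "differences_pp": {z: float(v) for z, v in cmp_res.differences.items()},
            "mean_difference_pp": float(cmp_res.mean_difference),
        }, sort_keys=True))
        bundle["comparison"] = cmp_res
        log.append(f"compare: mean_difference={cmp_res.mean_difference:.3f}pp")

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": log,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
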