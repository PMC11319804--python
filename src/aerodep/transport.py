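"""Lagrangian particle transport through the airway tree.

Particles obey the force balance

    dx_p/dt = u_p,        m_p du_p/dt = F_D,

with drag as the only force (gravity, buoyancy and Brownian motion are
negligible for micron-sized pharmaceutical aerosol).  Writing the drag as a
relaxation rate beta (see :mod:`aerodep.drag`), the velocity update over a
step is the exact solution for frozen fluid velocity,

    u_p(t + dt) = u_f + (u_p(t) - u_f) exp(-beta dt),

which is unconditionally stable for any dt (beta ~ 2e5 1/s for 1.32 um
droplets, far stiffer than any practical time step).  Positions advance
with the trapezoid of the old and new particle velocity.

Turbulent dispersion uses a discrete-random-walk (eddy-interaction) model:
while a particle is inside an eddy it sees a frozen Gaussian velocity
fluctuation with per-component variance 2k/3; when the eddy lifetime
expires a new fluctuation is drawn.

Particle coordinates are local to the current branch: axial position s,
radial fraction eta = r/R in [0, 1], azimuth phi.  Boundary events:

* eta >= 1: *trap* -- deposited on the wall (zone/lobe/generation of the
  branch are recorded);
* s beyond a terminal branch during inflow: *escape* -- leaves through a
  resolved outlet, scored as peripheral dose of that branch's lobe;
* s beyond a non-terminal branch: transfer to a daughter chosen with
  probability proportional to the instantaneous daughter flow magnitude;
* s < 0 at the mouth inlet during expiration: *exhaled*.

One-way coupling is assumed and checked: a warning is emitted if the
particle volume fraction exceeds 1e-6, the dilute-flow threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .accounting import DepositionTally
from .drag import MORSI_ALEXANDER, DragModel, cd_re_over_24, drag_factor
from .flow import (
    I_LAMINAR,
    RE_CRIT,
    FluidProperties,
    FlowSolution,
    local_axial_velocity,
    solve_branch_flows,
)
from .synthetic import SyntheticPatient
from .tree import LOBES, AirwayTree, Branch, Zone
from .ventilation import lobar_fractions, outlet_flow_profiles

__all__ = [
    "Particle",
    "EddyState",
    "SimParams",
    "sample_fluctuation",
    "advance_particle",
    "check_boundary",
    "run_simulation",
    "particle_volume_fraction",
]

#: Eddy length scale coefficient: L_e = 0.07 * branch diameter.
EDDY_LENGTH_COEFF = 0.07

STATUS_SUSPENDED = "suspended"
STATUS_TRAPPED = "trapped"
STATUS_ESCAPED = "escaped"
STATUS_EXHALED = "exhaled"


@dataclass
class Particle:
    """Lagrangian particle state in branch-local coordinates.

    ``u_p`` holds (axial, radial, tangential) velocity components in m/s.
    Status transitions are one-way from ``suspended``.
    """

    branch_id: str
    s: float = 0.0
    eta: float = 0.0
    phi: float = 0.0
    u_p: np.ndarray = field(default_factory=lambda: np.zeros(3))
    d_p: float = 1.32e-6
    rho_p: float = 1015.0
    status: str = STATUS_SUSPENDED
    injection_time: float = 0.0

    @property
    def m_p(self) -> float:
        """Particle mass, kg (consistent with d_p and rho_p)."""
        return self.rho_p * math.pi * self.d_p**3 / 6.0


@dataclass
class EddyState:
    """Frozen turbulent velocity fluctuation and its remaining lifetime."""

    u_prime: np.ndarray = field(default_factory=lambda: np.zeros(3))
    remaining_lifetime: float = 0.0


@dataclass(frozen=True)
class SimParams:
    """Simulation controls.

    dt_s defaults to 5e-3 s.  ``n_particles`` is desk-scale (5e4); the
    convergence harness (:func:`aerodep.accounting.convergence_study`)
    quantifies the sampling error this leaves.  ``max_time_s`` defaults to
    the full breathing pattern duration.  ``injection_profile`` is
    ``"disc"`` (area-uniform over the inlet cross-section) or
    ``"centerline"``; ``turbulence=False`` forces k = 0 everywhere.
    """

    dt_s: float = 5e-3
    n_particles: int = 50_000
    seed: int = 0
    max_time_s: float | None = None
    coupling_volume_fraction_limit: float = 1e-6
    d_p: float = 1.32e-6
    rho_p: float = 1015.0
    turbulence: bool = True
    injection_profile: str = "disc"
    eps_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.injection_profile not in ("disc", "centerline"):
            raise ValueError("injection_profile must be 'disc' or 'centerline'")


def particle_volume_fraction(diameters: np.ndarray, domain_volume: float) -> float:
    """Total particle volume over domain volume (one-way-coupling check)."""
    d = np.asarray(diameters, dtype=float)
    return float(np.sum(math.pi * d**3 / 6.0) / domain_volume)


def sample_fluctuation(
    k: float,
    rng: np.random.Generator,
    eddy: EddyState | None,
    branch: Branch,
    dt: float = 0.0,
    eps_floor: float = 1e-6,
) -> EddyState:
    """Discrete-random-walk eddy interaction.

    If the current eddy has expired (or none exists), draw a new isotropic
    Gaussian fluctuation with per-component standard deviation
    sigma = sqrt(2k/3) and lifetime L_e / max(sigma, eps_floor), with eddy
    length L_e = 0.07 * branch diameter.  Otherwise keep the fluctuation
    and decrement the lifetime by ``dt``.
    """
    if k < 0:
        raise ValueError("turbulence kinetic energy must be >= 0")
    if eddy is None or eddy.remaining_lifetime <= 0.0:
        sigma = math.sqrt(2.0 * k / 3.0)
        u_prime = rng.standard_normal(3) * sigma
        lifetime = EDDY_LENGTH_COEFF * branch.diameter / max(sigma, eps_floor)
        return EddyState(u_prime=u_prime, remaining_lifetime=lifetime - dt)
    return EddyState(u_prime=eddy.u_prime,
                     remaining_lifetime=eddy.remaining_lifetime - dt)


def advance_particle(
    particle: Particle,
    flow: FlowSolution,
    fluid: FluidProperties,
    model: DragModel = MORSI_ALEXANDER,
    eddy: EddyState | None = None,
    dt: float = 5e-3,
    t: float = 0.0,
) -> Particle:
    """One transport step: relax velocity toward the local fluid velocity
    and advance the position with the trapezoid of old/new velocity.

    The local fluid velocity is the mean axial profile at the particle's
    radial position plus the eddy fluctuation.  ``dt = 0`` returns the
    particle unchanged.
    """
    if particle.status != STATUS_SUSPENDED:
        raise ValueError("can only advance suspended particles")
    if dt == 0.0:
        return replace(particle, u_p=particle.u_p.copy())
    branch = flow.tree[particle.branch_id]
    bf = flow[particle.branch_id]
    u_prime = eddy.u_prime if eddy is not None else np.zeros(3)
    u_ax = float(local_axial_velocity(branch, bf, particle.eta, t))
    u_f = np.array([u_ax + u_prime[0], u_prime[1], u_prime[2]])
    beta = drag_factor(particle, u_f, fluid, model)
    decay = math.exp(-beta * dt)
    u_new = u_f + (particle.u_p - u_f) * decay
    s = particle.s + dt * 0.5 * (particle.u_p[0] + u_new[0])
    r = particle.eta * branch.radius + dt * 0.5 * (particle.u_p[1] + u_new[1])
    phi = particle.phi + dt * u_new[2] / max(abs(r), 0.05 * branch.radius)
    if r < 0.0:  # crossed the centerline: reflect the radial axis
        r = -r
        phi += math.pi
        u_new[1] = -u_new[1]
    return replace(particle, s=s, eta=r / branch.radius, phi=phi, u_p=u_new)


def check_boundary(
    particle: Particle,
    tree: AirwayTree,
    flow: FlowSolution,
    rng: np.random.Generator,
    t: float = 0.0,
) -> str:
    """Classify and apply the boundary event for a particle after a step.

    Returns one of ``"none"``, ``"trap"``, ``"junction_transfer"``,
    ``"escape"``, ``"exhaled"`` and updates the particle in place (status,
    or branch/axial position for transfers).  Trap wins over axial events.
    """
    if particle.status != STATUS_SUSPENDED:
        raise ValueError("can only check suspended particles")
    branch = tree[particle.branch_id]
    if particle.eta >= 1.0:
        particle.status = STATUS_TRAPPED
        particle.eta = 1.0
        return "trap"
    if particle.s > branch.length:
        if branch.is_terminal:
            if float(flow[branch.id].Q(t)) > 0.0:
                particle.status = STATUS_ESCAPED
                particle.s = branch.length
                return "escape"
            particle.s = branch.length
            return "none"
        kids = sorted(branch.children)
        q = np.array([abs(float(flow[k].Q(t))) for k in kids])
        total = q.sum()
        p1 = q[0] / total if total > 0 else 0.5
        chosen = kids[0] if rng.random() < p1 else kids[1] if len(kids) > 1 else kids[0]
        particle.branch_id = chosen
        particle.s = 0.0
        return "junction_transfer"
    if particle.s < 0.0:
        if branch.parent is None:
            if float(flow[branch.id].Q(t)) < 0.0:
                particle.status = STATUS_EXHALED
                particle.s = 0.0
                return "exhaled"
            particle.s = 0.0
            return "none"
        particle.branch_id = branch.parent
        particle.s = tree[branch.parent].length
        return "junction_transfer"
    return "none"


# ---------------------------------------------------------------------------
# vectorised engine (same kernels over all particles on a shared time grid)
# ---------------------------------------------------------------------------

_ZONE_NAMES = {0: Zone.EXTRATHORACIC.value, 1: Zone.CENTRAL.value, 2: Zone.DISTAL.value}
_STATUS_NAMES = {0: STATUS_SUSPENDED, 1: STATUS_TRAPPED, 2: STATUS_ESCAPED,
                 3: STATUS_EXHALED}


def run_simulation(
    patient: SyntheticPatient,
    params: SimParams,
    mode: str = "patient_specific",
    fluid: FluidProperties | None = None,
    model: DragModel = MORSI_ALEXANDER,
    diameters: np.ndarray | None = None,
) -> DepositionTally:
    """Simulate aerosol transport and deposition for one patient.

    Particles are injected at the mouth inlet over the inspiratory phase,
    with injection times distributed proportionally to the instantaneous
    inhaled flow (continuous nebulised delivery), and tracked until they
    deposit, escape, are exhaled, or the simulation clock runs out.
    Delivered dose is the full injected count.

    Parameters
    ----------
    diameters : array, optional
        Per-particle diameters (m) for polydisperse runs; defaults to the
        monodisperse ``params.d_p``.

    Returns
    -------
    DepositionTally
        Counts by (zone, lobe, generation) plus the per-particle fate
        table in ``tally.particles``.
    """
    fluid = fluid or FluidProperties()
    tree = patient.tree
    fractions = lobar_fractions(patient.volumes)
    outlets = outlet_flow_profiles(tree, fractions, patient.pattern, mode=mode)
    flow = solve_branch_flows(tree, outlets, fluid)
    ta = tree.arrays()
    w = flow.weights
    pattern = patient.pattern
    T = pattern.period_s
    max_time = params.max_time_s if params.max_time_s is not None else pattern.total_time
    n = params.n_particles
    rng = np.random.default_rng(params.seed)

    d_p = (np.full(n, params.d_p) if diameters is None
           else np.asarray(diameters, dtype=float))
    if d_p.shape != (n,):
        raise ValueError("diameters must have length n_particles")
    vf = particle_volume_fraction(d_p, tree.total_volume())
    if vf > params.coupling_volume_fraction_limit:
        warnings.warn(
            f"particle volume fraction {vf:.2e} exceeds the one-way coupling "
            f"limit {params.coupling_volume_fraction_limit:.0e}; results assume "
            "dilute flow", stacklevel=2,
        )

    # flow-weighted injection times within the inspiratory half-cycles
    u = rng.random(n)
    t_inj = (T / (2.0 * math.pi)) * np.arccos(1.0 - 2.0 * u)
    if pattern.n_cycles > 1:
        t_inj = t_inj + T * rng.integers(0, pattern.n_cycles, n)
    if params.injection_profile == "centerline":
        eta = np.zeros(n)
    else:
        eta = np.sqrt(rng.random(n))
    phi = rng.random(n) * 2.0 * math.pi
    b = np.full(n, ta.root, dtype=np.int64)
    s = np.zeros(n)
    up = np.zeros((n, 3))
    uprime = np.zeros((n, 3))
    eddy_left = np.zeros(n)
    status = np.zeros(n, dtype=np.int8)
    dep_branch = np.full(n, -1, dtype=np.int64)
    dep_time = np.full(n, np.nan)

    dt = params.dt_s
    beta0 = 18.0 * fluid.mu / (params.rho_p * d_p**2)
    n_steps = int(math.ceil(max_time / dt))
    two_pi_over_T = 2.0 * math.pi / T
    q_peak = math.pi * pattern.vt_L / T  # L/s

    for i_step in range(n_steps):
        t = i_step * dt
        idx = np.flatnonzero((status == 0) & (t_inj <= t))
        if idx.size == 0:
            if np.all(status != 0):
                break
            continue
        qt = q_peak * math.sin(two_pi_over_T * t)  # mouth flow, L/s
        bi = b[idx]
        R = ta.radius[bi]
        q = w[bi] * qt * 1e-3  # m^3/s
        um = q / (math.pi * R**2)
        re = fluid.rho * np.abs(um) * 2.0 * R / fluid.mu
        turb = re >= RE_CRIT
        re_safe = np.maximum(re, 1e-300)
        intensity = np.where(turb, 0.16 * re_safe ** (-0.125), I_LAMINAR)
        k = 1.5 * (intensity * np.abs(um)) ** 2
        if not params.turbulence:
            k = np.zeros_like(k)
        sigma = np.sqrt(2.0 * k / 3.0)
        renew = eddy_left[idx] <= 0.0
        if np.any(renew):
            ridx = idx[renew]
            uprime[ridx] = rng.standard_normal((ridx.size, 3)) * sigma[renew][:, None]
            eddy_left[ridx] = (EDDY_LENGTH_COEFF * 2.0 * R[renew]
                               / np.maximum(sigma[renew], params.eps_floor))
        eddy_left[idx] -= dt

        eta_i = eta[idx]
        u_ax_f = np.where(turb, um, 2.0 * um * (1.0 - eta_i**2))
        uf = np.stack([u_ax_f + uprime[idx, 0], uprime[idx, 1], uprime[idx, 2]],
                      axis=1)
        slip = up[idx] - uf
        slip_mag = np.sqrt(np.einsum("ij,ij->i", slip, slip))
        re_p = fluid.rho * d_p[idx] * slip_mag / fluid.mu
        beta = beta0[idx] * np.asarray(cd_re_over_24(re_p, model))
        decay = np.exp(-beta * dt)
        u_new = uf + slip * decay[:, None]
        s[idx] += dt * 0.5 * (up[idx, 0] + u_new[:, 0])
        r_m = eta_i * R + dt * 0.5 * (up[idx, 1] + u_new[:, 1])
        phi[idx] += dt * u_new[:, 2] / np.maximum(np.abs(r_m), 0.05 * R)
        neg = r_m < 0.0
        if np.any(neg):
            r_m[neg] = -r_m[neg]
            u_new[neg, 1] = -u_new[neg, 1]
            uprime[idx[neg], 1] = -uprime[idx[neg], 1]
            phi[idx[neg]] += math.pi
        eta[idx] = r_m / R
        up[idx] = u_new

        # boundary events; a step can cross at most a few short branches
        for _ in range(8):
            bi = b[idx]
            trap = eta[idx] >= 1.0
            if np.any(trap):
                tidx = idx[trap]
                status[tidx] = 1
                dep_branch[tidx] = b[tidx]
                dep_time[tidx] = t
                eta[tidx] = 1.0
                idx = idx[~trap]
                bi = b[idx]
            if idx.size == 0:
                break
            moved = False
            over = s[idx] > ta.length[bi]
            if np.any(over):
                oidx = idx[over]
                obi = bi[over]
                term = ta.is_terminal[obi]
                if qt > 0.0:
                    eidx = oidx[term]
                    if eidx.size:
                        status[eidx] = 2
                        dep_branch[eidx] = b[eidx]
                        dep_time[eidx] = t
                        moved = True
                else:
                    cidx = oidx[term]
                    if cidx.size:
                        s[cidx] = ta.length[b[cidx]]
                jidx = oidx[~term]
                if jidx.size:
                    jbi = obi[~term]
                    c1 = ta.child1[jbi]
                    c2 = ta.child2[jbi]
                    q1 = np.abs(w[c1])
                    q2 = np.where(c2 >= 0, np.abs(w[np.maximum(c2, 0)]), 0.0)
                    tot = q1 + q2
                    p1 = np.where(tot > 0, q1 / np.maximum(tot, 1e-300), 0.5)
                    pick1 = (rng.random(jidx.size) < p1) | (c2 < 0)
                    b[jidx] = np.where(pick1, c1, np.maximum(c2, 0))
                    s[jidx] = 0.0
                    moved = True
            under = (s[idx] < 0.0) & (status[idx] == 0)
            if np.any(under):
                uidx = idx[under]
                ubi = b[uidx]
                at_root = ta.parent[ubi] < 0
                ridx = uidx[at_root]
                if ridx.size:
                    if qt < 0.0:
                        status[ridx] = 3
                        dep_time[ridx] = t
                        moved = True
                    s[ridx] = 0.0
                pidx = uidx[~at_root]
                if pidx.size:
                    par = ta.parent[b[pidx]]
                    b[pidx] = par
                    s[pidx] = ta.length[par]
                    moved = True
            idx = idx[status[idx] == 0]
            if not moved:
                break
        if idx.size:  # clamp any residual overshoot after the transfer budget
            np.clip(s[idx], 0.0, ta.length[b[idx]], out=s[idx])

    return _build_tally(ta, n, status, b, dep_branch, dep_time, s, eta, phi,
                        d_p, t_inj)


def _build_tally(ta, n, status, b, dep_branch, dep_time, s, eta, phi, d_p,
                 t_inj) -> DepositionTally:
    counts: dict[tuple[str, str | None, int], int] = {}
    trapped = status == 1
    escaped = status == 2
    if np.any(trapped):
        keys = np.stack([ta.zone[dep_branch[trapped]],
                         ta.lobe[dep_branch[trapped]],
                         ta.generation[dep_branch[trapped]]], axis=1)
        uniq, cnt = np.unique(keys, axis=0, return_counts=True)
        for (z, l, g), c in zip(uniq, cnt):
            lobe = LOBES[l].value if l >= 0 else None
            counts[(_ZONE_NAMES[int(z)], lobe, int(g))] = int(c)
    if np.any(escaped):
        keys = np.stack([ta.lobe[dep_branch[escaped]],
                         ta.generation[dep_branch[escaped]]], axis=1)
        uniq, cnt = np.unique(keys, axis=0, return_counts=True)
        for (l, g), c in zip(uniq, cnt):
            lobe = LOBES[l].value if l >= 0 else None
            counts[(Zone.PERIPHERAL.value, lobe, int(g))] = int(c)
    ids = np.array(ta.ids)
    cloud = pd.DataFrame({
        "particle_id": np.arange(n),
        "branch_id": ids[b],
        "s": s,
        "eta": eta,
        "phi": phi,
        "status": pd.Categorical([_STATUS_NAMES[int(v)] for v in status]),
        "time": dep_time,
        "d_p": d_p,
        "injection_time": t_inj,
    })
    return DepositionTally(
        counts=counts,
        exhaled=int(np.sum(status == 3)),
        suspended=int(np.sum(status == 0)),
        n_injected=n,
        particles=cloud,
    )
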