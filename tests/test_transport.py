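"""Particle kinematics, DRW dispersion, boundary events, full simulations."""

import math

import numpy as np
import pytest

import aerodep as ad
from aerodep.drag import stokes_rate
from aerodep.flow import FluidProperties
from aerodep.transport import particle_volume_fraction
from aerodep.tree import LOBES
from aerodep.ventilation import LobarFractions

from conftest import SMALL_PARAMS


def test_particle_mass_consistent_with_size_and_density():
    p = ad.Particle(branch_id="T", d_p=1.32e-6, rho_p=1015.0)
    expected = 1015.0 * math.pi * 1.32e-6**3 / 6.0
    assert p.m_p == pytest.approx(expected, rel=1e-12)


# --- discrete random walk --------------------------------------------------

def test_zero_k_gives_zero_fluctuation(small_tree, rng):
    eddy = ad.sample_fluctuation(0.0, rng, None, small_tree["T"])
    assert np.all(eddy.u_prime == 0.0)


def test_negative_k_rejected(small_tree, rng):
    with pytest.raises(ValueError):
        ad.sample_fluctuation(-1.0, rng, None, small_tree["T"])


def test_fluctuation_moments_match_isotropic_model(small_tree):
    k = 2.5e-3
    rng = np.random.default_rng(77)
    n = 100_000
    draws = np.empty((n, 3))
    for i in range(n):
        draws[i] = ad.sample_fluctuation(k, rng, None, small_tree["T"]).u_prime
    sigma2 = 2.0 * k / 3.0
    se_mean = math.sqrt(sigma2 / n)
    assert np.all(np.abs(draws.mean(axis=0)) < 3.0 * se_mean)
    assert np.allclose(draws.var(axis=0), sigma2, rtol=0.03)


def test_fluctuation_sequence_deterministic_under_seed(small_tree):
    seqs = []
    for _ in range(2):
        rng = np.random.default_rng(5)
        seqs.append([ad.sample_fluctuation(1e-3, rng, None, small_tree["T"]).u_prime
                     for _ in range(10)])
    assert np.allclose(seqs[0], seqs[1], atol=0)


def test_live_eddy_is_kept_and_lifetime_decremented(small_tree, rng):
    eddy = ad.EddyState(u_prime=np.array([1.0, 2.0, 3.0]), remaining_lifetime=0.5)
    out = ad.sample_fluctuation(1e-3, rng, eddy, small_tree["T"], dt=0.1)
    assert np.all(out.u_prime == eddy.u_prime)
    assert out.remaining_lifetime == pytest.approx(0.4)


# --- velocity integrator ---------------------------------------------------

def _quiet_flow(u_centerline):
    """Flow whose mouth-branch laminar centerline velocity is u_centerline
    at t = 1 s (quarter period)."""
    tree = ad.generate_airway_tree(SMALL_PARAMS)
    r = tree["mouth"].radius
    q_peak = (u_centerline / 2.0) * math.pi * r**2 * 1e3  # L/s
    vt = q_peak * 4.0 / math.pi
    pattern = ad.tidal_waveform(vt, 4.0)
    fr = LobarFractions(f={l: 0.2 for l in LOBES})
    prof = ad.outlet_flow_profiles(tree, fr, pattern)
    return tree, ad.solve_branch_flows(tree, prof)


def test_zero_dt_leaves_particle_unchanged():
    tree, flow = _quiet_flow(0.5)
    p = ad.Particle(branch_id="mouth", s=0.01, eta=0.3,
                    u_p=np.array([0.2, 0.01, 0.0]))
    q = ad.advance_particle(p, flow, FluidProperties(), dt=0.0, t=1.0)
    assert q.s == p.s and q.eta == p.eta
    assert np.all(q.u_p == p.u_p)


def test_drag_equilibrium_reached_after_ten_relaxation_times():
    tree, flow = _quiet_flow(1.0)
    fluid = FluidProperties()
    d_p = 4e-5
    beta = stokes_rate(d_p, 1015.0, fluid)
    dt = (10.0 / beta) / 10.0
    p = ad.Particle(branch_id="mouth", eta=0.0, d_p=d_p, u_p=np.zeros(3))
    for _ in range(10):  # frozen field: t held fixed
        p = ad.advance_particle(p, flow, fluid, dt=dt, t=1.0)
    u_f = ad.local_axial_velocity(tree["mouth"], flow["mouth"], 0.0, 1.0)
    assert abs(p.u_p[0] - u_f) / abs(u_f) < 5e-5


def test_exponential_update_matches_fine_step_euler_oracle():
    # Stokes regime (constant beta): one exponential step vs 1000 explicit
    # Euler sub-steps under frozen fluid velocity
    tree, flow = _quiet_flow(0.004)
    fluid = FluidProperties()
    d_p = 2.8e-4  # beta ~ 4 1/s so beta*dt ~ 0.02
    dt = 5e-3
    u_f = float(ad.local_axial_velocity(tree["mouth"], flow["mouth"], 0.0, 1.0))
    beta = stokes_rate(d_p, 1015.0, fluid)
    u0 = 0.5 * u_f
    u_euler = u0
    sub = dt / 1000.0
    for _ in range(1000):
        u_euler += beta * (u_f - u_euler) * sub
    p = ad.Particle(branch_id="mouth", eta=0.0, d_p=d_p,
                    u_p=np.array([u0, 0.0, 0.0]))
    p = ad.advance_particle(p, flow, fluid, dt=dt, t=1.0)
    assert p.u_p[0] == pytest.approx(u_euler, rel=1e-6)


# --- boundary events -------------------------------------------------------

def test_wall_contact_traps_particle(small_tree, small_flow, rng):
    p = ad.Particle(branch_id="T", s=0.01, eta=1.01)
    event = ad.check_boundary(p, small_tree, small_flow, rng, t=1.0)
    assert event == "trap"
    assert p.status == "trapped"


def test_terminal_overshoot_escapes_during_inflow(small_tree, small_flow, rng):
    term = small_tree.terminals()[0]
    p = ad.Particle(branch_id=term.id, s=term.length * 1.1, eta=0.2)
    event = ad.check_boundary(p, small_tree, small_flow, rng, t=1.0)
    assert event == "escape"
    assert p.status == "escaped"


def test_terminal_overshoot_clamped_during_expiration(small_tree, small_flow, rng):
    term = small_tree.terminals()[0]
    p = ad.Particle(branch_id=term.id, s=term.length * 1.1, eta=0.2)
    event = ad.check_boundary(p, small_tree, small_flow, rng, t=3.0)
    assert event == "none"
    assert p.status == "suspended" and p.s == term.length


def test_mouth_undershoot_exhales_only_during_expiration(small_tree, small_flow, rng):
    p = ad.Particle(branch_id="mouth", s=-0.01)
    assert ad.check_boundary(p, small_tree, small_flow, rng, t=1.0) == "none"
    assert p.s == 0.0 and p.status == "suspended"
    p.s = -0.01
    assert ad.check_boundary(p, small_tree, small_flow, rng, t=3.0) == "exhaled"
    assert p.status == "exhaled"


def test_backward_motion_transfers_to_parent(small_tree, small_flow, rng):
    p = ad.Particle(branch_id="T", s=-0.001, eta=0.4)
    event = ad.check_boundary(p, small_tree, small_flow, rng, t=3.0)
    assert event == "junction_transfer"
    assert p.branch_id == "mouth"
    assert p.s == small_tree["mouth"].length


def test_junction_routing_follows_daughter_flow_split():
    # LUL:LLL ventilation 3:1 -> routing frequencies 0.75/0.25
    tree = ad.generate_airway_tree(SMALL_PARAMS)
    fr = LobarFractions(f=dict(zip(LOBES, [0.125, 0.125, 0.25, 0.375, 0.125])))
    prof = ad.outlet_flow_profiles(tree, fr, ad.tidal_waveform(0.5, 4.0))
    flow = ad.solve_branch_flows(tree, prof)
    rng = np.random.default_rng(13)
    n = 100_000
    length = tree["L"].length
    hits = 0
    for _ in range(n):
        p = ad.Particle(branch_id="L", s=length * 1.01, eta=0.3)
        ev = ad.check_boundary(p, tree, flow, rng, t=1.0)
        assert ev == "junction_transfer"
        hits += p.branch_id == "L0"
    p_exact = 0.75
    se = math.sqrt(p_exact * (1 - p_exact) / n)
    assert abs(hits / n - p_exact) < 3.0 * se


# --- full simulation -------------------------------------------------------

def test_status_counts_sum_to_injected(small_patient):
    tally = ad.run_simulation(small_patient,
                              ad.SimParams(n_particles=2000, seed=9))
    total = sum(tally.counts.values()) + tally.exhaled + tally.suspended
    assert total == 2000
    assert len(tally.particles) == 2000


def test_simulation_deterministic_under_seed(small_patient):
    params = ad.SimParams(n_particles=1500, seed=4)
    t1 = ad.run_simulation(small_patient, params)
    t2 = ad.run_simulation(small_patient, params)
    assert t1.counts == t2.counts
    assert t1.exhaled == t2.exhaled and t1.suspended == t2.suspended
    assert t1.particles.equals(t2.particles)


def test_centerline_laminar_particles_never_deposit(small_patient):
    params = ad.SimParams(n_particles=500, seed=2, turbulence=False,
                          injection_profile="centerline")
    tally = ad.run_simulation(small_patient, params)
    statuses = set(tally.particles["status"].unique())
    assert "trapped" not in statuses
    wall_zones = {z for (z, _, _) in tally.counts} - {"peripheral"}
    assert not wall_zones


def test_coupling_limit_warning():
    patient = ad.make_patient(tree_params=SMALL_PARAMS)
    params = ad.SimParams(n_particles=2000, seed=1, d_p=1e-4)
    with pytest.warns(UserWarning, match="volume fraction"):
        ad.run_simulation(patient, params)


def test_volume_fraction_arithmetic():
    d = np.full(10, 1e-3)
    vol = 10 * math.pi * 1e-9 / 6.0
    assert particle_volume_fraction(d, 2.0 * vol) == pytest.approx(0.5)


def test_doubling_particle_count_stays_within_binomial_error(small_patient):
    reps = {}
    for n in (4000, 8000):
        tally = ad.run_simulation(small_patient,
                                  ad.SimParams(n_particles=n, seed=21))
        reps[n] = ad.report(tally)
    for zone in ("extrathoracic", "central", "distal", "peripheral"):
        a = getattr(reps[4000], zone)
        b = getattr(reps[8000], zone)
        p = b / 100.0
        # both runs are independent samples: compare against the standard
        # error of their difference
        se_diff = 100.0 * math.sqrt(max(p * (1 - p), 1e-12) * (1 / 4000 + 1 / 8000))
        assert abs(a - b) < 3.0 * se_diff


def test_invalid_sim_params_rejected():
    with pytest.raises(ValueError):
        ad.SimParams(dt_s=0.0)
    with pytest.raises(ValueError):
        ad.SimParams(n_particles=0)
    with pytest.raises(ValueError):
        ad.SimParams(injection_profile="spiral")
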