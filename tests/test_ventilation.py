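"""Lobar fractions, tidal waveform, and outlet flow partitioning."""

import numpy as np
import pytest
from scipy.integrate import quad

import aerodep as ad
from aerodep.tree import LOBES, Lobe
from aerodep.ventilation import LobarFractions

from conftest import SMALL_PARAMS


def test_equal_deltas_give_uniform_fractions():
    v = ad.generate_lung_volumes({l: 0.2 for l in LOBES})
    fr = ad.lobar_fractions(v)
    assert np.allclose(fr.as_array(), 0.2, atol=1e-12)


def test_representative_deltas_recover_published_split():
    target = np.array([12.09, 5.39, 35.17, 14.86, 32.47])
    target = target / target.sum()
    v = ad.LungVolumes(
        v_frc={l: 0.5 for l in LOBES},
        v_tlc={l: 0.5 + t for l, t in zip(LOBES, target)},
    )
    assert np.allclose(ad.lobar_fractions(v).as_array(), target, atol=1e-12)


def test_fractions_sum_to_one_for_random_volumes():
    rng = np.random.default_rng(11)
    for _ in range(100):
        frc = rng.uniform(0.2, 1.5, 5)
        delta = rng.uniform(0.05, 2.0, 5)
        v = ad.LungVolumes(
            v_frc=dict(zip(LOBES, frc)),
            v_tlc=dict(zip(LOBES, frc + delta)),
        )
        assert ad.lobar_fractions(v).as_array().sum() == pytest.approx(1.0, abs=1e-12)


def test_fractions_invariant_under_uniform_delta_scaling():
    rng = np.random.default_rng(5)
    delta = rng.uniform(0.1, 1.0, 5)
    mk = lambda scale: ad.LungVolumes(
        v_frc={l: 1.0 for l in LOBES},
        v_tlc={l: 1.0 + scale * d for l, d in zip(LOBES, delta)},
    )
    f1 = ad.lobar_fractions(mk(1.0)).as_array()
    f3 = ad.lobar_fractions(mk(3.0)).as_array()
    assert np.allclose(f1, f3, atol=1e-12)


def test_nonpositive_delta_error_names_lobe():
    class FakeVolumes:
        v_frc = {l: 1.0 for l in LOBES}
        v_tlc = {l: (1.0 if l is Lobe.LUL else 2.0) for l in LOBES}

    with pytest.raises(ValueError, match="LUL"):
        ad.lobar_fractions(FakeVolumes())


# --- waveform --------------------------------------------------------------

def test_sinusoid_endpoints_and_peak():
    vt, T = 0.5, 4.0
    p = ad.tidal_waveform(vt, T)
    assert p.flow(0.0) == pytest.approx(0.0, abs=1e-15)
    assert p.flow(T / 4) == pytest.approx(np.pi * vt / T)


def test_inspiratory_integral_equals_tidal_volume():
    vt, T = 0.73, 3.1
    p = ad.tidal_waveform(vt, T)
    integral, _ = quad(p.flow, 0.0, T / 2)
    assert integral == pytest.approx(vt, rel=1e-8)


def test_waveform_periodicity():
    p = ad.tidal_waveform(0.5, 4.0)
    rng = np.random.default_rng(2)
    t = rng.uniform(0, 20, 50)
    assert np.allclose(p.flow(t + 4.0), p.flow(t), atol=1e-12)


def test_invalid_waveform_parameters():
    with pytest.raises(ValueError):
        ad.tidal_waveform(-0.5, 4.0)
    with pytest.raises(ValueError):
        ad.tidal_waveform(0.5, 0.0)


# --- outlet partitioning ---------------------------------------------------

def test_outlet_flows_conserve_mouth_flow_both_modes(small_patient):
    fr = ad.lobar_fractions(small_patient.volumes)
    t = np.linspace(0.0, 4.0, 1000)
    q_mouth = np.asarray(small_patient.pattern.flow(t))
    for mode in ("patient_specific", "area_uniform"):
        prof = ad.outlet_flow_profiles(small_patient.tree, fr,
                                       small_patient.pattern, mode=mode)
        total = sum(np.asarray(prof.flow(bid, t)) for bid in prof.weights)
        assert np.allclose(total, q_mouth, rtol=1e-9, atol=1e-15)


def test_within_lobe_split_proportional_to_area():
    # enlarge one terminal's area 2x: its lobe's flow must split 2:1 with
    # equal face velocity across the lobe's outlets
    tree = ad.generate_airway_tree(SMALL_PARAMS)
    lul_terms = [b for b in tree.terminals() if b.lobe is ad.Lobe.LUL]
    big, small = lul_terms[0], lul_terms[1]
    big.radius *= np.sqrt(2.0)  # double the area
    fr = ad.lobar_fractions(ad.generate_lung_volumes({l: 0.2 for l in LOBES}))
    prof = ad.outlet_flow_profiles(tree, fr, ad.tidal_waveform(0.5, 4.0))
    assert prof.weights[big.id] / prof.weights[small.id] == pytest.approx(2.0)
    v_big = prof.weights[big.id] / big.outlet_area
    v_small = prof.weights[small.id] / small.outlet_area
    assert v_big == pytest.approx(v_small)


def test_modes_coincide_when_area_shares_equal_fractions(small_tree):
    areas = {l: 0.0 for l in LOBES}
    total = 0.0
    for b in small_tree.terminals():
        areas[b.lobe] += b.outlet_area
        total += b.outlet_area
    fr = LobarFractions(f={l: areas[l] / total for l in LOBES})
    pat = ad.tidal_waveform(0.5, 4.0)
    w_ps = ad.outlet_flow_profiles(small_tree, fr, pat, "patient_specific").weights
    w_au = ad.outlet_flow_profiles(small_tree, fr, pat, "area_uniform").weights
    for bid in w_ps:
        assert w_ps[bid] == pytest.approx(w_au[bid], rel=1e-12)


def test_unknown_mode_rejected(small_patient):
    fr = ad.lobar_fractions(small_patient.volumes)
    with pytest.raises(ValueError, match="mode"):
        ad.outlet_flow_profiles(small_patient.tree, fr,
                                small_patient.pattern, mode="magic")
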