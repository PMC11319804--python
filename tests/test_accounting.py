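"""Regional dosimetry: reports, generational tables, convergence harness."""

import numpy as np
import pytest

import aerodep as ad
from aerodep.accounting import tally_from_cloud


def test_report_arithmetic_and_intrathoracic_rule():
    counts = {
        ("distal", "RLL", 4): 232,
        ("peripheral", "RLL", 5): 458,
        ("central", None, 0): 10,
        ("extrathoracic", None, -1): 200,
    }
    tally = ad.DepositionTally(counts=counts, exhaled=100, suspended=0,
                               n_injected=1000)
    rep = ad.report(tally)
    assert rep.distal == pytest.approx(23.2)
    assert rep.peripheral == pytest.approx(45.8)
    assert rep.intrathoracic == pytest.approx(69.0)
    assert rep.central == pytest.approx(1.0)
    assert rep.extrathoracic == pytest.approx(20.0)
    assert rep.exhaled == pytest.approx(10.0)


def test_all_extrathoracic_degenerate_tally():
    tally = ad.DepositionTally(counts={("extrathoracic", None, -1): 50},
                               exhaled=0, suspended=0, n_injected=50)
    rep = ad.report(tally)
    assert rep.extrathoracic == 100.0
    assert rep.intrathoracic == 0.0
    assert rep.distal == rep.peripheral == rep.central == 0.0


def test_lobar_totals_combine_distal_and_peripheral_parts():
    counts = {
        ("distal", "LUL", 3): 30, ("peripheral", "LUL", 5): 20,
        ("distal", "RUL", 3): 10, ("peripheral", "RLL", 5): 40,
    }
    tally = ad.DepositionTally(counts=counts, exhaled=0, suspended=0,
                               n_injected=100)
    rep = ad.report(tally)
    assert rep.lobar_total["LUL"] == pytest.approx(50.0)
    assert rep.lobar_total["LUL"] == pytest.approx(
        rep.lobar_distal["LUL"] + rep.lobar_peripheral["LUL"])
    assert rep.lobar_total["RUL"] == pytest.approx(10.0)
    assert rep.lobar_total["RLL"] == pytest.approx(40.0)


def test_random_tallies_close_to_100_percent():
    rng = np.random.default_rng(3)
    zones = ["extrathoracic", "central", "distal", "peripheral"]
    for _ in range(50):
        counts = {}
        for z in zones:
            lobe = None if z in ("extrathoracic", "central") else "RLL"
            counts[(z, lobe, int(rng.integers(0, 8)))] = int(rng.integers(0, 500))
        exhaled = int(rng.integers(0, 200))
        suspended = int(rng.integers(0, 50))
        n = sum(counts.values()) + exhaled + suspended
        if n == 0:
            continue
        rep = ad.report(ad.DepositionTally(counts=counts, exhaled=exhaled,
                                           suspended=suspended, n_injected=n))
        total = (rep.extrathoracic + rep.central + rep.distal + rep.peripheral
                 + rep.exhaled + rep.suspended)
        assert total == pytest.approx(100.0, abs=1e-9)
        assert rep.intrathoracic == pytest.approx(rep.distal + rep.peripheral,
                                                  abs=1e-9)


def test_tally_must_conserve_particles():
    with pytest.raises(ValueError, match="conserve"):
        ad.DepositionTally(counts={("distal", "RUL", 3): 10}, exhaled=0,
                           suspended=0, n_injected=5)


def test_report_rejects_empty_injection():
    with pytest.raises(ValueError):
        ad.report(ad.DepositionTally(counts={}, exhaled=0, suspended=0,
                                     n_injected=0))


# --- generational table ----------------------------------------------------

def test_generational_table_empty_tally_is_zero():
    tally = ad.DepositionTally(counts={}, exhaled=10, suspended=0, n_injected=10)
    table = ad.generational_table(tally)
    assert np.allclose(table["pct_dd"], 0.0)


def test_single_particle_at_generation_5():
    tally = ad.DepositionTally(counts={("distal", "RLL", 5): 1}, exhaled=99,
                               suspended=0, n_injected=100)
    table = ad.generational_table(tally).set_index("generation")
    assert table.loc["5", "pct_dd"] == pytest.approx(1.0)


def test_generational_total_equals_central_distal_peripheral(small_patient):
    tally = ad.run_simulation(small_patient, ad.SimParams(n_particles=3000, seed=6))
    rep = ad.report(tally)
    table = ad.generational_table(tally)
    assert table["pct_dd"].sum() == pytest.approx(
        rep.central + rep.distal + rep.peripheral, abs=1e-9)


def test_report_round_trips_through_particle_cloud(small_patient):
    tally = ad.run_simulation(small_patient, ad.SimParams(n_particles=2000, seed=8))
    rebuilt = tally_from_cloud(small_patient.tree, tally.particles)
    r1, r2 = ad.report(tally), ad.report(rebuilt)
    assert r1.to_frame().equals(r2.to_frame())
    assert r1.generations == r2.generations


# --- convergence harness ---------------------------------------------------

def test_convergence_single_count_single_row(small_patient):
    params = ad.SimParams(n_particles=10, seed=3)
    table = ad.convergence_study(small_patient, [500], params)
    assert len(table) == 1
    assert np.isnan(table["max_spread_above"].iloc[0])


def test_convergence_table_deterministic(small_patient):
    params = ad.SimParams(n_particles=10, seed=3)
    t1 = ad.convergence_study(small_patient, [300, 600], params)
    t2 = ad.convergence_study(small_patient, [300, 600], params)
    assert t1.equals(t2)


def test_convergence_requires_sorted_nonempty_counts(small_patient):
    params = ad.SimParams(n_particles=10, seed=3)
    with pytest.raises(ValueError):
        ad.convergence_study(small_patient, [], params)
    with pytest.raises(ValueError):
        ad.convergence_study(small_patient, [600, 300], params)
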