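import math

import numpy as np
import pandas as pd
import pytest

from tfspec import (
    SyntheticTruth,
    analyze_binding_table,
    boltzmann_frequencies,
    information_content,
    random_energy_matrix,
    recovery_report,
    relative_binding_energies,
    rt,
    selection_logo,
    simulate_mitomi,
    simulate_selection,
    true_ddg,
)

RT = rt(295.0)


class TestRandomEnergyMatrix:
    def test_zero_spread_gives_flat_penalties(self):
        em = random_energy_matrix(spread=0.0, mean_penalty=2.5, seed=1)
        vals = em.ddg.to_numpy()
        nonzero = vals[vals > 0]
        assert np.allclose(nonzero, 2.5)
        assert np.allclose(vals.min(axis=1), 0.0)

    def test_same_seed_reproduces_matrix(self):
        a = random_energy_matrix(seed=9)
        b = random_energy_matrix(seed=9)
        pd.testing.assert_frame_equal(a.ddg, b.ddg)

    def test_penalty_distribution_mean(self):
        draws = []
        for seed in range(300):
            em = random_energy_matrix(
                n_positions=4, mean_penalty=4.0, spread=1.5, seed=seed
            )
            vals = em.ddg.to_numpy()
            draws.extend(vals[vals > 0].tolist())
        assert np.mean(draws) == pytest.approx(4.0, abs=0.1)

    def test_default_positions_follow_core_frame(self):
        assert random_energy_matrix(n_positions=3).positions == [-2, -1, 0]


class TestSimulateMitomi:
    def test_noise_free_no_floor_roundtrip_recovers_truth(self):
        em = random_energy_matrix(seed=12)
        truth = SyntheticTruth(truth_matrix=em, dg_ns_true=1e3, noise_sigma=0.0)
        bt = simulate_mitomi(truth)
        assert bt.strongest_site == em.consensus
        from tfspec import energy_matrix_from_single_mutants

        ddg = relative_binding_energies(bt)
        est = energy_matrix_from_single_mutants(ddg, em.consensus, positions=em.positions)
        assert np.allclose(est.ddg.to_numpy(), em.ddg.to_numpy(), atol=1e-9)

    def test_floor_saturates_weak_sites(self):
        em = random_energy_matrix(seed=12)
        floor = 3.3
        truth = SyntheticTruth(truth_matrix=em, dg_ns_true=floor, noise_sigma=0.0)
        ddg = relative_binding_energies(simulate_mitomi(truth))
        plateau = floor + RT * math.log(1 + math.exp(-floor / RT))
        weak = [s for s in ddg.index if true_ddg(truth, s) > floor + 5 * RT]
        assert weak, "need genuinely weak sites for the saturation check"
        assert np.allclose(ddg[weak].to_numpy(), plateau, atol=RT * math.log(2))

    def test_identical_seeds_identical_tables(self):
        em = random_energy_matrix(seed=3)
        t1 = SyntheticTruth(truth_matrix=em, noise_sigma=0.1, seed=77)
        t2 = SyntheticTruth(truth_matrix=em, noise_sigma=0.1, seed=77)
        pd.testing.assert_frame_equal(simulate_mitomi(t1).data, simulate_mitomi(t2).data)

    def test_coupling_term_enters_ka(self):
        em = random_energy_matrix(seed=3)
        pos = em.positions
        cons = em.consensus
        coupling = {((pos[0], cons[0]), (pos[1], cons[1])): 1.5}
        plain = SyntheticTruth(truth_matrix=em, dg_ns_true=1e3, noise_sigma=0.0)
        coupled = SyntheticTruth(
            truth_matrix=em, dg_ns_true=1e3, noise_sigma=0.0, coupling=coupling
        )
        assert true_ddg(coupled, cons) == pytest.approx(true_ddg(plain, cons) + 1.5)


class TestSimulateSelection:
    def test_harsh_stringency_gives_single_clone_logo(self):
        em = random_energy_matrix(seed=0)
        truth = SyntheticTruth(truth_matrix=em, dg_ns_true=3.3, noise_sigma=0.0)
        best_penalty = min(v for v in em.ddg.to_numpy().ravel() if v > 0)
        outcome = simulate_selection(truth, stringency_ddg=best_penalty * 0.5)
        assert list(outcome.population.index) == [em.consensus]
        logo = selection_logo(outcome.chromatogram, blank_fixed=True)
        assert logo.information_bits == pytest.approx(2.0 * len(em.positions))

    def test_infinite_stringency_matches_boltzmann_closed_form(self):
        em = random_energy_matrix(seed=0)
        truth = SyntheticTruth(truth_matrix=em, dg_ns_true=3.3, noise_sigma=0.0)
        outcome = simulate_selection(truth, stringency_ddg=1e6)
        logo = selection_logo(outcome.chromatogram, blank_fixed=True)
        closed_form = information_content(boltzmann_frequencies(em)).total
        assert logo.information_bits == pytest.approx(closed_form, abs=1e-9)

    def test_tightening_stringency_never_loses_information(self):
        em = random_energy_matrix(seed=0)
        truth = SyntheticTruth(truth_matrix=em, dg_ns_true=3.3, noise_sigma=0.0)
        infos = []
        for stringency in (2.5, 4.0, 6.0, 9.0, 15.0, 1e6):
            logo = selection_logo(
                simulate_selection(truth, stringency).chromatogram, blank_fixed=True
            )
            infos.append(logo.information_bits)
        assert all(a >= b - 1e-9 for a, b in zip(infos, infos[1:]))

    def test_empty_survivor_set_advises(self):
        em = random_energy_matrix(seed=0)
        truth = SyntheticTruth(truth_matrix=em, dg_ns_true=3.3, noise_sigma=0.0)
        with pytest.raises(ValueError, match="loosen"):
            simulate_selection(truth, stringency_ddg=-1.0)

    def test_library_sampling_is_seeded(self):
        em = random_energy_matrix(seed=0)
        truth = SyntheticTruth(truth_matrix=em, dg_ns_true=3.3, noise_sigma=0.0)
        a = simulate_selection(truth, 8.0, library_size=200, seed=5)
        b = simulate_selection(truth, 8.0, library_size=200, seed=5)
        pd.testing.assert_series_equal(a.population, b.population)


class TestRecoveryReport:
    def test_perfect_estimates_all_pass(self):
        em = random_energy_matrix(seed=2)
        truth = SyntheticTruth(truth_matrix=em, dg_ns_true=3.3, noise_sigma=0.0)
        report = recovery_report(
            truth,
            estimated_matrix=em,
            estimated_dg_ns=3.3,
            estimated_information_bits=1.5,
            true_information_bits=1.5,
        )
        assert report["passed"].all()
        assert np.allclose(report["bias"].to_numpy(), 0.0)

    def test_known_offset_appears_as_bias(self):
        em = random_energy_matrix(seed=2)
        truth = SyntheticTruth(truth_matrix=em, dg_ns_true=3.3, noise_sigma=0.0)
        report = recovery_report(truth, estimated_dg_ns=3.3 + 0.7)
        assert report.at["dg_ns", "bias"] == pytest.approx(0.7)

    def test_shape_mismatch_rejected(self):
        truth = SyntheticTruth(truth_matrix=random_energy_matrix(seed=2))
        other = random_energy_matrix(n_positions=4, seed=2)
        with pytest.raises(ValueError, match="mismatch"):
            recovery_report(truth, estimated_matrix=other)

    def test_full_pipeline_noise005_within_documented_tolerances(self):
        em = random_energy_matrix(seed=0)
        truth = SyntheticTruth(truth_matrix=em, dg_ns_true=3.3, noise_sigma=0.05, seed=0)
        va = analyze_binding_table(simulate_mitomi(truth))
        report = recovery_report(
            truth,
            estimated_dg_ns=va.boundary.dg_ns,
            tolerances={"dg_ns_kj_mol": rt() * math.log(2)},
        )
        assert report.at["dg_ns", "passed"]
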