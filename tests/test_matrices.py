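import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tfspec import (
    AA_ALPHABET,
    EnergyMatrix,
    FrequencyMatrix,
    boltzmann_frequencies,
    enumerate_sites,
    frequency_matrix_from_sites,
    information_content,
    logo_table,
    ri_weights,
    rt,
    score_site,
    score_sites,
    small_sample_correction,
)
from tfspec.datasets import load_binding_domain_variants

from conftest import make_random_frequency_matrix


def column(*vals, positions=(1,)):
    return FrequencyMatrix(
        pd.DataFrame([list(vals)], index=list(positions), columns=["A", "C", "G", "T"])
    )


class TestFrequencyMatrixFromSites:
    def test_unanimous_sites_give_certainty(self):
        fm = frequency_matrix_from_sites(["GCA", "GCA"], pseudocount=0)
        assert fm.n == 2
        for pos, base in zip((1, 2, 3), "GCA"):
            assert fm.probs.at[pos, base] == 1.0
        assert fm.probs.to_numpy().sum() == pytest.approx(3.0)

    def test_uniform_second_position(self):
        fm = frequency_matrix_from_sites(["AA", "AC", "AG", "AT"], pseudocount=0)
        assert list(fm.probs.loc[1]) == [1, 0, 0, 0]
        assert list(fm.probs.loc[2]) == [0.25] * 4

    def test_ragged_sites_rejected(self):
        with pytest.raises(ValueError, match="ragged|equal length"):
            frequency_matrix_from_sites(["GCA", "GC"])

    def test_alien_symbol_names_position_and_symbol(self):
        with pytest.raises(ValueError, match="'X'.*position 2|position 2.*'X'"):
            frequency_matrix_from_sites(["GXA"], pseudocount=0)

    def test_weighted_equals_expanded_multiset(self, rng):
        sites = ["GCA", "TCC", "GAA", "TAG"]
        weights = [3, 1, 2, 5]
        weighted = frequency_matrix_from_sites(sites, weights=weights, pseudocount=0.25)
        expanded = frequency_matrix_from_sites(
            [s for s, w in zip(sites, weights) for _ in range(w)], pseudocount=0.25
        )
        pd.testing.assert_frame_equal(weighted.probs, expanded.probs)
        assert weighted.n == expanded.n == 11

    def test_selected_binding_domain_tally(self):
        """Amino-acid logo input: the published variant lists, counts as weights.

        Recounted directly from the published table: among the 13 variants
        selected against 'GCA' (total colony count 27) only TCK (count 1)
        lacks Arg at residue 46, so the Arg probability there is 26/27; with
        the 18 colonies of the lower-stringency arm only, it is 17/18.
        """
        table = load_binding_domain_variants()
        block = table[table["selected_against"] == "GCA"]
        assert len(block) == 13
        assert int(block["total"].sum()) == 27
        assert int(block["tet20"].sum()) == 18

        fm = frequency_matrix_from_sites(
            list(block["residues_42_45_46"]),
            weights=list(block["total"]),
            pseudocount=0,
            alphabet=AA_ALPHABET,
            positions=(42, 45, 46),
        )
        assert fm.n == 27
        assert fm.probs.at[46, "R"] == pytest.approx(26 / 27)
        assert fm.probs.at[46, "K"] == pytest.approx(1 / 27)

        fm20 = frequency_matrix_from_sites(
            list(block["residues_42_45_46"]),
            weights=list(block["tet20"]),
            pseudocount=0,
            alphabet=AA_ALPHABET,
            positions=(42, 45, 46),
        )
        assert fm20.probs.at[46, "R"] == pytest.approx(17 / 18)


class TestInformationContent:
    @pytest.mark.parametrize(
        "probs, expected_bits",
        [((0.25, 0.25, 0.25, 0.25), 0.0), ((0.5, 0.5, 0, 0), 1.0), ((1, 0, 0, 0), 2.0)],
    )
    def test_reference_columns(self, probs, expected_bits):
        res = information_content(column(*probs), apply_correction=False)
        assert res.total == pytest.approx(expected_bits, abs=1e-12)

    def test_total_is_sum_of_positions_and_nonnegative(self, rng):
        for _ in range(20):
            fm = make_random_frequency_matrix(rng, length=4)
            res = information_content(fm, apply_correction=False)
            assert (res.per_position >= -1e-12).all()
            assert res.total == pytest.approx(res.per_position.sum(), abs=1e-9)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            information_content(column(1, 0, 0, 0), position_range=[])

    def test_correction_applied_by_default_for_counted_sites(self):
        fm = frequency_matrix_from_sites(["GCA"], pseudocount=0)
        res = information_content(fm)
        # one site: 2 bits raw, e(1) = 2 bits, corrected content 0 per position
        assert res.total == pytest.approx(0.0, abs=1e-12)
        assert res.sd_total is not None


class TestSmallSampleCorrection:
    def test_single_site_carries_no_information(self):
        corr = small_sample_correction(1, 4)
        assert corr.e_bits == pytest.approx(2.0)
        assert corr.sd_bits == pytest.approx(0.0)

    def test_vanishes_for_large_n(self):
        assert small_sample_correction(10**9, 4).e_bits < 1e-8

    def test_exact_enumeration_matches_monte_carlo_n8(self, rng):
        # independent oracle: sample multinomial entropies directly
        counts = rng.multinomial(8, [0.25] * 4, size=200_000)
        f = counts / 8
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(f * np.log2(np.where(f > 0, f, 1)), axis=1)
        mc = 2.0 - h.mean()
        assert small_sample_correction(8, 4).e_bits == pytest.approx(mc, abs=5e-3)

    def test_asymptotic_regime_close_to_monte_carlo_n16(self, rng):
        counts = rng.multinomial(16, [0.25] * 4, size=1_000_000)
        f = counts / 16
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(f * np.log2(np.where(f > 0, f, 1)), axis=1)
        mc = 2.0 - h.mean()
        # chi-square asymptotic (3/(2 ln2 * 16)) sits ~0.007 bits under the truth
        assert small_sample_correction(16, 4).e_bits == pytest.approx(mc, abs=0.02)

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            small_sample_correction(0, 4)


class TestBoltzmannFrequencies:
    def test_zero_energies_give_uniform(self):
        em = EnergyMatrix(pd.DataFrame([[0.0] * 4], index=[1], columns=list("ACGT")))
        fm = boltzmann_frequencies(em)
        assert list(fm.probs.loc[1]) == pytest.approx([0.25] * 4)
        assert fm.n is None

    def test_rt_ln2_penalty_halves_weight(self):
        pen = rt(295.0) * math.log(2)  # 1.700 kJ/mol
        em = EnergyMatrix(
            pd.DataFrame([[0.0, pen, pen, pen]], index=[1], columns=list("ACGT"))
        )
        fm = boltzmann_frequencies(em)
        assert list(fm.probs.loc[1]) == pytest.approx([0.4, 0.2, 0.2, 0.2], abs=1e-12)

    def test_sharpening_energies_never_loses_information(self, rng):
        for _ in range(10):
            ddg = np.abs(rng.normal(3, 2, size=(3, 4)))
            ddg -= ddg.min(axis=1, keepdims=True)
            infos = []
            for c in (0.5, 1.0, 2.0, 4.0):
                em = EnergyMatrix(
                    pd.DataFrame(c * ddg, index=[-2, -1, 0], columns=list("ACGT"))
                )
                infos.append(information_content(boltzmann_frequencies(em)).total)
            assert all(b >= a - 1e-9 for a, b in zip(infos, infos[1:]))


class TestRiScoring:
    def test_uniform_model_scores_zero_everywhere(self):
        fm = FrequencyMatrix(
            pd.DataFrame(0.25, index=[-2, -1, 0], columns=list("ACGT"))
        )
        rm = ri_weights(fm, apply_correction=False)
        assert np.allclose(rm.weights.to_numpy(), 0.0)
        assert score_site(rm, "ACG") == pytest.approx(0.0)

    def test_conserved_model_consensus_and_antidote(self):
        fm = frequency_matrix_from_sites(["GCA"] * 5, pseudocount=0, positions=(-2, -1, 0))
        rm = ri_weights(fm, pseudocount=0, apply_correction=False)
        assert score_site(rm, "GCA") == pytest.approx(6.0)
        # triple mismatch: three zero-probability symbols at the -50-bit floor
        assert score_site(rm, "TGC") == pytest.approx(-150.0)

    def test_consensus_attains_maximum_by_enumeration(self, rng):
        for _ in range(5):
            fm = make_random_frequency_matrix(rng, length=3, positions=[-2, -1, 0])
            rm = ri_weights(fm, apply_correction=False)
            sites = enumerate_sites(length=3)
            scores = score_sites(rm, sites)
            assert scores.max() == pytest.approx(
                float(rm.weights.max(axis=1).sum()), abs=1e-9
            )

    def test_vectorized_matches_per_site_scoring(self, rng):
        fm = make_random_frequency_matrix(rng, length=4)
        rm = ri_weights(fm, apply_correction=False)
        sites = enumerate_sites(length=4)
        scores = score_sites(rm, sites)
        brute = {s: score_site(rm, s) for s in sites}
        for s in sites:
            assert scores[s] == pytest.approx(brute[s], abs=0)

    def test_bad_symbol_rejected(self):
        fm = column(0.25, 0.25, 0.25, 0.25)
        rm = ri_weights(fm, apply_correction=False)
        with pytest.raises(ValueError, match="outside the alphabet"):
            score_site(rm, "X")


class TestLogoTable:
    def test_uniform_gives_zero_heights(self):
        fm = column(0.25, 0.25, 0.25, 0.25)
        assert np.allclose(logo_table(fm, apply_correction=False).to_numpy(), 0.0)

    def test_conserved_column_single_two_bit_letter(self):
        fm = column(0, 0, 1, 0)
        heights = logo_table(fm, apply_correction=False)
        assert heights.at[1, "G"] == pytest.approx(2.0)
        assert heights.loc[1].sum() == pytest.approx(2.0)

    def test_heights_sum_to_information_per_position(self, rng):
        fm = make_random_frequency_matrix(rng, length=5)
        heights = logo_table(fm, apply_correction=False)
        info = information_content(fm, apply_correction=False).per_position
        assert np.allclose(heights.sum(axis=1).to_numpy(), info.to_numpy())


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.integers(1, 50), min_size=4, max_size=4))
def test_probability_rows_always_normalised(counts):
    total = sum(counts)
    sites = [b * 1 for b, c in zip("ACGT", counts) for _ in range(c)]
    fm = frequency_matrix_from_sites(sites, pseudocount=0.125)
    assert fm.probs.loc[1].sum() == pytest.approx(1.0, abs=1e-12)
    assert fm.n == total
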