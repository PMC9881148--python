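"""Photon-count histogram model and labelled-chain combinatorics.

The combinatorics oracle is exhaustive enumeration of all 2^P labelling
configurations; the PCH oracle is the analytic Poisson limit and the
convolution/superposition structure of independent species.
"""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

from parfcs import (
    PCHistogram,
    SimulationConfig,
    SpeciesBrightness,
    fit_pch,
    gen_pch,
    mean_multi_brightness,
    mean_multi_brightness_conditional,
    p_multi_label,
    p_single_label,
    p_x_labels,
    pch_mean,
    pch_model,
    solve_chains_per_complex,
)
from parfcs.errors import (
    DegenerateInputError,
    InvalidParameterError,
    TruncationError,
)


def enumerate_label_distribution(P, L):
    """Probability of each dye count by brute force over 2^P configurations."""
    probs = np.zeros(P + 1)
    for cfg in product((0, 1), repeat=P):
        x = sum(cfg)
        probs[x] += np.prod([L if c else 1.0 - L for c in cfg])
    return probs


class TestCombinatorics:
    @pytest.mark.parametrize("L", [0.02, 0.2, 0.36])
    @pytest.mark.parametrize("P", [1, 2, 3, 5, 8, 12])
    def test_agrees_with_enumeration(self, P, L):
        probs = enumerate_label_distribution(P, L)
        assert p_single_label(P, L) == pytest.approx(probs[1], abs=1e-12)
        assert p_multi_label(P, L) == pytest.approx(probs[2:].sum(), abs=1e-12)
        for x in range(P + 1):
            assert p_x_labels(P, x, L) == pytest.approx(probs[x], abs=1e-12)
        qm = sum(x * probs[x] for x in range(2, P + 1))
        assert mean_multi_brightness(P, L) == pytest.approx(qm, abs=1e-12)

    def test_known_values(self):
        assert p_single_label(1, 0.2) == pytest.approx(0.2)
        assert p_single_label(4, 0.2) == pytest.approx(0.4096, abs=1e-12)
        assert p_x_labels(4, 2, 0.2) == pytest.approx(0.1536, abs=1e-12)
        assert p_multi_label(4, 0.2) == pytest.approx(0.1808, abs=1e-12)
        assert mean_multi_brightness(4, 0.2) == pytest.approx(0.3904, abs=1e-12)
        assert p_multi_label(1, 0.3) == 0.0

    def test_single_label_maximised_near_reciprocal_l(self):
        vals = {P: p_single_label(P, 0.2) for P in range(1, 51)}
        assert max(vals, key=vals.get) in (4, 5)

    @settings(deadline=None, max_examples=60)
    @given(P=st.integers(1, 20), L=st.floats(0.01, 0.99))
    def test_binomial_identities(self, P, L):
        total = sum(p_x_labels(P, x, L) for x in range(P + 1))
        assert total == pytest.approx(1.0, abs=1e-12)
        assert mean_multi_brightness(P, L) + p_single_label(P, L) == pytest.approx(
            L * P, abs=1e-12
        )

    def test_conditional_variant(self):
        qm_cond = mean_multi_brightness_conditional(4, 0.2)
        assert qm_cond == pytest.approx(0.3904 / 0.1808, rel=1e-12)
        assert qm_cond > 2.0  # conditional mean over x >= 2 must exceed 2

    def test_domain_errors(self):
        with pytest.raises(InvalidParameterError):
            p_x_labels(4, 5, 0.2)
        with pytest.raises(InvalidParameterError):
            p_single_label(0, 0.2)
        with pytest.raises(InvalidParameterError):
            p_multi_label(4, 1.0)


class TestCompositionSolver:
    @pytest.mark.parametrize("L", [0.02, 0.2, 0.36])
    def test_noiseless_inversion_up_to_thirty_chains(self, L):
        for P in range(1, 31):
            singly = SpeciesBrightness(p_single_label(P, L), 1.0)
            nm = p_multi_label(P, L)
            multiply = (
                SpeciesBrightness(nm, mean_multi_brightness(P, L)) if nm > 0 else None
            )
            got, diag = solve_chains_per_complex(singly, multiply, L)
            assert got == P
            if P > 1:
                assert diag["residual"] < 1e-20

    def test_no_multiple_species_degenerate(self):
        got, diag = solve_chains_per_complex(
            SpeciesBrightness(0.4, 1.0), None, 0.2
        )
        assert got == 1 and diag["degenerate"]

    def test_modal_recovery_under_ratio_noise(self):
        """10% relative noise on all four observables, 100 seeds: the modal
        estimate equals the true P for P in 2..8 at L = 0.2."""
        for P in range(2, 9):
            n1 = p_single_label(P, 0.2)
            nm = p_multi_label(P, 0.2)
            qm = mean_multi_brightness(P, 0.2)
            estimates = []
            for seed in range(100):
                rng = np.random.default_rng(1000 + seed)
                f = 1.0 + 0.1 * rng.standard_normal(4)
                got, _ = solve_chains_per_complex(
                    SpeciesBrightness(n1 * f[0], f[1]),
                    SpeciesBrightness(nm * f[2], qm * f[3]),
                    0.2,
                )
                estimates.append(got)
            vals, counts = np.unique(estimates, return_counts=True)
            assert vals[np.argmax(counts)] == P


class TestPCHModel:
    def test_valid_distribution_and_mean(self):
        species = [SpeciesBrightness(1.5, 2.0)]
        probs = pch_model(species, 80)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        mean = float(np.arange(probs.size) @ probs)
        assert mean == pytest.approx(pch_mean(species), rel=1e-6)

    def test_two_species_mean_additive(self):
        species = [SpeciesBrightness(0.5, 1.0), SpeciesBrightness(0.1, 4.0)]
        probs = pch_model(species, 80)
        mean = float(np.arange(probs.size) @ probs)
        assert mean == pytest.approx(pch_mean(species), rel=1e-6)

    def test_superposition_convolution(self):
        one = pch_model([SpeciesBrightness(1.0, 1.5)] * 2, 60)
        doubled = pch_model([SpeciesBrightness(2.0, 1.5)], 60)
        assert np.allclose(one, doubled, atol=1e-12)

    def test_empty_focus_point_mass_at_zero(self):
        probs = pch_model([SpeciesBrightness(1e-12, 1.0)], 10)
        assert probs[0] == pytest.approx(1.0, abs=1e-10)

    def test_poisson_limit(self):
        """q -> 0 at fixed n*q: counts become Poisson with the model mean."""
        species = [SpeciesBrightness(6000.0, 0.0005)]
        probs = pch_model(species, 30)
        mu = pch_mean(species)
        tv = 0.5 * np.abs(probs - poisson.pmf(np.arange(31), mu)).sum()
        assert tv < 1e-4

    def test_truncation_guard(self):
        with pytest.raises(TruncationError):
            pch_model([SpeciesBrightness(5.0, 10.0)], 5)

    def test_afterpulse_shifts_mass_upward(self):
        base = pch_model([SpeciesBrightness(0.5, 2.0)], 60)
        ap = pch_model([SpeciesBrightness(0.5, 2.0)], 60, afterpulse_prob=0.1)
        mean_base = float(np.arange(61) @ base)
        mean_ap = float(np.arange(61) @ ap)
        assert mean_ap == pytest.approx(1.1 * mean_base, rel=1e-6)


class TestFitPCH:
    def test_single_species_recovery(self):
        hist = gen_pch([SpeciesBrightness(0.5, 1.0)], SimulationConfig(seed=3))
        res = fit_pch(hist, n_species=1)
        assert res.species[0].n_mean == pytest.approx(0.5, rel=0.05)
        assert res.species[0].q == pytest.approx(1.0, rel=0.05)

    def test_two_species_needed_when_brightness_differs(self):
        """Brightness ratio 4: the one-species fit is grossly worse (the
        two-model chi-square comparison used to detect multiply labelled
        complexes)."""
        species = [SpeciesBrightness(0.45, 0.6), SpeciesBrightness(0.05, 2.4)]
        hist = gen_pch(species, SimulationConfig(seed=3))
        chi1 = fit_pch(hist, n_species=1).reduced_chi2
        chi2 = fit_pch(hist, n_species=2).reduced_chi2
        assert chi1 > 5.0 * chi2

    def test_single_species_data_not_improved_by_second(self):
        hist = gen_pch([SpeciesBrightness(0.5, 1.0)], SimulationConfig(seed=4))
        chi1 = fit_pch(hist, n_species=1).reduced_chi2
        chi2 = fit_pch(hist, n_species=2).reduced_chi2
        assert chi2 > 0.8 * chi1  # no >20% improvement

    def test_all_zero_histogram_degenerate(self):
        hist = PCHistogram(np.arange(5), np.array([1000.0, 0, 0, 0, 0]))
        with pytest.raises(DegenerateInputError):
            fit_pch(hist)


class TestHistogramValidation:
    def test_rejects_negative(self):
        with pytest.raises(InvalidParameterError):
            PCHistogram(np.array([0, 1]), np.array([10.0, -1.0]))

    def test_rejects_overfull(self):
        with pytest.raises(InvalidParameterError):
            PCHistogram(
                np.array([0]), np.array([1e12]), bin_time=40e-6, duration=300.0
            )
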