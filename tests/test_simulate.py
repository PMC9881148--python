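"""Generators: determinism, protocol defaults, and round-trip convergence."""

import numpy as np
import pytest

from parfcs import (
    SimulationConfig,
    SpeciesBrightness,
    binding_model_tau,
    gen_branched_ensemble,
    gen_correlation_curve,
    gen_labelled_complexes,
    gen_pch,
    gen_titration,
    mean_multi_brightness,
    p_multi_label,
    p_single_label,
    pch_mean,
    model_g2,
)
from parfcs.errors import InvalidParameterError


class TestDeterminism:
    def test_all_generators_bit_reproducible(self):
        cfg = SimulationConfig(seed=42, noise_sigma=0.02)
        c1 = gen_correlation_curve(0.2, 3e-4, 5.0, cfg)
        c2 = gen_correlation_curve(0.2, 3e-4, 5.0, cfg)
        assert np.array_equal(c1.values, c2.values)
        t1 = gen_titration(8e-9, 431e-6, 907e-6, cfg)
        t2 = gen_titration(8e-9, 431e-6, 907e-6, cfg)
        assert np.array_equal(t1.tau_mean, t2.tau_mean)
        h1 = gen_pch([SpeciesBrightness(0.5, 1.0)], cfg)
        h2 = gen_pch([SpeciesBrightness(0.5, 1.0)], cfg)
        assert np.array_equal(h1.frequency, h2.frequency)
        x1 = gen_labelled_complexes(4, 0.2, 1000, cfg)
        x2 = gen_labelled_complexes(4, 0.2, 1000, cfg)
        assert np.array_equal(x1, x2)
        m1, _ = gen_branched_ensemble(1000, 50, 0.1, cfg)
        m2, _ = gen_branched_ensemble(1000, 50, 0.1, cfg)
        assert np.array_equal(m1, m2)

    def test_different_seeds_differ(self):
        a = gen_correlation_curve(0.2, 3e-4, 5.0, SimulationConfig(seed=1, noise_sigma=0.01))
        b = gen_correlation_curve(0.2, 3e-4, 5.0, SimulationConfig(seed=2, noise_sigma=0.01))
        assert not np.array_equal(a.values, b.values)


class TestDilutionGrid:
    def test_protocol_grid(self):
        """5 µM starting solution, twelve 1:1 dilutions (lowest 1.22 nM),
        plus the probe-only blank: 14 points."""
        grid = SimulationConfig().dilution_grid
        assert grid.size == 14
        assert grid[0] == 0.0
        assert grid[-1] == pytest.approx(5e-6)
        assert grid[1] == pytest.approx(5e-6 / 4096, rel=1e-12)  # 1.22 nM
        nz = grid[1:]
        assert np.allclose(nz[1:] / nz[:-1], 2.0)


class TestCorrelationGenerator:
    def test_noiseless_is_exact_model(self):
        cfg = SimulationConfig(noise_sigma=0.0)
        curve = gen_correlation_curve(0.2, 3e-4, 5.0, cfg)
        assert np.allclose(curve.values, model_g2(curve.lags, 0.2, 3e-4, 5.0))
        assert curve.sd is None

    def test_sd_tracks_noise_scale(self):
        cfg = SimulationConfig(seed=0, noise_sigma=0.05)
        curve = gen_correlation_curve(0.2, 3e-4, 5.0, cfg)
        clean = model_g2(curve.lags, 0.2, 3e-4, 5.0)
        assert np.allclose(curve.sd, 0.05 * clean)


class TestTitrationGenerator:
    def test_weak_binder_flat(self):
        cfg = SimulationConfig(noise_sigma=0.0)
        series = gen_titration(1.0, 431e-6, 907e-6, cfg)  # kd = 1 M
        assert np.all(np.abs(series.tau_mean / 431e-6 - 1.0) < 1e-4)

    def test_half_saturation_position_on_grid(self):
        """kd = 8 nM sits between the 3rd (4.88 nM) and 4th (9.77 nM) lowest
        non-zero concentrations, so the midpoint crossing lies there."""
        cfg = SimulationConfig(noise_sigma=0.0)
        series = gen_titration(8e-9, 431e-6, 907e-6, cfg)
        mid = (431e-6 + 907e-6) / 2
        nz = series.concentrations > 0
        below = series.concentrations[nz][series.tau_mean[nz] < mid]
        above = series.concentrations[nz][series.tau_mean[nz] > mid]
        assert below.max() == pytest.approx(5e-6 / 1024)  # 4.88 nM
        assert above.min() == pytest.approx(5e-6 / 512)  # 9.77 nM

    def test_correlation_convention_biases_midpoint(self):
        """The brightness-weighted observable (1-component fit to the
        2-component correlation) deviates from the linear convention most
        near half-saturation but shares the endpoints."""
        cfg = SimulationConfig(noise_sigma=0.0)
        lin = gen_titration(8e-9, 200e-6, 600e-6, cfg, convention="linear")
        cor = gen_titration(8e-9, 200e-6, 600e-6, cfg, convention="correlation")
        assert cor.tau_mean[0] == pytest.approx(200e-6, rel=1e-3)
        assert cor.tau_mean[-1] == pytest.approx(600e-6, rel=1e-2)
        mid_idx = np.argmin(np.abs(lin.tau_mean - 400e-6))
        assert abs(cor.tau_mean[mid_idx] - lin.tau_mean[mid_idx]) > 1e-6

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            gen_titration(8e-9, 500e-6, 400e-6)  # bound faster than free


class TestPCHGenerator:
    def test_empirical_mean_matches_model(self):
        species = [SpeciesBrightness(0.5, 1.0)]
        hist = gen_pch(species, SimulationConfig(seed=21))
        n = hist.frequency.sum()
        emp_mean = float((hist.counts_axis * hist.frequency).sum() / n)
        mu = pch_mean(species)
        # variance of the count distribution bounds the SE of the mean
        var = float(
            ((hist.counts_axis - emp_mean) ** 2 * hist.frequency).sum() / n
        )
        assert abs(emp_mean - mu) < 3.0 * np.sqrt(var / n)

    def test_vanishing_occupancy_all_zero_bins(self):
        hist = gen_pch([SpeciesBrightness(1e-12, 1.0)], SimulationConfig(seed=5))
        assert hist.frequency[1:].sum() == 0


class TestLabelledComplexes:
    def test_empirical_frequencies_converge(self):
        x = gen_labelled_complexes(4, 0.2, 10**6, SimulationConfig(seed=11))
        n1_emp = float((x == 1).mean())
        assert abs(n1_emp - p_single_label(4, 0.2)) < 0.002
        nm_emp = float((x >= 2).mean())
        assert abs(nm_emp - p_multi_label(4, 0.2)) < 0.002
        qm_emp = float(x[x >= 2].sum() / x.size)
        # 3 SE bound on the unconditional multi-label brightness
        se = np.sqrt(0.8704 / x.size)  # E[x^2 1(x>=2)] for P=4, L=0.2
        assert abs(qm_emp - mean_multi_brightness(4, 0.2)) < 3 * se

    def test_zero_labelling_all_dark(self):
        x = gen_labelled_complexes(4, 0.0, 1000, SimulationConfig(seed=1))
        assert np.all(x == 0)


class TestBranchedEnsemble:
    def test_linear_ensemble(self):
        mols, counts = gen_branched_ensemble(500, 50, 0.0, SimulationConfig(seed=2))
        assert counts.r2_ado == 0
        assert counts.ado == 500

    def test_length_distribution_callable_and_sequence(self):
        cfg = SimulationConfig(seed=3)
        mols, _ = gen_branched_ensemble(100, [10, 20, 30], 0.01, cfg)
        assert set(np.unique(mols[:, 0])) <= {10, 20, 30}

    def test_feasibility_constraint_enforced(self):
        mols, _ = gen_branched_ensemble(2000, 5, 0.4, SimulationConfig(seed=4))
        assert np.all(mols[:, 0] >= 2 * mols[:, 1] + 1)

    def test_infeasible_branching_raises(self):
        with pytest.raises(InvalidParameterError):
            gen_branched_ensemble(
                200, 3, 0.99, SimulationConfig(seed=5), max_rejections=1
            )

    def test_mean_titration_uses_binding_model(self):
        cfg = SimulationConfig(noise_sigma=0.0)
        series = gen_titration(32e-9, 431e-6, 907e-6, cfg)
        expect = binding_model_tau(series.concentrations, 32e-9, 431e-6, 907e-6)
        assert np.allclose(series.tau_mean, expect)
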