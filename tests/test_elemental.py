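"""Ionomics operations: intensities, K/Ca deconvolution, ANOVA, summaries."""

import math

import numpy as np
import pytest

import xrfpit as xp
from xrfpit.elemental import (
    CA_KA,
    K_KA,
    anova_two_way_table,
    group_summaries,
    r_squared,
)


def _kca_config(k_amp=1000.0, ca_amp=500.0, **kw):
    lines = (
        xp.ElementLine("K", "Ka", 3.31, 1.0),
        xp.ElementLine("K", "Kb", 3.59, 0.12),
        xp.ElementLine("Ca", "Ka", 3.69, 1.0),
        xp.ElementLine("Ca", "Kb", 4.01, 0.12),
    )
    return xp.default_config(
        line_table=lines,
        baseline_amplitudes={"K": k_amp, "Ca": ca_amp},
        bp_effects={"K": 1.3, "Ca": 0.65},
        poisson_noise=kw.pop("poisson_noise", False),
        within_fruit_cv=0.0,
        between_fruit_cv=0.0,
        **kw,
    )


def _render(cfg, seed=0):
    rng = np.random.default_rng(seed)
    fr = xp.simulate_fruit(cfg, "non_BP", rng)
    return fr, xp.render_spectrum(fr, cfg, rng)


class TestLineIntensity:
    def test_noiseless_peak_apex(self):
        cfg = _kca_config()
        _, y = _render(cfg)
        h = xp.line_intensity(y, cfg.grid, K_KA)
        assert h == pytest.approx(1000.0 + cfg.background_level, rel=5e-3)

    def test_flat_zero_spectrum(self):
        cfg = _kca_config()
        assert xp.line_intensity(np.zeros(cfg.grid.n_channels), cfg.grid, K_KA) == 0.0

    def test_overlapping_peak_adds_analytic_tail(self):
        cfg = _kca_config(k_amp=10_000.0, ca_amp=500.0)
        _, y = _render(cfg)
        h = xp.line_intensity(y, cfg.grid, CA_KA, half_window=0.01)
        e = cfg.grid.energies
        apex = np.argmin(np.abs(e - CA_KA))
        analytic = cfg.background_level + sum(
            amp * math.exp(-((e[apex] - c) ** 2) / (2 * cfg.detector_sigma**2))
            for amp, c in [(10_000 * 0.12, 3.59), (500.0, 3.69), (500 * 0.12, 4.01)]
        )
        assert h == pytest.approx(analytic, rel=1e-6)
        assert h > 500.0 + cfg.background_level  # K Kb tail raises the Ca apex

    def test_window_outside_grid_rejected(self):
        cfg = _kca_config()
        with pytest.raises(ValueError, match="outside"):
            xp.line_intensity(np.zeros(cfg.grid.n_channels), cfg.grid, 7.99)


class TestDeconvolution:
    def test_noiseless_recovery_of_amplitude_ratio(self):
        cfg = _kca_config(k_amp=1000.0, ca_amp=500.0)
        _, y = _render(cfg)
        fit = xp.deconvolve_k_ca(y, cfg.grid)
        assert fit.converged
        assert fit.ratio_deconvolved == pytest.approx(2.0, abs=0.01)

    def test_noiseless_area_recovery_within_a_tenth_percent(self, noiseless_cfg):
        fr, y = _render(noiseless_cfg)
        fit = xp.deconvolve_k_ca(y, noiseless_cfg.grid)
        s = noiseless_cfg.detector_sigma
        for el, key in [("K", "K_Ka"), ("Ca", "Ca_Ka")]:
            true_area = fr.true_amplitudes[el] * s * math.sqrt(2 * math.pi)
            assert abs(fit.areas[key] / true_area - 1) < 1e-3

    def test_absent_ca_peak_leaves_ratio_undefined(self):
        cfg = _kca_config(k_amp=1000.0, ca_amp=500.0)
        cfg = cfg.replace(
            line_table=cfg.line_table[:2], baseline_amplitudes={"K": 1000.0}
        )
        _, y = _render(cfg)
        fit = xp.deconvolve_k_ca(y, cfg.grid)
        assert fit.ratio_deconvolved is None or fit.areas["Ca_Ka"] < 1.0

    def test_poisson_replicates_recover_mean_ratio_within_3pct(self, default_cfg):
        cfg = default_cfg.replace(within_fruit_cv=0.0, between_fruit_cv=0.0)
        rng = np.random.default_rng(3)
        fr = xp.simulate_fruit(cfg, "non_BP", rng)
        true_ratio = fr.true_amplitudes["K"] / fr.true_amplitudes["Ca"]
        ratios = []
        for _ in range(200):
            y = xp.render_spectrum(fr, cfg, rng)
            fit = xp.deconvolve_k_ca(y, cfg.grid)
            ratios.append(fit.ratio_deconvolved)
        assert np.mean(ratios) == pytest.approx(true_ratio, rel=0.03)

    def test_ratio_invariant_to_spectrum_rescaling(self):
        cfg = _kca_config(k_amp=1000.0, ca_amp=400.0)
        _, y = _render(cfg)
        a = xp.deconvolve_k_ca(y, cfg.grid).ratio_deconvolved
        b = xp.deconvolve_k_ca(y * 10, cfg.grid).ratio_deconvolved
        assert a == pytest.approx(b, rel=1e-6)


class TestDirectRatio:
    def test_noiseless_background_subtracted_ratio(self):
        cfg = _kca_config(k_amp=1000.0, ca_amp=500.0)
        _, y = _render(cfg)
        # Ca apex includes the K Kb tail; subtract it analytically for the oracle
        tail = 1000 * 0.12 * math.exp(-(0.1**2) / (2 * cfg.detector_sigma**2))
        assert xp.kca_direct(y, cfg.grid) == pytest.approx(1000 / (500 + tail), rel=0.01)

    def test_scale_invariance(self):
        cfg = _kca_config()
        _, y = _render(cfg)
        assert xp.kca_direct(y * 10, cfg.grid) == pytest.approx(
            xp.kca_direct(y, cfg.grid), rel=1e-9
        )

    def test_agreement_r2_perfect_and_null(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 10, 1000)
        assert r_squared(x, x) == pytest.approx(1.0)
        assert r_squared(x, rng.uniform(1, 10, 1000)) <= 0.01
        with pytest.raises(ValueError, match="constant"):
            r_squared(np.ones(10), x[:10])


class TestTwoWayAnova:
    def test_matches_brute_force_on_balanced_2x2(self):
        # two replicates per cell; classical balanced-layout sums of squares
        y = np.array([3.0, 4.0, 6.0, 7.0, 5.0, 6.0, 10.0, 12.0])
        a = ["lo", "lo", "lo", "lo", "hi", "hi", "hi", "hi"]
        b = ["x", "x", "y", "y", "x", "x", "y", "y"]
        tab = anova_two_way_table(y, a, b)

        arr = y.reshape(2, 2, 2)  # (a, b, replicate)
        grand = arr.mean()
        ss_a = 4 * ((arr.mean(axis=(1, 2)) - grand) ** 2).sum()
        ss_b = 4 * ((arr.mean(axis=(0, 2)) - grand) ** 2).sum()
        cell = arr.mean(axis=2)
        ss_ab = 2 * (
            (cell - cell.mean(axis=1, keepdims=True) - cell.mean(axis=0, keepdims=True) + grand) ** 2
        ).sum()
        ss_e = ((arr - cell[..., None]) ** 2).sum()
        f_a = (ss_a / 1) / (ss_e / 4)
        f_b = (ss_b / 1) / (ss_e / 4)
        f_ab = (ss_ab / 1) / (ss_e / 4)
        assert tab.loc["C(a)", "F"] == pytest.approx(f_a)
        assert tab.loc["C(b)", "F"] == pytest.approx(f_b)
        assert tab.loc["C(a):C(b)", "F"] == pytest.approx(f_ab)

    def test_power_and_position_null_on_generated_study(self, default_cfg):
        sset = xp.generate_balanced_study(default_cfg, 60, seed=13)
        kline = next(l for l in xp.DEFAULT_LINE_TABLE if l.element == "K" and l.line_label == "Ka")
        cmp = xp.two_way_anova(sset, kline)
        assert cmp.anova_p_status < 1e-5
        assert cmp.anova_p_position > 0.01  # no position effect in the generator
        assert cmp.group_means["BP"] > cmp.group_means["non_BP"]

    def test_null_p_values_uniform_across_seeds(self):
        from scipy import stats

        # between-fruit dispersion off: rows are then i.i.d. under the null, so
        # the status F-test's p-value is exactly uniform
        cfg = xp.default_config(points_per_fruit=4, bp_effects={}, between_fruit_cv=0.0)
        kline = next(l for l in xp.DEFAULT_LINE_TABLE if l.element == "K" and l.line_label == "Ka")
        pvals = []
        for seed in range(120):
            sset = xp.generate_balanced_study(cfg, 4, seed=seed)
            pvals.append(xp.two_way_anova(sset, kline).anova_p_status)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_within_group_variance_rejected(self):
        y = [1.0, 1.0, 2.0, 2.0, 1.0, 1.0, 2.0, 2.0]
        a = ["l", "l", "l", "l", "h", "h", "h", "h"]
        b = ["x", "x", "y", "y", "x", "x", "y", "y"]
        with pytest.raises(ValueError, match="variance"):
            anova_two_way_table(y, a, b)

    def test_empty_cells_listed(self):
        y = [1.0, 2.0, 3.0, 4.0]
        a = ["l", "l", "h", "h"]
        b = ["x", "x", "y", "y"]
        with pytest.raises(ValueError, match="empty cells"):
            anova_two_way_table(y, a, b)


class TestGroupSummaries:
    def test_quartiles_linear_interpolation_convention(self):
        out = group_summaries({"non_BP": [1, 2, 3, 4, 5]})["non_BP"]["box"]
        assert (out["q1"], out["median"], out["q3"]) == (2.0, 3.0, 4.0)

    def test_single_value_collapses_quartiles(self):
        box = group_summaries({"BP": [7.0]})["BP"]["box"]
        assert box["q1"] == box["median"] == box["q3"] == 7.0

    def test_ecdf_reaches_one_and_monotone(self):
        vals, frac = group_summaries({"BP": [3, 1, 2]})["BP"]["ecdf"]
        assert frac[-1] == 1.0
        assert (np.diff(vals) >= 0).all() and (np.diff(frac) > 0).all()
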