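"""Resolution shells, CC1/2, Wilson B, information gain, anomalous maps."""

import numpy as np
import pandas as pd
import pytest

from swsx import UnitCell, WedgePlan, generate_ground_truth, make_polymorphs, simulate_wedges
from swsx.metrics import (
    ShellStats,
    anomalous_peak,
    cc_half,
    dmin_at_cchalf,
    information_gain,
    make_shells,
    mean_i_over_sigma,
    wilson_b,
)
from swsx.scale_merge import MergedDataset, fit_wedge_scales, merge
from swsx.sim_core import random_symmetric_model


def synthetic_observations(truth, n_obs, noise_sd, d_values, seed):
    """Scaled-observation table for a known signal/noise decomposition."""
    rng = np.random.default_rng(seed)
    n = len(truth)
    obs = np.repeat(truth, n_obs) + rng.normal(0, noise_sd, n * n_obs)
    return MergedDataset(
        table=pd.DataFrame(
            {
                "kh": np.arange(n), "kk": 0, "kl": 0, "sign": 1,
                "s": 0.5 / d_values, "d": d_values,
                "i_mean": truth, "sigma_mean": noise_sd / np.sqrt(n_obs),
                "n_obs": n_obs,
            }
        ),
        anomalous=False,
        scaled_obs=pd.DataFrame(
            {
                "code": np.repeat(np.arange(n), n_obs),
                "i_scaled": obs,
                "sigma_scaled": noise_sd,
                "wedge": 0,
                "frame": 0,
                "s": np.repeat(0.5 / d_values, n_obs),
                "d": np.repeat(d_values, n_obs),
                "kept": True,
            }
        ),
    )


class TestShells:
    def test_equal_volume_partition(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(1.5, 10.0, 5000)
        shells, idx = make_shells(d, n_shells=10)
        u = 1.0 / d**3
        widths = np.diff(np.linspace(u.min(), u.max(), 11))
        assert np.allclose(widths, widths[0])
        assert idx.min() == 0 and idx.max() == 9
        assert shells.n_unique.sum() == len(d)


class TestCCHalf:
    def test_noiseless_duplicates_give_unity(self):
        rng = np.random.default_rng(1)
        truth = rng.exponential(1.0, 300)
        m = synthetic_observations(truth, 4, 1e-12, rng.uniform(2, 5, 300), seed=1)
        shells = cc_half(m, n_shells=3, seed=0)
        assert np.all(shells.cc_half > 0.999999)

    def test_pure_noise_decorrelates(self):
        rng = np.random.default_rng(2)
        truth = np.full(400, 10.0)  # constant truth: no signal variance
        m = synthetic_observations(truth, 4, 5.0, rng.uniform(2, 5, 400), seed=2)
        ccs = [cc_half(m, n_shells=1, seed=s).cc_half[0] for s in range(40)]
        assert abs(np.mean(ccs)) < 3 / np.sqrt(400)

    @pytest.mark.parametrize("noise_sd", [0.5, 1.0, 2.0])
    def test_monte_carlo_mean_matches_analytic_half_set_formula(self, noise_sd):
        s2 = 1.0
        n_obs = 4
        e2 = noise_sd**2 / (n_obs / 2)
        expected = s2 / (s2 + e2)
        rng = np.random.default_rng(3)
        vals = []
        for rep in range(120):
            truth = rng.normal(10.0, np.sqrt(s2), 400)
            m = synthetic_observations(
                truth, n_obs, noise_sd, np.linspace(2, 5, 400), seed=1000 + rep
            )
            vals.append(cc_half(m, n_shells=1, seed=rep).cc_half[0])
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se


class TestDminAtCCHalf:
    def _shells(self, cc):
        return ShellStats(
            d_lo=np.array([5.0, 3.54, 2.89, 2.5]),
            d_hi=np.array([3.54, 2.89, 2.5, 2.24]),
            center_invd2=np.array([0.04, 0.08, 0.12, 0.16]),
            n_unique=np.full(4, 100),
            multiplicity=np.full(4, 5.0),
            cc_half=np.asarray(cc, dtype=float),
        )

    def test_hand_interpolation_oracle(self):
        shells = self._shells([0.99, 0.9, 0.7, 0.45])
        # crossing at 1/d^2 = 0.12 + 0.04*(0.7-0.5)/(0.7-0.45)
        assert dmin_at_cchalf(shells) == pytest.approx(1 / np.sqrt(0.152), abs=1e-6)

    def test_never_below_level_returns_finest_boundary(self):
        shells = self._shells([0.99, 0.99, 0.99, 0.99])
        assert dmin_at_cchalf(shells) == pytest.approx(2.24)
        assert not shells.no_signal

    def test_below_level_in_first_shell_flags_no_signal(self):
        shells = self._shells([0.99, 0.9, 0.7, 0.45])
        assert dmin_at_cchalf(shells, level=1.1) == pytest.approx(5.0)
        assert shells.no_signal

    def test_all_undefined_errors(self):
        shells = self._shells([np.nan] * 4)
        with pytest.raises(ValueError):
            dmin_at_cchalf(shells)


class TestMeanIOverSigma:
    def test_constant_ratio(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(2, 6, 200)
        m = synthetic_observations(np.full(200, 10.0), 2, 1.0, d, seed=0)
        m.table["sigma_mean"] = 2.0
        shells = mean_i_over_sigma(m, n_shells=4)
        assert np.allclose(shells.mean_i_over_sigma, 5.0)

    def test_infinite_noise_drives_ratio_to_zero(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(2, 6, 50)
        m = synthetic_observations(np.full(50, 10.0), 2, 1.0, d, seed=0)
        m.table["sigma_mean"] = 1e12
        shells = mean_i_over_sigma(m, n_shells=2)
        assert np.all(shells.mean_i_over_sigma < 1e-9)

    def test_high_resolution_gain_scales_with_sqrt_multiplicity(self, wilson_gt):
        poly = make_polymorphs(wilson_gt, 1, 1.0, seed=1)
        plan = WedgePlan(wedge_deg=10.0, dose_total=1e7, n0=2e-4, sigma_sys=0.0, bg_rate=1.0)
        ratios = []
        for n in (8, 16):
            wedges = simulate_wedges(poly, n, plan, seed=10, sigma_g=0.0, sigma_b=0.0)
            sm = fit_wedge_scales(wedges)
            merged = merge(wedges, sm)
            shells = mean_i_over_sigma(merged, n_shells=5)
            ratios.append(shells.mean_i_over_sigma[-1])
        assert ratios[1] / ratios[0] == pytest.approx(np.sqrt(2), rel=0.10)


class TestWilsonB:
    def _merged_with_b(self, b_true, seed=0, n=4000):
        rng = np.random.default_rng(seed)
        d = 1.0 / np.sqrt(rng.uniform(1 / 36, 1 / 4, n))  # 2..6 A
        s2 = 0.25 / d**2
        i = rng.exponential(np.exp(-2 * b_true * s2))
        return MergedDataset(
            table=pd.DataFrame(
                {
                    "kh": np.arange(n), "kk": 0, "kl": 0, "sign": 1,
                    "s": np.sqrt(s2), "d": d, "i_mean": i,
                    "sigma_mean": 0.01 + 0.001 * i, "n_obs": 4,
                }
            ),
            anomalous=False,
        )

    def test_recovers_planted_b(self):
        b, intercept, flag = wilson_b(self._merged_with_b(10.0), n_shells=12)
        assert 9.0 <= b <= 11.0
        assert not flag

    def test_flat_truth_gives_near_zero_slope(self):
        b, _, _ = wilson_b(self._merged_with_b(0.0), n_shells=12)
        assert abs(b) < 1.5

    def test_over_sharpening_flag_at_default_floor(self):
        b, _, flag = wilson_b(self._merged_with_b(2.0), n_shells=12)
        assert flag  # B ~ 2 < 8 A^2 floor


class TestInformationGain:
    def _single(self, i_obs, sigma):
        return MergedDataset(
            table=pd.DataFrame(
                {
                    "kh": [1], "kk": [0], "kl": [0], "sign": [1],
                    "s": [0.2], "d": [2.5], "i_mean": [i_obs],
                    "sigma_mean": [sigma], "n_obs": [2],
                }
            ),
            anomalous=False,
        )

    def test_uninformative_limit(self):
        total, per = information_gain(self._single(1.0, 100.0))
        assert per < 0.01

    def test_non_negative_for_odd_inputs(self):
        for i_obs, sigma in [(-5.0, 1.0), (0.0, 0.5), (30.0, 0.2)]:
            total, per = information_gain(self._single(i_obs, sigma))
            assert total >= 0.0

    def test_quadrature_matches_fine_grid_oracle(self):
        m = self._single(1.0, 0.1)
        g_coarse, _ = information_gain(m, quadrature_n=2000)
        g_fine, _ = information_gain(m, quadrature_n=100_000)
        assert abs(g_coarse - g_fine) < 1e-3

    def test_gain_increases_when_sigma_shrinks(self, small_merged):
        merged, _ = small_merged
        total1, _ = information_gain(merged)
        better = MergedDataset(
            table=merged.table.assign(sigma_mean=merged.table["sigma_mean"] / 2),
            anomalous=False, scaled_obs=merged.scaled_obs,
        )
        total2, _ = information_gain(better)
        assert total2 > total1

    def test_non_positive_sigma_rejected(self):
        with pytest.raises(ValueError):
            information_gain(self._single(1.0, 0.0))


@pytest.fixture(scope="module")
def model_setup():
    cell = UnitCell(20, 20, 20)
    model, sites = random_symmetric_model("23", n_light=30, seed=2)
    gt = generate_ground_truth(cell, "23", 2.0, mode="model", model=model, seed=0)
    return cell, gt, sites


class TestAnomalousPeak:
    def _merged_from_truth(self, gt, scale=1.0, noise=None, seed=0, flip=False):
        t = gt.table
        rng = np.random.default_rng(seed)
        rows = []
        for sgn, col in ((1, "i_plus"), (-1, "i_minus")):
            d = t.copy()
            vals = t[col].values * scale
            if noise is not None:
                vals = vals + rng.normal(0, noise, len(t))
            d["i_mean"] = vals
            d["sign"] = sgn
            d["sigma_mean"] = 1.0
            d["n_obs"] = 2
            rows.append(
                d[["h", "k", "l", "sign", "s", "d", "i_mean", "sigma_mean", "n_obs"]]
                .rename(columns={"h": "kh", "k": "kk", "l": "kl"})
            )
        if flip:
            rows = rows[::-1]
            rows[0]["sign"], rows[1]["sign"] = 1, -1
        return MergedDataset(table=pd.concat(rows, ignore_index=True), anomalous=True)

    def test_noise_free_peak_is_global_map_maximum_at_site(self, model_setup):
        cell, gt, sites = model_setup
        merged = self._merged_from_truth(gt)
        peak = anomalous_peak(merged, gt.model, cell, gt.pointgroup, sites[0])
        off = anomalous_peak(merged, gt.model, cell, gt.pointgroup, (0.123, 0.321, 0.456))
        assert peak > 5.0
        assert peak > 3 * abs(off)

    def test_null_distribution_without_anomalous_signal(self, model_setup):
        cell, gt, sites = model_setup
        # strip the Bijvoet differences, keep noise: peak should be noise-level
        t = gt.table.copy()
        mean = 0.5 * (t["i_plus"] + t["i_minus"])
        null_gt = gt
        hits = 0
        for seed in range(20):
            t2 = t.copy()
            t2["i_plus"] = mean
            t2["i_minus"] = mean
            null_gt = type(gt)(
                cell=gt.cell, pointgroup=gt.pointgroup, d_min=gt.d_min,
                mode=gt.mode, table=t2, model=gt.model, params=gt.params,
            )
            merged = self._merged_from_truth(null_gt, noise=mean.mean() * 0.05, seed=seed)
            peak = anomalous_peak(merged, gt.model, cell, gt.pointgroup, sites[0])
            hits += abs(peak) < 4.0
        assert hits >= 19

    def test_negating_differences_negates_peak(self, model_setup):
        cell, gt, sites = model_setup
        merged = self._merged_from_truth(gt)
        peak = anomalous_peak(merged, gt.model, cell, gt.pointgroup, sites[0])
        flipped = self._merged_from_truth(gt, flip=True)
        peak_f = anomalous_peak(flipped, gt.model, cell, gt.pointgroup, sites[0])
        assert peak_f == pytest.approx(-peak, rel=1e-6)

    def test_too_few_pairs_rejected(self, model_setup):
        cell, gt, sites = model_setup
        merged = self._merged_from_truth(gt)
        merged.table = merged.table.iloc[:40]
        with pytest.raises(ValueError, match="Bijvoet"):
            anomalous_peak(merged, gt.model, cell, gt.pointgroup, sites[0])
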