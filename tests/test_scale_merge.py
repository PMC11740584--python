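"""Relative scaling, outlier rejection, merging and merging statistics."""

import numpy as np
import pandas as pd
import pytest

from swsx import UnitCell, WedgePlan, make_polymorphs, simulate_wedges
from swsx.scale_merge import (
    MergedDataset,
    ScalingModel,
    fit_wedge_scales,
    merge,
    merging_stats,
    reject_outlier_frames,
    reject_outlier_wedges,
    three_run_merge,
)


@pytest.fixture(scope="module")
def clean_wedges(wilson_gt):
    """High-count Poisson-only wedges with planted per-wedge scales."""
    poly = make_polymorphs(wilson_gt, 1, 1.0, seed=1)
    plan = WedgePlan(
        wedge_deg=10.0, frame_deg=0.2, dose_total=1e7, n0=2e-3,
        sigma_sys=0.0, bg_rate=0.0,
    )
    return simulate_wedges(poly, 20, plan, seed=8, sigma_g=0.3, sigma_b=3.0)


class TestScaling:
    def test_planted_scale_and_b_recovered(self, clean_wedges):
        sm = fit_wedge_scales(clean_wedges)
        assert sm.converged
        jref = sm.wedge_ids.index(sm.reference_id)
        tg = np.array([w.true_ln_g for w in clean_wedges])
        tb = np.array([w.true_b for w in clean_wedges])
        assert np.sqrt(np.mean((sm.ln_g - (tg - tg[jref])) ** 2)) < 0.02
        assert np.sqrt(np.mean((sm.b_rel - (tb - tb[jref])) ** 2)) < 0.3

    def test_reference_has_zero_parameters_and_lowest_b(self, clean_wedges):
        sm = fit_wedge_scales(clean_wedges)
        jref = sm.wedge_ids.index(sm.reference_id)
        assert sm.ln_g[jref] == 0.0 and sm.b_rel[jref] == 0.0
        assert np.all(sm.b_rel >= -1e-9)

    def test_identical_wedges_get_unit_scales(self, small_wedges):
        clones = []
        for j in range(4):
            w = small_wedges[0].with_observations(small_wedges[0].observations.copy())
            w.wedge_id = f"c{j}"
            clones.append(w)
        sm = fit_wedge_scales(clones)
        assert np.allclose(sm.ln_g, 0.0, atol=1e-9)
        assert np.allclose(sm.b_rel, 0.0, atol=1e-9)

    def test_gauge_invariance_of_merged_intensities(self, clean_wedges):
        sm1 = fit_wedge_scales(clean_wedges)
        m1 = merge(clean_wedges, sm1)
        scaled = [
            w.with_observations(
                w.observations.assign(
                    i_obs=w.observations["i_obs"] * 7.0,
                    sigma=w.observations["sigma"] * 7.0,
                )
            )
            for w in clean_wedges
        ]
        sm2 = fit_wedge_scales(scaled)
        m2 = merge(scaled, sm2)
        ratio = m2.table["i_mean"].values / m1.table["i_mean"].values
        assert np.std(ratio / ratio.mean()) < 1e-8


class TestMerge:
    def test_inverse_variance_arithmetic(self):
        obs = pd.DataFrame(
            {
                "kh": [1, 1], "kk": [0, 0], "kl": [0, 0], "sign": [1, 1],
                "s": [0.1, 0.1], "d": [5.0, 5.0],
                "i_obs": [10.0, 20.0], "sigma": [1.0, 2.0], "frame": [0, 0],
                "h": [1, 1], "k": [0, 0], "l": [0, 0], "phi": [0.0, 0.0],
            }
        )
        from swsx.sim_core import WedgeDataset

        wedges = [
            WedgeDataset(
                wedge_id=f"w{j}", cell=UnitCell(10, 10, 10), pointgroup_name="1",
                plan=WedgePlan(), observations=obs.iloc[[j]].reset_index(drop=True),
            )
            for j in range(2)
        ]
        sm = ScalingModel(["w0", "w1"], np.zeros(2), np.zeros(2), "w0", 1, True)
        merged = merge(wedges, sm, reject_k=np.inf)
        assert merged.table["i_mean"].iloc[0] == pytest.approx(12.0)
        assert merged.table["sigma_mean"].iloc[0] == pytest.approx(np.sqrt(1 / 1.25))
        assert merged.table["n_obs"].iloc[0] == 2

    def test_duplicate_observations_merge_to_value(self, small_wedges):
        w = small_wedges[0]
        dup = w.with_observations(pd.concat([w.observations] * 2, ignore_index=True))
        setattr(dup, "wedge_id", "dup")
        sm = ScalingModel([w.wedge_id, "dup"], np.zeros(2), np.zeros(2), w.wedge_id, 1, True)
        merged = merge([w, dup], sm, reject_k=np.inf)
        # each unique now holds 3x its original observations; spot check one
        row = merged.table.iloc[0]
        sel = w.observations[
            (w.observations["kh"] == row.kh)
            & (w.observations["kk"] == row.kk)
            & (w.observations["kl"] == row.kl)
        ]
        assert row.n_obs == 3 * len(sel)

    def test_merged_cc_to_truth_improves_with_wedge_count(self, wilson_gt):
        poly = make_polymorphs(wilson_gt, 1, 1.0, seed=1)
        plan = WedgePlan(wedge_deg=5.0, dose_total=1e7, n0=2e-4, sigma_sys=0.03)
        ccs = []
        for n in (4, 16):
            wedges = simulate_wedges(poly, n, plan, seed=9)
            res = three_run_merge(wedges)
            tab = res.merged.table
            i_true = wilson_gt.intensities(
                tab[["kh", "kk", "kl"]].values, np.ones(len(tab), dtype=int)
            )
            ccs.append(np.corrcoef(tab["i_mean"], i_true)[0, 1])
        assert ccs[1] > ccs[0]

    def test_sigma_calibration_with_known_scales(self, wilson_gt):
        """z-scores of merged vs truth have unit spread in the Poisson regime."""
        poly = make_polymorphs(wilson_gt, 1, 1.0, seed=1)
        plan = WedgePlan(
            wedge_deg=10.0, dose_total=1e7, n0=2e-3, sigma_sys=0.0, bg_rate=0.0
        )
        sds = []
        for seed in range(3):
            wedges = simulate_wedges(poly, 20, plan, seed=seed, sigma_g=0.0, sigma_b=0.0)
            sm = ScalingModel(
                [w.wedge_id for w in wedges], np.zeros(20), np.zeros(20),
                wedges[0].wedge_id, 0, True,
            )
            m = merge(wedges, sm)
            tab = m.table
            i_true = wilson_gt.intensities(
                tab[["kh", "kk", "kl"]].values, np.ones(len(tab), dtype=int)
            )
            scale = np.nansum(tab["i_mean"] * i_true) / np.nansum(i_true**2)
            z = (tab["i_mean"] - scale * i_true) / tab["sigma_mean"]
            sds.append(np.nanstd(z))
        assert all(0.9 <= sd <= 1.1 for sd in sds)


class TestOutlierRejection:
    def test_clean_frames_rarely_rejected(self, clean_wedges):
        sm = fit_wedge_scales(clean_wedges)
        _, report = reject_outlier_frames(clean_wedges, sm, k_mad=3.5)
        assert report["rejected"].mean() <= 0.01

    def test_planted_corrupt_frame_rejected(self, clean_wedges):
        bad = clean_wedges[3]
        obs = bad.observations.copy()
        hit = obs["frame"] == 7
        obs.loc[hit, "i_obs"] *= 10.0
        wedges = list(clean_wedges)
        wedges[3] = bad.with_observations(obs)
        sm = fit_wedge_scales(wedges)
        filtered, report = reject_outlier_frames(wedges, sm, k_mad=3.5)
        flagged = report[(report["wedge_id"] == bad.wedge_id) & (report["frame"] == 7)]
        assert flagged["rejected"].all()
        assert not (filtered[3].observations["frame"] == 7).any()

    def test_infinite_k_rejects_nothing(self, clean_wedges):
        sm = fit_wedge_scales(clean_wedges)
        filtered, report = reject_outlier_frames(clean_wedges, sm, k_mad=np.inf)
        assert not report["rejected"].any()
        assert all(a.n_obs == b.n_obs for a, b in zip(filtered, clean_wedges))

    def test_homogeneous_wedges_not_rejected(self, clean_wedges):
        sm = fit_wedge_scales(clean_wedges)
        kept, report = reject_outlier_wedges(clean_wedges, sm, cc_min=0.8)
        assert report["rejected"].sum() <= 1

    def test_uncorrelated_wedge_rejected(self, wilson_gt):
        poly = make_polymorphs(wilson_gt, 2, 0.0, seed=2)
        plan = WedgePlan(wedge_deg=10.0, dose_total=1e7, n0=2e-3, sigma_sys=0.0, bg_rate=0.0)
        main = simulate_wedges(make_polymorphs(wilson_gt, 1, 1.0, seed=2), 8, plan, seed=5)
        alien = simulate_wedges(
            make_polymorphs(poly.members[1], 1, 1.0, seed=2), 1, plan, seed=6,
            id_prefix="alien",
        )
        wedges = main + alien
        sm = fit_wedge_scales(wedges)
        kept, report = reject_outlier_wedges(wedges, sm, cc_min=0.8)
        assert report.loc[report["wedge_id"] == "alien0000", "rejected"].all()
        assert all(w.wedge_id != "alien0000" for w in kept)

    def test_cc_min_minus_one_rejects_nothing(self, clean_wedges):
        sm = fit_wedge_scales(clean_wedges)
        kept, report = reject_outlier_wedges(clean_wedges, sm, cc_min=-1.0)
        assert len(kept) == len(clean_wedges)


class TestMergingStats:
    def _toy_merged(self):
        """Three uniques with multiplicities 3/2/1 and hand-set values."""
        rows = {
            "code": [0, 0, 0, 1, 1, 2],
            "i_scaled": [10.0, 12.0, 8.0, 5.0, 7.0, 3.0],
            "sigma_scaled": [1.0] * 6,
            "wedge": [0, 1, 2, 0, 1, 0],
            "frame": [0] * 6,
            "s": [0.1] * 6,
            "d": [5.0] * 6,
            "kept": [True] * 6,
        }
        table = pd.DataFrame(
            {
                "kh": [1, 2, 3], "kk": [0, 0, 0], "kl": [0, 0, 0], "sign": [1, 1, 1],
                "s": [0.1] * 3, "d": [5.0] * 3,
                "i_mean": [10.0, 6.0, 3.0], "sigma_mean": [0.6, 0.7, 1.0],
                "n_obs": [3, 2, 1],
            }
        )
        return MergedDataset(table=table, anomalous=False, scaled_obs=pd.DataFrame(rows))

    def test_r_statistics_match_hand_formula(self):
        merged = self._toy_merged()
        stats = merging_stats(merged, 4)
        # direct formulas on uniques 0 (mean 10; devs 0,2,2) and 1 (mean 6; devs 1,1)
        denom = 10.0 + 12.0 + 8.0 + 5.0 + 7.0
        r_merge = 100 * (0 + 2 + 2 + 1 + 1) / denom
        r_meas = 100 * (
            (0 + 2 + 2) * np.sqrt(3 / 2) + (1 + 1) * np.sqrt(2 / 1)
        ) / denom
        r_pim = 100 * (
            (0 + 2 + 2) * np.sqrt(1 / 2) + (1 + 1) * np.sqrt(1 / 1)
        ) / denom
        assert stats["r_merge"] == pytest.approx(r_merge, abs=1e-12)
        assert stats["r_meas"] == pytest.approx(r_meas, abs=1e-12)
        assert stats["r_pim"] == pytest.approx(r_pim, abs=1e-12)
        assert stats["completeness"] == pytest.approx(75.0)
        assert stats["multiplicity"] == pytest.approx(2.0)

    def test_identical_duplicates_give_zero_r(self):
        merged = self._toy_merged()
        obs = merged.scaled_obs.copy()
        obs["i_scaled"] = obs["code"].map({0: 4.0, 1: 6.0, 2: 1.0})
        merged.scaled_obs = obs
        stats = merging_stats(merged, 3)
        assert stats["r_merge"] == 0 and stats["r_meas"] == 0 and stats["r_pim"] == 0

    def test_all_singletons_report_absent_r(self):
        merged = self._toy_merged()
        merged.scaled_obs = merged.scaled_obs.drop_duplicates("code")
        stats = merging_stats(merged, 3)
        assert stats["r_merge"] is None and stats["r_pim"] is None

    def test_r_pim_never_exceeds_r_merge(self, small_merged):
        merged, _ = small_merged
        stats = merging_stats(merged, 10**9)
        assert stats["r_pim"] <= stats["r_merge"]

    def test_full_observation_gives_full_completeness(self, wilson_gt, small_merged):
        merged, _ = small_merged
        stats = merging_stats(merged, merged.n_unique)
        assert stats["completeness"] == pytest.approx(100.0)
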