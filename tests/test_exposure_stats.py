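"""Log-moment statistics, worker fits, aggregation and variance components."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from endotwa import (CampaignSpec, TaskParams, aggregate_task_distribution,
                     censor_at_lod, default_campaign_spec,
                     fit_worker_distributions, generate_campaign,
                     geometric_stats, personal_area_gm_ratio, sampled_volume,
                     task_summary_table, variance_components)


def frame(task="latrine", **worker_samples):
    rows = []
    for wid, concs in worker_samples.items():
        for c in concs:
            rows.append(dict(worker_id=wid, task=task, sample_type="personal",
                             duration_min=60.0, flow_l_min=2.0,
                             endotoxin_eu=c * 0.12, concentration_eu_m3=c,
                             below_lod=False))
    cols = ["worker_id", "task", "sample_type", "duration_min", "flow_l_min",
            "endotoxin_eu", "concentration_eu_m3", "below_lod"]
    return pd.DataFrame(rows, columns=cols)


class TestSampledVolume:
    @pytest.mark.parametrize("flow,dur,vol", [
        (2.0, 100.0, 0.200),
        (1.0, 1000.0, 1.000),
        (3.5, 48.0, 0.168),
    ])
    def test_unit_conversion(self, flow, dur, vol):
        assert sampled_volume(flow, dur) == pytest.approx(vol)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError, match="flow"):
            sampled_volume(0.0, 100.0)
        with pytest.raises(ValueError, match="duration"):
            sampled_volume(2.0, -1.0)


class TestGeometricStats:
    def test_two_values(self):
        gm, gsd = geometric_stats([10.0, 100.0])
        assert gm == pytest.approx(math.sqrt(1000.0))
        assert gsd == pytest.approx(math.exp(abs(math.log(10) - math.log(100))
                                             / math.sqrt(2)))

    def test_constant_values(self):
        gm, gsd = geometric_stats([7.0, 7.0, 7.0])
        assert gm == pytest.approx(7.0)
        assert gsd == pytest.approx(1.0)

    def test_single_value_has_undefined_gsd(self):
        gm, gsd = geometric_stats([42.0])
        assert gm == pytest.approx(42.0)
        assert math.isnan(gsd)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="values"):
            geometric_stats([1.0, 0.0])

    @given(values=st.lists(st.floats(0.01, 1e4), min_size=2, max_size=20),
           k=st.floats(0.01, 100.0))
    def test_scale_equivariance(self, values, k):
        gm, gsd = geometric_stats(values)
        gm_k, gsd_k = geometric_stats([v * k for v in values])
        assert gm_k == pytest.approx(gm * k, rel=1e-9)
        assert gsd_k == pytest.approx(gsd, rel=1e-9)


class TestTaskSummaryTable:
    def test_row_structure_matches_campaign_design(self, campaign):
        t = task_summary_table(campaign)
        key = t.set_index(["sample_type", "task"])["n"]
        assert key[("area", "latrine")] == 20
        assert key[("personal", "latrine")] == 11
        assert key[("personal", "inlet")] == 2
        assert key[("personal", "mechanical_dewatering")] == 10
        assert key[("personal", "solar_dehydration")] == 10
        assert key[("personal", "thermal_drying")] == 9

    def test_am_gm_inequality_every_row(self, campaign):
        t = task_summary_table(campaign)
        assert (t["am"] >= t["gm"] - 1e-12).all()
        assert t["gm"].between(t["conc_min"], t["conc_max"]).all()

    def test_single_record(self):
        t = task_summary_table(frame(w1=[50.0]))
        assert len(t) == 1
        row = t.iloc[0]
        assert row["n"] == 1
        assert row["am"] == pytest.approx(50.0)
        assert row["gm"] == pytest.approx(row["am"])
        assert math.isnan(row["sd"]) and math.isnan(row["gsd"])

    def test_degenerate_gsd_makes_am_equal_gm(self):
        spec = CampaignSpec(tasks=(TaskParams(
            task="inlet", gm=11.0, gsd=1.0, n_workers=2, samples_per_worker=4,
            duration_range_min=(48.0, 101.0)),), seed=1)
        t = task_summary_table(generate_campaign(spec))
        assert t.iloc[0]["am"] == pytest.approx(t.iloc[0]["gm"])
        assert t.iloc[0]["gsd"] == pytest.approx(1.0)

    def test_empty_input_gives_empty_table(self):
        t = task_summary_table(pd.DataFrame(columns=frame().columns))
        assert len(t) == 0


class TestWorkerFits:
    def test_log_moments_of_one_worker(self):
        fits = fit_worker_distributions(
            frame(w1=[math.e ** 2, math.e ** 4], w2=[1.0, 1.0]))
        w1 = fits.set_index("worker_id").loc["w1"]
        assert w1["mu_log"] == pytest.approx(3.0)
        assert w1["sigma_log"] == pytest.approx(math.sqrt(2.0))

    def test_constant_workers(self):
        fits = fit_worker_distributions(frame(w1=[5.0, 5.0], w2=[5.0, 5.0]))
        assert np.allclose(fits["mu_log"], math.log(5.0))
        assert np.allclose(fits["sigma_log"], 0.0)

    def test_between_fraction_one_gives_zero_within_spread(self):
        spec = CampaignSpec(tasks=(TaskParams(
            task="latrine", gm=75.0, gsd=2.4, between_fraction=1.0,
            n_workers=4, samples_per_worker=5,
            duration_range_min=(73.0, 251.0)),), seed=2)
        fits = fit_worker_distributions(generate_campaign(spec))
        assert (fits["sigma_log"].abs() < 1e-12).all()

    def test_singleton_worker_gets_pooled_sigma(self):
        fits = fit_worker_distributions(
            frame(w1=[math.e, math.e ** 3], w2=[10.0]))
        by = fits.set_index("worker_id")
        assert by.loc["w2", "sigma_imputed"]
        assert by.loc["w2", "sigma_log"] == pytest.approx(
            by.loc["w1", "sigma_log"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="records"):
            fit_worker_distributions(frame())


class TestAggregation:
    def test_single_worker_identity(self):
        d = aggregate_task_distribution([(1.5, 0.4)], task="inlet")
        assert d.mu_log == pytest.approx(1.5)
        assert d.sigma_log == pytest.approx(0.4)

    def test_two_point_workers(self):
        d = aggregate_task_distribution([(0.0, 0.0), (2.0, 0.0)])
        assert d.mu_log == pytest.approx(1.0)
        assert d.sigma_log ** 2 == pytest.approx(2.0)

    def test_aggregate_median_matches_mixture_median(self):
        """Brute-force oracle: sample the equal-weight worker mixture."""
        spec = CampaignSpec(tasks=(TaskParams(
            task="latrine", gm=75.0, gsd=2.0, between_fraction=0.3,
            n_workers=5, samples_per_worker=8,
            duration_range_min=(73.0, 251.0)),), seed=11)
        fits = fit_worker_distributions(generate_campaign(spec))
        agg = aggregate_task_distribution(fits)
        rng = np.random.default_rng(0)
        idx = rng.integers(0, len(fits), 100_000)
        mix = rng.lognormal(fits["mu_log"].to_numpy()[idx],
                            fits["sigma_log"].to_numpy()[idx])
        assert agg.gm == pytest.approx(np.median(mix), rel=0.10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="worker"):
            aggregate_task_distribution([])


class TestVarianceComponents:
    def test_constant_data_has_zero_components(self):
        vc = variance_components(frame(w1=[3.0, 3.0], w2=[3.0, 3.0]))
        assert vc.sigma2_between == 0.0
        assert vc.sigma2_within == 0.0

    def test_hand_anova_two_workers(self):
        # ln concentrations {0,0} and {2,2}: MSB=4, MSW=0, n0=2 -> between=2
        vc = variance_components(
            frame(w1=[1.0, 1.0], w2=[math.e ** 2, math.e ** 2]))
        assert vc.sigma2_within == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma2_between == pytest.approx(2.0)

    def test_unbalanced_against_direct_formula(self):
        df = frame(w1=[1.0, 2.0], w2=[3.0, 5.0, 8.0], w3=[0.5, 0.7, 0.9, 2.0])
        vc = variance_components(df)
        # independent recomputation from sums of squares
        logs = [np.log(np.array(v)) for v in
                ([1.0, 2.0], [3.0, 5.0, 8.0], [0.5, 0.7, 0.9, 2.0])]
        n = np.array([2, 3, 4])
        grand = np.mean(np.concatenate(logs))
        msb = sum(ni * (g.mean() - grand) ** 2
                  for ni, g in zip(n, logs)) / 2
        msw = sum(((g - g.mean()) ** 2).sum() for g in logs) / 6
        n0 = (9 - (n ** 2).sum() / 9) / 2
        assert vc.sigma2_within == pytest.approx(msw)
        assert vc.sigma2_between == pytest.approx(max(0.0, (msb - msw) / n0))

    def test_balanced_total_identity(self):
        """For balanced data the components reassemble the mean squares."""
        spec = CampaignSpec(tasks=(TaskParams(
            task="latrine", gm=75.0, gsd=2.4, n_workers=6,
            samples_per_worker=4, duration_range_min=(73.0, 251.0)),), seed=9)
        df = generate_campaign(spec)
        vc = variance_components(df)
        logs = np.log(df["concentration_eu_m3"].to_numpy())
        means = df.assign(l=logs).groupby("worker_id")["l"].mean()
        msb = 4 * means.var(ddof=1)
        msw = (df.assign(l=logs).groupby("worker_id")["l"].var(ddof=1)).mean()
        assert vc.sigma2_between + vc.sigma2_within == pytest.approx(
            msb / 4 + msw * 3 / 4)

    def test_matches_mixedlm_on_balanced_design(self):
        """Independent oracle: REML equals ANOVA for balanced one-way data."""
        import statsmodels.formula.api as smf
        spec = CampaignSpec(tasks=(TaskParams(
            task="latrine", gm=75.0, gsd=2.4, between_fraction=0.5,
            n_workers=8, samples_per_worker=6,
            duration_range_min=(73.0, 251.0)),), seed=4)
        df = generate_campaign(spec)
        vc = variance_components(df)
        df["y"] = np.log(df["concentration_eu_m3"])
        fit = smf.mixedlm("y ~ 1", df, groups=df["worker_id"]).fit(reml=True)
        assert vc.sigma2_between == pytest.approx(
            float(fit.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6)
        assert vc.sigma2_within == pytest.approx(float(fit.scale), rel=1e-3)

    def test_recovers_between_fraction(self):
        """Mean recovered split over replicate campaigns at the design size."""
        estimates = []
        for seed in range(20):
            spec = CampaignSpec(tasks=(TaskParams(
                task="latrine", gm=75.0, gsd=2.0, between_fraction=0.3,
                n_workers=10, samples_per_worker=50,
                duration_range_min=(73.0, 251.0)),), seed=seed)
            vc = variance_components(generate_campaign(spec))
            estimates.append(vc.sigma2_between / vc.sigma2_total)
        assert np.mean(estimates) == pytest.approx(0.3, abs=0.1)

    def test_single_worker_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            variance_components(frame(w1=[1.0, 2.0, 3.0]))


class TestPersonalAreaRatio:
    def test_ratio_concentrates_near_six_fold(self):
        """Personal latrine GM is ~6.25x the area GM at the design sizes;
        averaged over replicate campaigns the ratio pins down tightly."""
        log_ratios = []
        for seed in range(200):
            spec = default_campaign_spec(seed=seed)
            df = censor_at_lod(generate_campaign(spec), spec)
            log_ratios.append(math.log(personal_area_gm_ratio(df, "latrine")))
        assert math.exp(np.mean(log_ratios)) == pytest.approx(75 / 12, rel=0.2)

    def test_requires_both_sample_types(self):
        with pytest.raises(ValueError, match="task"):
            personal_area_gm_ratio(frame(w1=[1.0]), "latrine")
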