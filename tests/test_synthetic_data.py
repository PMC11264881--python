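"""Generator contracts: matching calipers, confounder structure, censoring,
planted effects, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neometab import synthetic_data as sd
from neometab.io_model import ConfigError, records_to_frame, write_feature_table
from neometab.association import auc_single


def test_shift_calibration_identity():
    # d*sqrt(1 + d^2/4) must equal ln(OR) by construction
    for orr in (1.1, 1.7, 2.5, 0.6):
        d = sd.shift_for_or(orr)
        assert d * math.sqrt(1 + d * d / 4) == pytest.approx(math.log(orr), abs=1e-12)


def test_shift_induces_target_logistic_coefficient():
    """Gaussian-shift construction yields the planted per-pooled-SD log-OR.

    Independent oracle: a plain logistic ML fit on a large balanced sample of
    the standardized mixture.
    """
    import statsmodels.api as sm

    rng = np.random.default_rng(5)
    n = 200_000
    d = sd.shift_for_or(1.7)
    y = np.repeat([1.0, 0.0], n // 2)
    x = rng.normal(size=n) + d * y
    x = (x - x.mean()) / x.std(ddof=1)
    fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    assert fit.params[1] == pytest.approx(math.log(1.7), abs=0.02)


class TestNeonatalCohort:
    def test_pairs_matched_within_calipers(self):
        cfg = sd.SimConfig(n_pairs=200, n_features=5, seed=1)
        records, _ = sd.generate_neonatal_cohort(cfg)
        df = records_to_frame(records)
        assert len(records) == 400
        for pair_id, grp in df.groupby("pair_id"):
            assert set(grp["group"]) == {"case", "control"}
            ga = grp["gestational_age"]
            assert abs(ga.iloc[0] - ga.iloc[1]) <= 4 / 7 + 1e-9  # 4 days in weeks
            aas = grp["age_at_sampling"]
            assert abs(aas.iloc[0] - aas.iloc[1]) <= 1.0 + 1e-9
        assert df["gestational_age"].between(34, 42).all()
        assert df["age_at_sampling"].between(3, 8).all()

    def test_family_history_rates(self):
        cfg = sd.SimConfig(n_pairs=739, n_features=5, seed=7)
        records, _ = sd.generate_neonatal_cohort(cfg)
        df = records_to_frame(records)
        n_case_fh = df.loc[df.group == "case", "family_history"].sum()
        n_ctrl_fh = df.loc[df.group == "control", "family_history"].sum()
        # binomial means 221.7 and 138.2 with SD ~12.5 / ~10.6
        assert abs(n_case_fh - 739 * 0.300) < 4 * math.sqrt(739 * 0.3 * 0.7)
        assert abs(n_ctrl_fh - 739 * 0.187) < 4 * math.sqrt(739 * 0.187 * 0.813)

    def test_prs_auc_matches_binormal_target(self):
        cfg = sd.SimConfig(n_pairs=5000, n_features=5, seed=3)
        records, _ = sd.generate_neonatal_cohort(cfg)
        df = records_to_frame(records)
        auc = auc_single(df["prs"], df["y"])
        assert 0.56 <= auc <= 0.60

    def test_prs_symmetric_when_auc_half(self):
        cfg = sd.SimConfig(n_pairs=2000, n_features=5, prs_auc=0.5, seed=3)
        records, _ = sd.generate_neonatal_cohort(cfg)
        df = records_to_frame(records)
        t = stats.ttest_ind(df.loc[df.y == 1, "prs"], df.loc[df.y == 0, "prs"])
        assert t.pvalue > 0.001

    def test_invalid_rates_rejected(self):
        with pytest.raises(ConfigError):
            sd.SimConfig(fh_rate_case=1.5)
        with pytest.raises(ConfigError):
            sd.SimConfig(n_pairs=1)

    def test_seasons_follow_month_rule(self):
        cfg = sd.SimConfig(n_pairs=100, n_features=2, seed=9)
        records, _ = sd.generate_neonatal_cohort(cfg)
        assert {r.season for r in records} <= {"winter", "spring", "summer", "autumn"}
        # cases only get a diagnosis age
        for r in records:
            if r.group == "control":
                assert math.isnan(r.age_at_diagnosis)
            else:
                assert 1.0 <= r.age_at_diagnosis <= 10.0


class TestFeatureMatrix:
    def test_same_seed_identical_output(self, tmp_path):
        outs = []
        for _ in range(2):
            cfg = sd.SimConfig(n_pairs=30, n_features=15, n_plates=2, seed=11)
            records, truth = sd.generate_neonatal_cohort(cfg)
            table = sd.generate_feature_matrix(records, truth, cfg)
            write_feature_table(table, tmp_path / "t.tsv", tmp_path / "m.tsv")
            outs.append((tmp_path / "t.tsv").read_bytes())
        assert outs[0] == outs[1]

    def test_no_structure_means_complete_matrix(self):
        cfg = sd.SimConfig(
            n_pairs=40, n_features=10, n_plates=2, drift_amplitude=0.0, batch_sd=0.0,
            presence_targets={f"F{j + 1:04d}": 1.0 for j in range(10)},
            signal_features=[], seed=2,
        )
        records, truth = sd.generate_neonatal_cohort(cfg)
        table = sd.generate_feature_matrix(records, truth, cfg)
        assert not table.missing_mask.to_numpy().any()

    def test_presence_target_recovered(self):
        cfg = sd.SimConfig(
            n_pairs=500, n_features=3, n_plates=4,
            presence_targets={"F0001": 0.20, "F0002": 0.60, "F0003": 0.95},
            signal_features=[], seed=4,
        )
        records, truth = sd.generate_neonatal_cohort(cfg)
        table = sd.generate_feature_matrix(records, truth, cfg)
        analytical = table.analytical()
        frac = analytical.intensities.notna().mean()
        assert 0.16 <= frac["F0001"] <= 0.24  # binomial 99% band at n=1000
        assert 0.55 <= frac["F0002"] <= 0.65
        assert frac["F0003"] >= 0.90

    def test_binary_signal_presence_odds(self):
        cfg = sd.SimConfig(
            n_pairs=4000, n_features=3, n_plates=4,
            signal_features=[sd.SignalFeature("F0002", "binary", 2.0)], seed=8,
        )
        records, truth = sd.generate_neonatal_cohort(cfg)
        table = sd.generate_feature_matrix(records, truth, cfg)
        analytical = table.analytical()
        df = records_to_frame(records).loc[analytical.sample_ids]
        present = analytical.intensities["F0002"].notna()
        a = (present & (df.group == "case")).sum()
        b = (~present & (df.group == "case")).sum()
        c = (present & (df.group == "control")).sum()
        d = (~present & (df.group == "control")).sum()
        orr = (a * d) / (b * c)
        assert orr == pytest.approx(2.0, rel=0.25)

    def test_qc_rows_have_only_technical_noise(self):
        cfg = sd.SimConfig(n_pairs=60, n_features=10, n_plates=2,
                           drift_amplitude=0.0, batch_sd=0.0, seed=6)
        records, truth = sd.generate_neonatal_cohort(cfg)
        table = sd.generate_feature_matrix(records, truth, cfg)
        qc = table.qc_rows(("plate_pool",))
        cv = np.log(qc.intensities).std(ddof=1)
        assert (cv < 2.5 * cfg.analytical_cv).all()


class TestAdultCohort:
    def test_null_scan_calibrated(self):
        from neometab.genetics_scan import gwas_scan, lambda_gc

        cohort = sd.generate_adult_cohort(n=1500, n_snps=5000, seed=0)
        res = gwas_scan(cohort.genotypes, cohort.metabolite,
                        cohort.phenotypes[["age", "sex"]])
        assert 0.9 <= lambda_gc(res["P"]) <= 1.1
        ks = stats.kstest(res["P"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_snp_variance(self):
        cohort = sd.generate_adult_cohort(
            n=3409, n_snps=20, causal=[("rs000001", 0.024)], seed=1
        )
        g = cohort.genotypes["rs000001"]
        r2 = np.corrcoef(g, cohort.metabolite)[0, 1] ** 2
        assert r2 == pytest.approx(0.024, abs=0.012)

    def test_diet_corr_target(self):
        from neometab.enrichment_network import partial_spearman

        cohort = sd.generate_adult_cohort(n=3714, n_snps=5, diet_corr=0.18, seed=2)
        rho, p = partial_spearman(
            cohort.metabolite, cohort.phenotypes["dairy"],
            cohort.phenotypes[["age", "sex", "bmi"]],
        )
        assert 0.14 <= rho <= 0.22
        assert p < 1e-6

    def test_total_variance_guard(self):
        with pytest.raises(ConfigError):
            sd.generate_adult_cohort(n=100, n_snps=30,
                                     causal=[(f"rs{j + 1:06d}", 0.05) for j in range(21)])
        with pytest.raises(ConfigError):
            sd.generate_adult_cohort(n=100, n_snps=5, causal=[("rs000001", 0.2)])
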