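"""Heterogeneity, MR-PRESSO and leave-one-out diagnostics."""

import numpy as np
import pytest

from mrlink.estimators import ivw
from mrlink.sensitivity import (
    cochran_q,
    egger_intercept_test,
    leave_one_out,
    mr_presso,
    remove_outliers_until_clean,
    sensitivity_report,
)
from mrlink.synthetic_gwas import SimulationConfig, simulate_two_sample
from mrlink.harmonize import harmonize

from conftest import make_dataset


def _spiked(seed=0, k=50, effect=0.05, n_out=1):
    cfg = SimulationConfig(n_snps=k, seed=seed, n_outliers=n_out, outlier_effect=effect)
    ex, out, truth = simulate_two_sample(cfg)
    return harmonize(ex, out), {f"rs{i + 1}" for i in truth.outlier_indices}


class TestCochranQ:
    def test_hand_arithmetic(self):
        d = make_dataset([1.0, 1.0], [1.0, 3.0], [1.0, 1.0])
        q, df, p = cochran_q(d, beta_ivw=2.0)
        assert q == pytest.approx(2.0)
        assert df == 1

    def test_identical_ratios_give_zero_q(self):
        d = make_dataset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.01, 0.01, 0.01])
        q, _, p = cochran_q(d)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_q_equals_weighted_rss_identity(self, random_dataset):
        """Q on the ratio scale equals the IVW-residual RSS identically."""
        d = random_dataset(k=30, seed=4)
        beta = ivw(d, mode="fixed").beta
        q, _, _ = cochran_q(d, beta)
        rss = np.sum((d.Gamma - beta * d.gamma) ** 2 / d.se_Gamma**2)
        assert q == pytest.approx(rss, rel=1e-12)

    def test_homogeneous_calibration(self):
        """Under homogeneity E[Q/(k-1)] ≈ 1 over replicates."""
        ratios = []
        for s in range(100):
            cfg = SimulationConfig(n_snps=60, seed=s)
            ex, out, _ = simulate_two_sample(cfg)
            q, df, _ = cochran_q(harmonize(ex, out))
            ratios.append(q / df)
        mean = np.mean(ratios)
        mc_se = np.std(ratios, ddof=1) / 10
        assert abs(mean - 1.0) < 3 * mc_se

    def test_fewer_than_two_snps_rejected(self):
        with pytest.raises(ValueError):
            cochran_q(make_dataset([1.0], [1.0], [1.0]))


class TestMRPresso:
    def test_spiked_snp_flagged_and_seed_stable(self):
        d, spiked = _spiked(seed=3)
        a = mr_presso(d, n_sim=1000, seed=11)
        b = mr_presso(d, n_sim=1000, seed=11)
        assert set(d.variant_ids[a.outlier_indices]) >= spiked
        assert list(a.outlier_indices) == list(b.outlier_indices)
        assert a.global_pval == b.global_pval

    def test_clean_data_rarely_flags(self):
        n_flagged = 0
        for s in range(20):
            cfg = SimulationConfig(n_snps=50, seed=s)
            ex, out, _ = simulate_two_sample(cfg)
            pr = mr_presso(harmonize(ex, out), n_sim=1000, seed=s)
            n_flagged += len(pr.outlier_indices) > 0
        assert n_flagged <= 1

    def test_global_pval_bounds_and_monotonicity(self):
        """p in [1/(n+1), 1]; larger outliers give no larger global p."""
        pvals = []
        for effect in (0.0, 0.02, 0.08):
            d, _ = _spiked(seed=5, effect=effect, n_out=1 if effect else 0)
            pr = mr_presso(d, n_sim=500, seed=9)
            assert 1 / 501 <= pr.global_pval <= 1.0
            pvals.append(pr.global_pval)
        assert pvals[0] >= pvals[1] >= pvals[2]

    def test_distortion_pval_present_with_outliers(self):
        d, _ = _spiked(seed=7)
        pr = mr_presso(d, n_sim=1000, seed=1)
        assert len(pr.outlier_indices) >= 1
        assert 0 < pr.distortion_pval <= 1

    def test_preconditions(self):
        d = make_dataset([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            mr_presso(d)  # < 4 SNPs
        d4, _ = _spiked(seed=0, k=10)
        with pytest.raises(ValueError):
            mr_presso(d4, n_sim=0)


class TestOutlierLoop:
    def test_clean_data_unchanged(self):
        cfg = SimulationConfig(n_snps=40, seed=17)
        ex, out, _ = simulate_two_sample(cfg)
        d = harmonize(ex, out)
        clean, log = remove_outliers_until_clean(d, seed=1)
        assert clean.n_snp == d.n_snp
        assert log.status in ("clean", "no-outliers-flagged")
        assert log.removed_ids == []

    def test_loop_only_removes_flagged_snps(self):
        d, _ = _spiked(seed=19, n_out=2)
        clean, log = remove_outliers_until_clean(d, n_sim=1000, seed=2)
        total_flagged = sum(r["n_flagged"] for r in log.rounds)
        assert len(log.removed_ids) <= total_flagged
        assert clean.n_snp == d.n_snp - len(log.removed_ids)

    def test_terminates_on_max_rounds(self):
        # adversarial: strong directional pleiotropy on every SNP
        rng = np.random.default_rng(23)
        k = 20
        gamma = rng.uniform(0.05, 0.15, k)
        Gamma = 0.1 * gamma + rng.uniform(0.01, 0.05, k)
        d = make_dataset(gamma, Gamma, np.full(k, 0.002))
        clean, log = remove_outliers_until_clean(d, max_rounds=2, n_sim=500, seed=3)
        assert len(log.rounds) <= 2  # terminates within the round budget

    def test_shrinking_below_minimum_stops_with_warning_state(self):
        d = make_dataset([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        clean, log = remove_outliers_until_clean(d, seed=4)
        assert log.status == "too-few-snps"


class TestLeaveOneOut:
    def test_three_snps_each_estimate_uses_other_two(self):
        d = make_dataset([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        loo = leave_one_out(d, mode="fixed")
        assert len(loo) == 3
        # dropping rs1 leaves ratios {2, 3} with equal weights -> IVW 2.5
        assert loo.loc[loo["SNP"] == "rs1", "beta"].iloc[0] == pytest.approx(2.5)
        assert loo.loc[loo["SNP"] == "rs3", "beta"].iloc[0] == pytest.approx(1.5)

    def test_negligible_weight_snp_changes_nothing(self, random_dataset):
        d = random_dataset(k=10, seed=31)
        d.se_Gamma[0] = 1e6  # ~zero weight
        loo = leave_one_out(d, mode="fixed")
        full = ivw(d, mode="fixed").beta
        assert loo.loc[0, "beta"] == pytest.approx(full, rel=1e-6)

    def test_loo_spread_shrinks_with_k(self):
        spreads = []
        for k in (10, 50, 200):
            per_seed = []
            for s in range(8):
                cfg = SimulationConfig(n_snps=k, seed=41 + s)
                ex, out, _ = simulate_two_sample(cfg)
                loo = leave_one_out(harmonize(ex, out), mode="fixed")
                per_seed.append(loo["beta"].max() - loo["beta"].min())
            spreads.append(np.mean(per_seed))
        assert spreads[0] > spreads[1] > spreads[2]


def test_sensitivity_report_assembles_consistently(random_dataset):
    d = random_dataset(k=20, seed=51)
    rep = sensitivity_report(d, n_sim=200, seed=0)
    assert rep.q_df == d.n_snp - 1
    assert len(rep.loo) == d.n_snp
    i, se, p = egger_intercept_test(d)
    assert rep.egger_intercept == pytest.approx(i)
    assert rep.intercept_pval == pytest.approx(p)
    assert rep.mre_recommended == (rep.q_pval < 0.05)
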