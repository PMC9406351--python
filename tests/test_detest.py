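import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import radskin as rs
from radskin.detest import (
    DEThresholds,
    ModerationParams,
    estimate_moderation,
    flag_sdtgs,
    signed_fc,
)
from radskin.errors import ConfigError

from conftest import two_group_matrix


# ---- fold change -------------------------------------------------------------


@pytest.mark.parametrize(
    "log2fc,fc",
    [
        (math.log2(2.41), 2.41),  # worked example: 2.41-fold upregulation
        (0.0, 1.0),
        (-1.0, -2.0),
        (1.0, 2.0),
        (-math.log2(7.09), -7.09),
    ],
)
def test_fold_change_examples(log2fc, fc):
    lfc, sfc = rs.fold_change(log2fc, 0.0)
    assert lfc == pytest.approx(log2fc)
    assert sfc == pytest.approx(fc)
    assert abs(sfc) >= 1.0


def test_fold_change_sign_symmetry():
    # antisymmetric away from 0 (equal means give FC +1 by convention)
    for lfc in np.linspace(0.1, 5, 20):
        assert signed_fc(lfc) == pytest.approx(-signed_fc(-lfc))
        assert abs(signed_fc(lfc)) >= 1.0


# ---- moderated t -------------------------------------------------------------


def test_d0_zero_equals_ordinary_pooled_t():
    m = two_group_matrix(n_genes=150, shift=np.linspace(-2, 2, 30), seed=10)
    res = rs.moderated_t_contrast(m, 1.0, "2h", params=ModerationParams(0.0, 1.0))
    exposed = m.group_values(1.0, "2h").to_numpy()
    control = m.group_values(0.0, "2h").to_numpy()
    t_ref, p_ref = stats.ttest_ind(exposed, control, axis=1, equal_var=True)
    np.testing.assert_allclose(res.table["t_mod"].to_numpy(), t_ref, atol=1e-10)
    np.testing.assert_allclose(res.table["p_raw"].to_numpy(), p_ref, atol=1e-10)


def test_full_shrinkage_limit_uses_prior_variance():
    m = two_group_matrix(n_genes=80, seed=11)
    s0_sq = 0.04
    res = rs.moderated_t_contrast(
        m, 1.0, "2h", params=ModerationParams(np.inf, s0_sq)
    )
    lfc = res.table["log2fc"].to_numpy()
    se = math.sqrt(s0_sq * (2 / 5))
    np.testing.assert_allclose(res.table["t_mod"].to_numpy(), lfc / se, atol=1e-10)


def test_posterior_variance_between_prior_and_sample():
    params = ModerationParams(4.0, 0.05)
    s_sq = np.array([0.01, 0.05, 0.4])
    post = params.posterior_variance(s_sq, dg=8.0)
    lo = np.minimum(s_sq, params.s0_sq)
    hi = np.maximum(s_sq, params.s0_sq)
    assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)


def test_moderation_estimator_recovers_prior():
    # variances drawn from scaled-inv-chi2(d0=4, s0^2=0.0625) with dg=8
    rng = np.random.default_rng(12)
    n, dg, d0, s0_sq = 20_000, 8, 4.0, 0.0625
    sigma2 = d0 * s0_sq / rng.chisquare(d0, n)
    s_sq = sigma2 * rng.chisquare(dg, n) / dg
    params = estimate_moderation(s_sq, dg)
    assert params.d0 == pytest.approx(d0, rel=0.15)
    assert params.s0_sq == pytest.approx(s0_sq, rel=0.1)


def test_matches_limma_oracle(tmp_path):
    """Independent cross-check against the canonical eBayes implementation."""
    m = two_group_matrix(n_genes=250, shift=np.linspace(-2, 2, 40), seed=13)
    res = rs.moderated_t_contrast(m, 1.0, "2h")
    m.values.to_csv(tmp_path / "fixture.csv")
    script = tmp_path / "check.R"
    script.write_text(
        """
suppressMessages(library(limma))
args <- commandArgs(trailingOnly=TRUE)
x <- as.matrix(read.csv(args[1], row.names=1))
design <- cbind(Intercept=1, dose=c(rep(1,5), rep(0,5)))
fit <- eBayes(lmFit(x, design))
out <- data.frame(logFC=fit$coefficients[,"dose"], t=fit$t[,"dose"],
                  p=fit$p.value[,"dose"], d0=fit$df.prior, s0sq=fit$s2.prior)
write.csv(out, args[2], row.names=FALSE)
"""
    )
    subprocess.run(
        ["Rscript", str(script), str(tmp_path / "fixture.csv"), str(tmp_path / "out.csv")],
        check=True,
        capture_output=True,
    )
    ref = pd.read_csv(tmp_path / "out.csv")
    np.testing.assert_allclose(res.table["log2fc"], ref["logFC"], atol=1e-8)
    np.testing.assert_allclose(res.table["t_mod"], ref["t"], atol=1e-6)
    np.testing.assert_allclose(res.table["p_raw"], ref["p"], atol=1e-8)
    assert res.params.d0 == pytest.approx(ref["d0"][0], rel=1e-4)
    assert res.params.s0_sq == pytest.approx(ref["s0sq"][0], rel=1e-4)


def test_null_simulation_p_values_calibrated():
    # pooled over two independent null experiments: P(p_raw < 0.05) within
    # 3 binomial SEs of 0.05
    fracs, n_tot = [], 0
    for seed in (3, 17):
        matrix, _ = rs.simulate_experiment(rs.null_preset(n_genes=20_000, seed=seed))
        res = rs.moderated_t_contrast(matrix, 1.0, "2h")
        fracs.append((res.table["p_raw"] < 0.05).mean())
        n_tot += len(res.table)
    frac = float(np.mean(fracs))
    se = math.sqrt(0.05 * 0.95 / n_tot)
    assert abs(frac - 0.05) < 3 * se


def test_group_absent_is_explicit(small_experiment):
    matrix, _ = small_experiment
    res = rs.moderated_t_contrast(matrix, 20.0, "d21")
    assert res.group_absent
    assert res.table is None
    with pytest.raises(rs.GroupAbsentError):
        rs.call_sdtgs(res)


# ---- BH adjustment and SDTG calling -----------------------------------------


def test_bh_monotone_and_dominates_raw(small_experiment):
    matrix, _ = small_experiment
    res = rs.moderated_t_contrast(matrix, 6.0, "d7")
    tab = res.table.sort_values("p_raw")
    assert (tab["p_adj"].to_numpy() >= tab["p_raw"].to_numpy() - 1e-15).all()
    # BH-adjusted p is non-decreasing in raw-p rank
    assert (np.diff(tab["p_adj"].to_numpy()) >= -1e-15).all()


def test_all_padj_one_gives_empty_set():
    m = two_group_matrix(n_genes=50, sigma=1.0, seed=14)
    res = rs.moderated_t_contrast(m, 1.0, "2h")
    res.table["p_adj"] = 1.0
    s = rs.call_sdtgs(res)
    assert s.total == 0
    assert s.percent_up is None


def test_sdtg_set_shrinks_as_thresholds_tighten(small_experiment):
    matrix, _ = small_experiment
    res = rs.moderated_t_contrast(matrix, 20.0, "2h")
    loose = rs.call_sdtgs(res, DEThresholds(p_adj_max=0.1, fc_min=1.5))
    mid = rs.call_sdtgs(res, DEThresholds(p_adj_max=0.05, fc_min=2.0))
    tight = rs.call_sdtgs(res, DEThresholds(p_adj_max=0.01, fc_min=3.5))
    assert tight.genes <= mid.genes <= loose.genes


def test_threshold_validation():
    with pytest.raises(ConfigError):
        DEThresholds(p_adj_max=0.0)
    with pytest.raises(ConfigError):
        DEThresholds(fc_min=0.5)


def test_planted_recovery_at_study_conditions(small_experiment):
    """Sensitivity >= 0.8 and empirical FDR <= 0.10 at BH 0.05 + |FC| >= 2."""
    matrix, truth = small_experiment
    sens, fdr = [], []
    for dose, tp in ((1.0, "d4"), (6.0, "d7"), (20.0, "2h")):
        res = rs.moderated_t_contrast(matrix, dose, tp)
        called = rs.call_sdtgs(res).genes
        planted = truth.planted_probe_ids(dose, tp)
        sens.append(len(called & planted) / len(planted))
        fdr.append(len(called - planted) / max(len(called), 1))
    assert min(sens) >= 0.8
    assert max(fdr) <= 0.10


def test_near_zero_noise_recovers_everything():
    # planted effects just above the 2-fold cutoff (|log2FC| exactly 1 sits
    # on the threshold, where symmetric noise makes >= a coin flip)
    cfg = rs.study_preset(n_genes=6000, doses=(1.0,), seed=15)
    cfg.lfc_range = (1.1, 1.1)
    cfg.variance_prior = (1e6, 1e-10)  # s0 -> 0
    matrix, truth = rs.simulate_experiment(cfg)
    res = rs.moderated_t_contrast(matrix, 1.0, "d4")
    called = rs.call_sdtgs(res).genes
    planted = truth.planted_probe_ids(1.0, "d4")
    assert len(called & planted) / len(planted) >= 0.99


def test_flag_sdtgs_raw_p_mode(small_experiment):
    matrix, _ = small_experiment
    tab = rs.moderated_t_contrast(matrix, 1.0, "2h").table
    raw = flag_sdtgs(tab, DEThresholds(use_raw_p=True))
    adj = flag_sdtgs(tab, DEThresholds())
    assert adj.sum() <= raw.sum()  # BH can only be more conservative
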