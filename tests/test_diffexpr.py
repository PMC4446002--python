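"""Moderated-t estimator, selection rules and pH-response classification.

The empirical-Bayes fit is checked against an independent brute-force
implementation of the moment equations (bisection on the trigamma, written
here from the marginal-distribution identities) and against the reference
linear-modelling package in R on a shared fixture.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from phregulon.diffexpr import (
    Contrast,
    SelectionThresholds,
    classify_ph_response,
    fit_contrast,
    fit_variance_prior,
    moderated_t,
    select_de,
    trigamma_inverse,
)


# ---------------------------------------------------------------------------
# independent oracle: moment equations solved by log-scale bisection
# ---------------------------------------------------------------------------

def _oracle_prior(s2, df):
    z = np.log(np.asarray(s2, dtype=float))
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    lo, hi = 1e-6, 1e6  # trigamma is strictly decreasing on (0, inf)
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid) > evar:
            lo = mid
        else:
            hi = mid
    d0 = 2 * np.sqrt(lo * hi)
    s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_2


@pytest.fixture(scope="module")
def fixture_3v3():
    """50-gene two-group fixture with gene-specific variances (seed 11)."""
    rng = np.random.default_rng(11)
    n, reps = 50, 3
    sd = np.sqrt(4 * 0.3**2 / rng.chisquare(4, size=n))  # heavy-tailed variances
    a = rng.normal(0, 1, (n, reps)) * sd[:, None]
    b = rng.normal(0, 1, (n, reps)) * sd[:, None] + rng.normal(0, 0.5, (n, 1))
    return a, b


def _pooled(a, b):
    df = a.shape[1] + b.shape[1] - 2
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(1, keepdims=True)) ** 2).sum(1) + (
        (b - b.mean(1, keepdims=True)) ** 2
    ).sum(1)
    return log2fc, ss / df, df


def test_prior_fit_matches_bruteforce_oracle(fixture_3v3):
    a, b = fixture_3v3
    _, s2, df = _pooled(a, b)
    d0, s0_2 = fit_variance_prior(s2, df)
    d0_o, s0_o = _oracle_prior(s2, df)
    assert np.isfinite(d0)
    assert d0 == pytest.approx(d0_o, rel=1e-6)
    assert s0_2 == pytest.approx(s0_o, rel=1e-8)


def test_moderated_t_matches_oracle_statistics(fixture_3v3):
    a, b = fixture_3v3
    log2fc, s2, df = _pooled(a, b)
    res = moderated_t(log2fc, s2, df, np.sqrt(2 / 3))
    d0, s0_2 = _oracle_prior(s2, df)
    s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    t_expect = log2fc / (np.sqrt(s2_post) * np.sqrt(2 / 3))
    p_expect = 2 * stats.t.sf(np.abs(t_expect), d0 + df)
    np.testing.assert_allclose(res["t_mod"], t_expect, rtol=1e-8)
    np.testing.assert_allclose(res["p"], p_expect, rtol=1e-8)


def test_zero_prior_df_recovers_classical_t(fixture_3v3):
    a, b = fixture_3v3
    log2fc, s2, df = _pooled(a, b)
    res = moderated_t(log2fc, s2, df, np.sqrt(2 / 3), d0=0.0, s0_2=1.0)
    t_classic = stats.ttest_ind(a, b, axis=1).statistic
    np.testing.assert_allclose(res["t_mod"], t_classic, atol=1e-10)


def test_identical_groups_give_null_result():
    a = np.tile([[1.0, 2.0, 3.0]], (5, 1))
    rng = np.random.default_rng(0)
    a = a + rng.normal(0, 0.1, a.shape)
    res = moderated_t(np.zeros(5), _pooled(a, a)[1], 4, np.sqrt(2 / 3))
    assert (res["t_mod"] == 0).all()
    assert (res["p"] == 1.0).all()


def test_shrinkage_is_convex_combination(fixture_3v3):
    a, b = fixture_3v3
    _, s2, df = _pooled(a, b)
    d0, s0_2 = fit_variance_prior(s2, df)
    s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    lo = np.minimum(s2, s0_2)
    hi = np.maximum(s2, s0_2)
    assert ((s2_post >= lo - 1e-12) & (s2_post <= hi + 1e-12)).all()


def test_trigamma_inverse_is_inverse():
    for x in (0.1, 1.0, 7.3, 150.0):
        assert trigamma_inverse(float(special.polygamma(1, x))) == pytest.approx(x, rel=1e-8)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_moderated_t_matches_limma(tmp_path, fixture_3v3):
    """Dual-route cross-check against the reference R implementation."""
    a, b = fixture_3v3
    x = np.hstack([a, b])
    genes = [f"g{i}" for i in range(x.shape[0])]
    df_x = pd.DataFrame(x, index=genes,
                        columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)])
    df_x.to_csv(tmp_path / "x.csv")
    script = r"""
suppressMessages(library(limma))
x <- as.matrix(read.csv(commandArgs(TRUE)[1], row.names=1))
design <- model.matrix(~0 + factor(rep(c("a","b"), each=3)))
colnames(design) <- c("a","b")
fit <- lmFit(x, design)
fit <- contrasts.fit(fit, makeContrasts(a - b, levels=design))
fit <- eBayes(fit)
out <- data.frame(t=fit$t[,1], p=fit$p.value[,1],
                  d0=rep(fit$df.prior, nrow(x)), s02=rep(fit$s2.prior, nrow(x)))
write.csv(out, commandArgs(TRUE)[2])
"""
    (tmp_path / "run.R").write_text(script)
    subprocess.run(
        ["Rscript", str(tmp_path / "run.R"), str(tmp_path / "x.csv"),
         str(tmp_path / "out.csv")],
        check=True, capture_output=True,
    )
    ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
    log2fc, s2, df = _pooled(a, b)
    res = moderated_t(log2fc, s2, df, np.sqrt(2 / 3))
    assert res["d0"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
    assert res["s0_2"].iloc[0] == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
    np.testing.assert_allclose(res["t_mod"], ref["t"].to_numpy(), rtol=1e-5)
    np.testing.assert_allclose(res["p"], ref["p"].to_numpy(), rtol=1e-4)


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------

def _result(genes, log2fc, p):
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=genes)


def test_thresholds_are_strict():
    genes = ["g1"]
    r = _result(genes, [0.4], [0.001])  # exactly at the fold-change bound
    assert select_de(r, r).loc["g1"] == "not_de"
    r2 = _result(genes, [0.5], [0.01])  # exactly at the p bound
    assert select_de(r2, r2).loc["g1"] == "not_de"


def test_selection_passes_clear_case_and_requires_both_time_points():
    genes = ["g1"]
    good = _result(genes, [0.5], [0.005])
    weak = _result(genes, [0.5], [0.02])
    assert select_de(good, good).loc["g1"] == "up_in_a"
    assert select_de(good, weak).loc["g1"] == "not_de"
    down = _result(genes, [-0.5], [0.005])
    assert select_de(down, down).loc["g1"] == "up_in_b"


def test_selection_monotone_in_thresholds():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(300)]
    r1 = _result(genes, rng.normal(0, 1, 300), rng.uniform(0, 0.05, 300))
    r2 = _result(genes, rng.normal(0, 1, 300), rng.uniform(0, 0.05, 300))
    base = select_de(r1, r2, SelectionThresholds(0.4, 0.01))
    stricter_p = select_de(r1, r2, SelectionThresholds(0.4, 0.005))
    stricter_fc = select_de(r1, r2, SelectionThresholds(0.8, 0.01))
    for strict in (stricter_p, stricter_fc):
        assert set(strict.index[strict != "not_de"]) <= set(base.index[base != "not_de"])


def test_mismatched_gene_sets_rejected():
    r1 = _result(["g1"], [0.5], [0.001])
    r2 = _result(["g2"], [0.5], [0.001])
    with pytest.raises(ValueError):
        select_de(r1, r2)


# ---------------------------------------------------------------------------
# pH-response classification
# ---------------------------------------------------------------------------

def _dec(genes, values):
    return pd.Series(values, index=genes)


@pytest.mark.parametrize(
    "d63,d645,d453,expected",
    [
        ("up_in_a", "not_de", "not_de", "high_up"),   # up toward high pH only
        ("not_de", "not_de", "up_in_b", "low_up"),
        ("not_de", "up_in_b", "up_in_a", "peak"),     # up 3->4.5 then down 4.5->6
        ("not_de", "up_in_a", "up_in_b", "dip"),
        ("not_de", "not_de", "not_de", "flat"),
        ("up_in_a", "up_in_b", "not_de", "flat"),     # irreconcilable signs
    ],
)
def test_ph_categories(d63, d645, d453, expected):
    g = ["g1"]
    cat = classify_ph_response(_dec(g, [d63]), _dec(g, [d645]), _dec(g, [d453]))
    assert cat.loc["g1"] == expected


def test_categories_form_a_partition():
    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(500)]
    opts = np.array(["up_in_a", "up_in_b", "not_de"])
    cat = classify_ph_response(
        _dec(genes, rng.choice(opts, 500)),
        _dec(genes, rng.choice(opts, 500)),
        _dec(genes, rng.choice(opts, 500)),
    )
    assert set(cat.unique()) <= {"high_up", "low_up", "peak", "dip", "flat"}
    assert len(cat) == 500 and not cat.isna().any()


# ---------------------------------------------------------------------------
# contract checks on fit_contrast
# ---------------------------------------------------------------------------

def test_fit_contrast_requires_replicates(small_study):
    matrix, design = small_study["matrix"], small_study["design"]
    one_rep = design[design["replicate"] == 1]
    c = Contrast("6v3", ("parent", 6.0), ("parent", 3.0), "t1")
    with pytest.raises(ValueError, match="replicates"):
        fit_contrast(matrix, one_rep, c)


def test_fit_contrast_sign_convention(small_study):
    matrix, design, truth = (
        small_study["matrix"], small_study["design"], small_study["truth"]
    )
    res = fit_contrast(matrix, design, Contrast("6v3", ("parent", 6.0), ("parent", 3.0), "t1"))
    hi = truth.index[truth["ph_category"] == "high_up"]
    assert res.loc[hi, "log2fc"].mean() > 1.0  # two effect steps planted
    nz = res["log2fc"] != 0
    assert (np.sign(res.loc[nz, "t_mod"]) == np.sign(res.loc[nz, "log2fc"])).all()
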