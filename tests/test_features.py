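"""Feature extraction: contrast calibration, moderation, schema parity."""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from comblearn import features as ft


def test_feature_schema_is_19_dimensional():
    rng = np.random.default_rng(0)
    gf = ft.extract_features(rng.normal(0, 1, (4, 4)))
    assert len(gf.vector()) == 19
    assert len(ft.FEATURE_COLUMNS) == 19
    assert np.all((gf.contrast_p >= 0) & (gf.contrast_p <= 1))
    assert gf.delta_hat >= 0


def test_null_contrasts_are_calibrated():
    """Under pure-null genes each contrast p-value is ~Uniform(0,1): the
    rejection fraction at alpha=0.05 stays near nominal and the KS test
    does not reject uniformity."""
    rng = np.random.default_rng(11)
    reps = rng.normal(2.0, 0.7, size=(10_000, 4, 4))
    table, _ = ft.featurize(reps)
    for col in ("p_0X", "p_XY", "p_YXY", "omnibus_p"):
        p = table[col].to_numpy()
        assert (p > 0.05).mean() >= 0.94
        assert stats.kstest(p, "uniform").pvalue > 0.01


def test_large_separation_gives_tiny_pvalues():
    rng = np.random.default_rng(2)
    reps = np.stack([rng.normal([0, 0, 0, 10], 0.1, (4, 4)).T
                     for _ in range(5)])
    table, _ = ft.featurize(reps, moderation="off")
    assert (table["p_0XY"] < 1e-6).all()
    assert (table["p_XXY"] < 1e-6).all()
    assert (table["p_YXY"] < 1e-6).all()


def test_pvalue_monotone_in_mean_separation():
    """Growing a group separation with spread fixed never increases the
    contrast p-value."""
    base = np.array([[0.0, 0.1, -0.1, 0.05]] * 4)
    prev = 1.1
    for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
        reps = base.copy()
        reps[3] += shift
        gf = ft.extract_features(reps)
        p = gf.contrast_p[2]  # (0, XY) contrast
        assert p <= prev + 1e-12
        prev = p


def test_variance_shrinkage_fixed_points():
    common = np.full(50, 2.5)
    prior_var, prior_df = ft.shrink_variances(common, df=12)
    assert prior_var == pytest.approx(2.5)
    assert np.isinf(prior_df)
    assert np.allclose(ft.moderate(common, 12, (prior_var, prior_df)), 2.5)
    # prior_df -> 0 leaves the raw variances untouched
    raw = np.array([0.5, 1.0, 4.0, 2.0])
    assert np.allclose(ft.moderate(raw, 12, (1.0, 0.0)), raw)


def test_variance_prior_recovery_on_simulated_genes():
    """Method-of-moments recovers a known scaled inverse-chi-square prior
    within 15% at 5000 genes."""
    rng = np.random.default_rng(3)
    d0, s0, df = 8.0, 2.0, 12
    true_vars = s0 * d0 / rng.chisquare(d0, 5000)
    s2 = true_vars * rng.chisquare(df, 5000) / df
    prior_var, prior_df = ft.shrink_variances(s2, df)
    assert prior_var == pytest.approx(s0, rel=0.15)
    assert prior_df == pytest.approx(d0, rel=0.15)


def test_shrinkage_input_validation():
    with pytest.raises(ft.FeatureError):
        ft.shrink_variances(np.ones(5), df=12)
    with pytest.raises(ft.FeatureError):
        ft.shrink_variances(np.array([1.0] * 9 + [-1.0]), df=12)


def test_moderation_matches_limma_squeezevar():
    """Independent oracle: limma::squeezeVar on the same variances."""
    rng = np.random.default_rng(7)
    d0, s0, df = 6.0, 1.5, 12
    s2 = (s0 * d0 / rng.chisquare(d0, 400)) * rng.chisquare(df, 400) / df
    prior_var, prior_df = ft.shrink_variances(s2, df)
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        s2 <- c({', '.join(f'{x:.12g}' for x in s2)})
        fit <- squeezeVar(s2, df={df})
        cat(fit$var.prior, fit$df.prior, sep="\\n")
    """)
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    r_var, r_df = (float(x) for x in out.stdout.split())
    assert prior_var == pytest.approx(r_var, rel=1e-4)
    assert prior_df == pytest.approx(r_df, rel=1e-4)
    mod = ft.moderate(s2, df, (prior_var, prior_df))
    expected = (r_df * r_var + df * s2) / (r_df + df)
    np.testing.assert_allclose(mod, expected, rtol=1e-4)


def test_single_and_batch_featurization_agree():
    """Training/application parity: one gene through the batch path equals
    the single-instance path."""
    rng = np.random.default_rng(5)
    reps = rng.normal(0, 1, (30, 4, 4))
    table, _ = ft.featurize(reps, moderation="off")
    for i in (0, 13, 29):
        gf = ft.extract_features(reps[i])
        np.testing.assert_allclose(gf.vector(),
                                   table.iloc[i].to_numpy())


def test_zero_variance_degenerate_genes():
    flat_equal = np.zeros((4, 4))
    gf = ft.extract_features(flat_equal)
    assert gf.omnibus_p == 1.0
    assert np.all(gf.contrast_p == 1.0)
    flat_shift = np.zeros((4, 4))
    flat_shift[3] = 1.0
    with pytest.warns(UserWarning, match="zero pooled variance"):
        gf2 = ft.extract_features(flat_shift)
    assert gf2.contrast_p[2] == 0.0
    assert gf2.omnibus_p == 0.0


def test_too_few_replicates_rejected():
    with pytest.raises(ft.FeatureError):
        ft.featurize(np.zeros((3, 4, 1)))
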