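"""Classifier predictors for one gene: means, contrasts, signal.

Each gene (or simulated instance) is summarized by a fixed 19-dimensional
feature vector computed from its 4 x n replicate matrix:

* the four condition means (CTRL, X, Y, COMBO);
* two-sided p-values of the six pairwise contrasts between condition means,
  in the fixed pair order (0,X), (0,Y), (0,XY), (X,Y), (X,XY), (Y,XY);
* the six matching t statistics;
* the estimated signal delta-hat: the smallest pairwise mean difference
  that is statistically supported (contrast p < 0.05 and |difference| above
  the tie tolerance tau), or 0 when no difference is supported.  On noisy
  data the raw smallest-nonzero-difference statistic degenerates to the
  noise level for profiles with tied condition means, so "nonzero" is
  resolved by the contrast test rather than by magnitude alone;
* the omnibus 4-group F-test p-value;
* the pooled within-group variance.

Contrasts use the pooled within-group variance with 4(n-1) degrees of
freedom.  When a batch of genes is processed together, the per-gene
variances are shrunk toward an ensemble prior (empirical-Bayes moderation
with a scaled inverse-chi-square prior fitted by method of moments on the
log variances), and the contrast and omnibus tests gain the prior degrees
of freedom.  Feature order is identical between training and application.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

FEATURE_SCHEMA_VERSION = "1.0"

CONDITION_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
_PAIR_TAGS = ("0X", "0Y", "0XY", "XY", "XXY", "YXY")

FEATURE_COLUMNS = (
    "mean_e0", "mean_eX", "mean_eY", "mean_eXY",
    *(f"p_{t}" for t in _PAIR_TAGS),
    *(f"t_{t}" for t in _PAIR_TAGS),
    "delta_hat", "omnibus_p", "pooled_var",
)

#: batch size at and above which empirical-Bayes moderation turns on
MODERATION_MIN_GENES = 100

#: per-contrast significance level below which a pairwise difference counts
#: as real in the delta-hat estimate; Bonferroni-corrected for the minimum
#: being taken over the 6 contrasts (a chance-significant null contrast
#: would otherwise masquerade as the smallest real difference)
DELTA_ALPHA = 0.05 / 6


class FeatureError(ValueError):
    pass


@dataclass
class GeneFeatures:
    """Predictor vector for one gene, in documented fixed order."""

    means: np.ndarray
    contrast_p: np.ndarray
    contrast_t: np.ndarray
    delta_hat: float
    omnibus_p: float
    pooled_variance: float

    def vector(self) -> np.ndarray:
        return np.concatenate([
            self.means, self.contrast_p, self.contrast_t,
            [self.delta_hat, self.omnibus_p, self.pooled_variance]])


def shrink_variances(per_gene_variances, df: float) -> tuple[float, float]:
    """Fit a scaled inverse-chi-square prior to per-gene sample variances.

    Method-of-moments on the log variances: under the hierarchical model
    s^2 ~ s0^2 * F(df, prior_df), so mean and variance of log(s^2) involve
    digamma/trigamma terms whose inversion yields (prior_var, prior_df).
    The moderated variance is then
    (prior_df * prior_var + df * s^2) / (prior_df + df).

    All variances equal is a degenerate fit: infinite prior_df and
    prior_var equal to the common value (moderation becomes a no-op
    returning that value).
    """
    s2 = np.asarray(per_gene_variances, dtype=float)
    if s2.size < 10:
        raise FeatureError("need >= 10 genes to fit a variance prior")
    if np.any(s2 <= 0):
        raise FeatureError("variances must be > 0")
    if np.ptp(s2) == 0:
        return float(s2[0]), np.inf
    z = np.log(s2)
    evar = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        prior_df = np.inf
        prior_var = float(np.exp(z.mean() - special.digamma(df / 2.0)
                                 + np.log(df / 2.0)))
        return prior_var, prior_df
    prior_df = 2.0 * _trigamma_inverse(evar)
    log_s0 = (z.mean() - special.digamma(df / 2.0)
              + special.digamma(prior_df / 2.0)
              + np.log(df / 2.0) - np.log(prior_df / 2.0))
    return float(np.exp(log_s0)), float(prior_df)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise FeatureError("trigamma inverse requires y > 0")
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def moderate(per_gene_variances, df: float,
             prior: tuple[float, float]) -> np.ndarray:
    """Posterior (moderated) variances given a fitted prior."""
    prior_var, prior_df = prior
    s2 = np.asarray(per_gene_variances, dtype=float)
    if np.isinf(prior_df):
        return np.full_like(s2, prior_var)
    return (prior_df * prior_var + df * s2) / (prior_df + df)


def featurize(replicates: np.ndarray,
              moderation: str = "auto",
              tau: float = 0.0) -> tuple[pd.DataFrame, tuple[float, float] | None]:
    """Feature table for a batch of genes.

    ``replicates`` has shape (n_genes, 4, n_reps).  ``moderation`` is
    'auto' (on for batches of >= 100 genes), 'on' or 'off'.  Returns the
    feature DataFrame (columns ``FEATURE_COLUMNS``) and the fitted
    (prior_var, prior_df), or None when moderation is off.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.ndim == 2:
        reps = reps[None]
    n_genes, n_cond, n = reps.shape
    if n_cond != 4:
        raise FeatureError("expected 4 condition groups")
    if n < 2:
        raise FeatureError("need >= 2 replicates per condition")
    if not np.all(np.isfinite(reps)):
        raise FeatureError("replicate values must be finite")

    means = reps.mean(axis=2)                      # (N, 4)
    ss = ((reps - means[..., None]) ** 2).sum(axis=(1, 2))
    df = 4 * (n - 1)
    s2 = ss / df                                   # pooled within-group var

    if moderation == "auto":
        use_mod = n_genes >= MODERATION_MIN_GENES
    elif moderation in ("on", "off"):
        use_mod = moderation == "on"
    else:
        raise FeatureError(f"invalid moderation setting {moderation!r}")

    prior = None
    if use_mod:
        positive = s2[s2 > 0]
        if positive.size < 10:
            warnings.warn("too few positive variances to fit a prior; "
                          "moderation disabled")
            use_mod = False
        else:
            prior = shrink_variances(positive, df)
    if use_mod:
        s2_post = moderate(s2, df, prior)
        df_post = df + (prior[1] if np.isfinite(prior[1]) else np.inf)
    else:
        s2_post = s2
        df_post = df

    se = np.sqrt(np.maximum(s2_post, 0.0) * (2.0 / n))  # contrast SE

    p_cols = np.empty((n_genes, 6))
    t_cols = np.empty((n_genes, 6))
    t_dist_df = df_post if np.isfinite(df_post) else 1e12
    for k, (i, j) in enumerate(CONDITION_PAIRS):
        diff = means[:, j] - means[:, i]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        zero_se = se == 0
        if np.any(zero_se):
            bad = zero_se & (diff != 0)
            if np.any(bad):
                warnings.warn("zero pooled variance with unequal means; "
                              "p-value set to 0")
            with np.errstate(invalid="ignore"):
                t = np.where(zero_se, np.where(diff != 0,
                                               np.sign(diff) * np.inf,
                                               0.0), t)
        p = 2.0 * stats.t.sf(np.abs(t), t_dist_df)
        p_cols[:, k] = np.where(np.isinf(t), 0.0, p)
        t_cols[:, k] = t

    grand = means.mean(axis=1)
    ms_between = n * ((means - grand[:, None]) ** 2).sum(axis=1) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ms_between / s2_post
    f_df2 = df_post if np.isfinite(df_post) else 1e12
    omnibus_p = stats.f.sf(f_stat, 3, f_df2)
    omnibus_p = np.where(s2_post == 0,
                         np.where(ms_between > 0, 0.0, 1.0), omnibus_p)

    deltas = _delta_hat(means, p_cols, tau)

    data = np.column_stack([means, p_cols, t_cols, deltas, omnibus_p, s2])
    return pd.DataFrame(data, columns=list(FEATURE_COLUMNS)), prior


def _delta_hat(means: np.ndarray, p_cols: np.ndarray,
               tau: float) -> np.ndarray:
    """Smallest statistically supported pairwise difference per gene."""
    diffs = np.column_stack([np.abs(means[:, j] - means[:, i])
                             for i, j in CONDITION_PAIRS])
    supported = (p_cols < DELTA_ALPHA) & (diffs > max(tau, 1e-9))
    masked = np.where(supported, diffs, np.inf)
    delta = masked.min(axis=1)
    return np.where(np.isfinite(delta), delta, 0.0)


def extract_features(replicates: np.ndarray,
                     prior: tuple[float, float] | None = None,
                     tau: float = 0.0) -> GeneFeatures:
    """Feature vector for a single gene's 4 x n replicate matrix.

    When ``prior`` (prior_var, prior_df) from an ensemble of genes is
    supplied, the within-gene variance is shrunk toward it before testing;
    otherwise the raw pooled variance is used.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.ndim != 2 or reps.shape[0] != 4:
        raise FeatureError("expected a 4 x n replicate matrix")
    if prior is None:
        table, _ = featurize(reps[None], moderation="off", tau=tau)
    else:
        table = _featurize_with_prior(reps[None], prior, tau)
    row = table.iloc[0]
    return GeneFeatures(
        means=row[list(FEATURE_COLUMNS[:4])].to_numpy(),
        contrast_p=row[[f"p_{t}" for t in _PAIR_TAGS]].to_numpy(),
        contrast_t=row[[f"t_{t}" for t in _PAIR_TAGS]].to_numpy(),
        delta_hat=float(row["delta_hat"]),
        omnibus_p=float(row["omnibus_p"]),
        pooled_variance=float(row["pooled_var"]),
    )


def _featurize_with_prior(reps: np.ndarray, prior: tuple[float, float],
                          tau: float) -> pd.DataFrame:
    """Single-pass featurization reusing an externally fitted prior."""
    table, _ = featurize(reps, moderation="off", tau=tau)
    n = reps.shape[2]
    df = 4 * (n - 1)
    s2 = table["pooled_var"].to_numpy()
    s2_post = moderate(s2, df, prior)
    df_post = df + prior[1] if np.isfinite(prior[1]) else 1e12
    means = table[list(FEATURE_COLUMNS[:4])].to_numpy()
    se = np.sqrt(s2_post * (2.0 / n))
    for k, (i, j) in enumerate(CONDITION_PAIRS):
        diff = means[:, j] - means[:, i]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, diff / se,
                         np.where(diff != 0, np.sign(diff) * np.inf, 0.0))
        table[f"t_{_PAIR_TAGS[k]}"] = t
        table[f"p_{_PAIR_TAGS[k]}"] = np.where(
            np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df_post))
    grand = means.mean(axis=1)
    ms_between = n * ((means - grand[:, None]) ** 2).sum(axis=1) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ms_between / s2_post
    omnibus = stats.f.sf(f_stat, 3, df_post)
    table["omnibus_p"] = np.where(
        s2_post == 0, np.where(ms_between > 0, 0.0, 1.0), omnibus)
    p_cols = table[[f"p_{t}" for t in _PAIR_TAGS]].to_numpy()
    table["delta_hat"] = _delta_hat(means, p_cols, tau)
    return table
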