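"""Differential exon-junction usage testing.

Per-feature engine: ordinary least squares of log-CPM on a two-group design
gives each feature a group log-fold-change ``beta`` with residual variance
``s^2`` on ``n - 2`` degrees of freedom and unscaled coefficient variance
``v = 1/n1 + 1/n2``.  Empirical-Bayes moderation borrows strength across
features: the prior ``(d0, s0^2)`` is estimated by matching the moments of
``log(s^2)`` (digamma/trigamma matching), and each feature's posterior
variance is ``(d0*s0^2 + d*s^2) / (d0 + d)`` with ``d + d0`` total degrees
of freedom.

Usage test: within each gene, the feature effect is contrasted against the
precision-weighted gene average,

    delta_j = beta_j - sum(w beta)/sum(w),    w_j = 1/v_j,

with ``Var(delta_j) = s~_j^2 (v_j - 1/sum w)``; the moderated t of each
feature is referred to a t distribution on ``d + d0`` df.  Gene-level
summaries are the Simes combination of the feature p-values and an F-type
statistic ``sum(t^2)/(J-1)`` on ``(J-1, d + d0)`` df, each followed by
Benjamini–Hochberg adjustment across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "EngineConfig",
    "FeatureFit",
    "fit_feature_models",
    "estimate_variance_prior",
    "trigamma_inverse",
    "diff_splice_test",
    "aggregate_genes",
    "simes_p",
    "bh_adjust",
]


@dataclass
class EngineConfig:
    gene_min_features: int = 2
    ebayes: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class FeatureFit:
    """Per-feature linear-model summaries on a two-group design."""

    beta: np.ndarray  # group-2 minus group-1 coefficient
    s2: np.ndarray  # residual variance, d df each
    v: float  # unscaled coefficient variance 1/n1 + 1/n2
    d: float  # residual degrees of freedom
    d0: float  # prior degrees of freedom (inf when no moderation signal)
    s0_2: float  # prior variance
    s2_post: np.ndarray  # posterior (moderated) variance
    df_total: float  # d + d0


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment estimates of the variance prior from observed residual variances.

    Matches mean and variance of ``log(s^2)`` against the scaled-F model of
    variance sampling; returns ``(d0, s0_2)``.  When the excess variance of
    the log variances is non-positive the prior is degenerate:
    ``d0 = inf`` and ``s0_2 = mean(s2)``.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmean(s2[np.isfinite(s2)])) if np.isfinite(
            s2
        ).any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if e_var <= 0:
        # no evidence of variance heterogeneity: degenerate prior, pooled s2
        return np.inf, float(s2[ok].mean())
    half_d0 = trigamma_inverse(e_var)
    d0 = 2.0 * half_d0
    s0_2 = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_2


def fit_feature_models(
    logcpm: np.ndarray, groups: np.ndarray, ebayes: bool = True
) -> FeatureFit:
    """Per-feature OLS on a two-group design, with optional eBayes moderation."""
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("the design must have exactly two groups")
    in2 = groups == levels[1]
    n1, n2 = int((~in2).sum()), int(in2.sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least two samples")
    x = np.asarray(logcpm, dtype=float)
    mean1 = x[:, ~in2].mean(axis=1)
    mean2 = x[:, in2].mean(axis=1)
    beta = mean2 - mean1
    fitted = np.where(in2[None, :], mean2[:, None], mean1[:, None])
    resid = x - fitted
    d = n1 + n2 - 2
    s2 = (resid**2).sum(axis=1) / d
    v = 1.0 / n1 + 1.0 / n2

    if ebayes:
        d0, s0_2 = estimate_variance_prior(s2, d)
    else:
        d0, s0_2 = 0.0, 0.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 > 0:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d + d0
    else:
        s2_post = s2.copy()
        df_total = float(d)
    return FeatureFit(beta, s2, v, float(d), d0, s0_2, s2_post, df_total)


def diff_splice_test(
    fit: FeatureFit,
    gene_ids: np.ndarray,
    config: EngineConfig | None = None,
) -> pd.DataFrame:
    """Feature-level usage test: effect relative to the gene average.

    Genes with fewer than ``gene_min_features`` features are reported
    untested (``tested = False``, NaN statistics).
    """
    config = config or EngineConfig()
    gene_ids = np.asarray(gene_ids)
    codes, uniques = pd.factorize(gene_ids)
    order = np.argsort(codes, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)

    beta = fit.beta[order]
    s2p = fit.s2_post[order]
    codes_s = codes[order]
    w = np.full(beta.shape, 1.0 / fit.v)
    starts = np.flatnonzero(np.r_[True, np.diff(codes_s) != 0])
    counts = np.diff(np.r_[starts, codes_s.size])
    sum_w = np.add.reduceat(w, starts)
    sum_wb = np.add.reduceat(w * beta, starts)
    gene_mean = sum_wb / sum_w
    j_per = np.repeat(counts, counts)
    delta = beta - np.repeat(gene_mean, counts)
    var_term = fit.v - 1.0 / np.repeat(sum_w, counts)
    se = np.sqrt(np.maximum(s2p * var_term, 0.0))
    tested = j_per >= config.gene_min_features
    t = np.full(beta.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t[tested] = delta[tested] / se[tested]
    if np.isinf(fit.df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), fit.df_total)

    out = pd.DataFrame(
        {
            "gene_id": gene_ids[order][inv],
            "logFC": fit.beta,
            "delta": delta[inv],
            "se_delta": se[inv],
            "t": t[inv],
            "p_feature": p[inv],
            "tested": tested[inv],
        }
    )
    out["df_total"] = fit.df_total
    return out


def simes_p(p: np.ndarray) -> float:
    """Simes combination: min over k of (J * p_(k) / k)."""
    p = np.sort(np.asarray(p, dtype=float))
    j = len(p)
    return float(min(1.0, (j * p / np.arange(1, j + 1)).min()))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def aggregate_genes(
    feature_stats: pd.DataFrame, config: EngineConfig | None = None
) -> pd.DataFrame:
    """Gene-level Simes and F summaries with BH adjustment across genes.

    Only tested features (genes with at least ``gene_min_features``) enter;
    untested genes are absent from the output.
    """
    config = config or EngineConfig()
    tested = feature_stats[feature_stats["tested"]]
    rows = []
    for gene_id, grp in tested.groupby("gene_id", sort=True):
        pvals = grp["p_feature"].to_numpy()
        tvals = grp["t"].to_numpy()
        j = len(grp)
        df_total = float(grp["df_total"].iloc[0])
        f_stat = float((tvals**2).sum() / (j - 1))
        if np.isinf(df_total):
            p_f = float(stats.chi2.sf(f_stat * (j - 1), j - 1))
        else:
            p_f = float(stats.f.sf(f_stat, j - 1, df_total))
        rows.append((gene_id, j, simes_p(pvals), f_stat, p_f))
    out = pd.DataFrame(
        rows, columns=["gene_id", "n_features", "p_simes", "F", "p_F"]
    )
    if len(out):
        out["fdr_simes"] = bh_adjust(out["p_simes"].to_numpy())
        out["fdr_F"] = bh_adjust(out["p_F"].to_numpy())
    else:
        out["fdr_simes"] = out["fdr_F"] = np.array([], dtype=float)
    return out
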