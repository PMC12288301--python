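"""Expression filtering, TMM normalisation and log-CPM transformation.

The filter keeps a feature when it is expressed at a worthwhile level in at
least a minimum number of samples (a per-million cutoff equivalent to
``min_count`` reads in the median-sized library) *and* its total count over
all samples clears ``min_total_count``.  Genes are then reduced to their
surviving features.

TMM (trimmed mean of M-values) corrects for composition bias between
libraries: relative to a reference sample, extreme log-ratios (M) and
log-abundances (A) are trimmed and the remaining M-values averaged with
inverse asymptotic binomial variances; factors are normalised to have unit
geometric mean, so they multiply library sizes without changing their scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .quantify import CountMatrix

__all__ = [
    "FilterConfig",
    "NormFactors",
    "filter_by_expression",
    "compute_tmm_factors",
    "log_cpm",
]


@dataclass
class FilterConfig:
    min_count: float = 10.0
    min_total_count: float = 15.0
    min_prop_samples: float = 0.7

    def __post_init__(self) -> None:
        if min(self.min_count, self.min_total_count, self.min_prop_samples) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors (unit geometric mean)."""

    factors: np.ndarray
    reference: str
    trim_m: float = 0.30
    trim_a: float = 0.05


def filter_by_expression(
    matrix: CountMatrix,
    groups: np.ndarray,
    config: FilterConfig | None = None,
) -> CountMatrix:
    """Drop features with too few mapped reads to support inference.

    A feature is kept iff its CPM is at least ``min_count`` (expressed as a
    CPM relative to the median library size) in at least
    ``ceil(min_prop_samples * smallest group size)`` samples, and its total
    count across samples is at least ``min_total_count``.
    """
    config = config or FilterConfig()
    groups = np.asarray(groups)
    if len(matrix.samples) < 2:
        raise ValueError("filtering requires at least two samples")
    lib = matrix.library_sizes.astype(float)
    cpm = matrix.counts / lib * 1e6
    cutoff = config.min_count / (np.median(lib) / 1e6)
    _, group_sizes = np.unique(groups, return_counts=True)
    n_needed = math.ceil(config.min_prop_samples * group_sizes.min())
    keep = ((cpm >= cutoff).sum(axis=1) >= n_needed) & (
        matrix.counts.sum(axis=1) >= config.min_total_count
    )
    if not keep.any():
        raise ValueError(
            "no feature passed the expression filter; relax min_count / "
            "min_total_count"
        )
    return matrix.subset(keep)


def _quantile_ratio(counts: np.ndarray, lib: np.ndarray, p: float = 0.75):
    return np.quantile(counts / lib, p, axis=0)


def compute_tmm_factors(
    matrix: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """Trimmed mean of M-values normalisation factors.

    The reference is the sample whose 75th-percentile count proportion is
    closest to the mean across samples.  For each sample, M and A values are
    computed over features positive in both sample and reference, the
    ``trim_m`` / ``trim_a`` most extreme fractions are discarded (two-sided,
    rank-based), and the factor is two to the inverse-variance-weighted mean
    of the remaining M-values.  Factors are scaled to unit geometric mean.
    """
    counts = matrix.counts.astype(float)
    lib = matrix.library_sizes.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    if (counts.sum(axis=0) <= 0).any():
        raise ValueError("every sample needs at least one positive count")

    f75 = _quantile_ratio(counts, lib)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    x_r = counts[:, ref]
    n_r = lib[ref]

    log_factors = np.zeros(counts.shape[1])
    for s in range(counts.shape[1]):
        if s == ref:
            continue
        x = counts[:, s]
        n = lib[s]
        pos = (x > 0) & (x_r > 0)
        if pos.sum() == 0:
            log_factors[s] = 0.0
            continue
        xs, xr = x[pos], x_r[pos]
        m = np.log2((xs / n) / (xr / n_r))
        a = 0.5 * np.log2((xs / n) * (xr / n_r))
        w = (n - xs) / (n * xs) + (n_r - xr) / (n_r * xr)
        finite = np.isfinite(m) & np.isfinite(a)
        m, a, w = m[finite], a[finite], w[finite]
        k = m.size
        if k == 0:
            continue
        # rank-based two-sided trimming of extreme M and A values
        lo_m = math.floor(k * trim_m) + 1
        hi_m = k + 1 - lo_m
        lo_a = math.floor(k * trim_a) + 1
        hi_a = k + 1 - lo_a
        rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1
        rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() < 10:
            warnings.warn(
                f"fewer than 10 features left after TMM trimming for sample "
                f"{matrix.samples[s]}; factor set to 1"
            )
            log_factors[s] = 0.0
            continue
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        if not np.isfinite(f) or abs(f) < 1e-6:
            f = 0.0
        log_factors[s] = f

    factors = 2.0 ** (log_factors - log_factors.mean())
    return NormFactors(factors, matrix.samples[ref], trim_m, trim_a)


def log_cpm(matrix: CountMatrix, norm: NormFactors | None = None) -> np.ndarray:
    """log2 counts per million on TMM-adjusted library sizes.

    ``log2((count + 0.5) / (lib * factor + 1) * 1e6)`` — the half-count
    offset keeps zeros finite and the +1 on the effective library size keeps
    the transform bounded.
    """
    factors = norm.factors if norm is not None else np.ones(len(matrix.samples))
    eff = matrix.library_sizes.astype(float) * factors
    return np.log2((matrix.counts + 0.5) / (eff + 1.0) * 1e6)
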