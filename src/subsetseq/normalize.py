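"""Count filtering, TMM scaling factors, log2-cpm and voom precision weights.

The chain implemented here is the canonical count-based normalization stack:

1. keep genes with at least ``min_cpm`` counts-per-million in at least
   ``min_samples`` samples (cpm computed on raw library sizes);
2. per-sample scaling factors by the trimmed mean of M-values (TMM):
   gene-wise log2 expression ratios against a reference sample are trimmed
   (30% on M, 5% on A) and averaged with inverse delta-method variance
   weights; factors are rescaled to geometric mean 1;
3. log2-cpm with a 0.5 pseudo-count over effective library sizes
   ``lib_size * factor + 1``;
4. per-observation precision weights from the fitted mean-variance trend:
   gene-wise residual standard deviations under the study design are
   lowess-smoothed against mean log2 counts and each observation receives
   weight ``predicted_sd^-4``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from subsetseq.io import CountMatrix

# TMM trimming defaults of the canonical implementation
LOG_RATIO_TRIM = 0.3
SUM_TRIM = 0.05


@dataclass
class NormalizedMatrix:
    """log2-cpm values with per-observation precision weights.

    Invariants: geometric mean of ``tmm_factors`` is 1; all weights > 0;
    all arrays share the genes x samples shape of the filtered matrix.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    log_cpm: np.ndarray
    weights: np.ndarray
    tmm_factors: np.ndarray
    lib_sizes: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.gene_ids), len(self.sample_ids))
        if self.log_cpm.shape != shape or self.weights.shape != shape:
            raise ValueError("log_cpm/weights shape mismatch")
        if not np.all(self.weights > 0):
            raise ValueError("non-positive precision weight")
        gm = np.exp(np.mean(np.log(self.tmm_factors)))
        if abs(gm - 1.0) > 1e-8:
            raise ValueError(f"TMM factors not normalized to geometric mean 1 (got {gm})")


def compute_cpm(counts: CountMatrix) -> np.ndarray:
    """Counts-per-million on raw library sizes (no TMM, no pseudo-count)."""
    lib = counts.counts.sum(axis=0)
    if np.any(lib == 0):
        bad = [counts.sample_ids[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"zero-library samples: {bad}")
    return counts.counts / lib * 1e6


def filter_low_expression(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples: int = 1
) -> CountMatrix:
    """Keep genes with cpm >= ``min_cpm`` in >= ``min_samples`` samples.

    The threshold is inclusive on both counts, matching the retention rule
    "at least 1 cpm in at least 1 sample"; gene order is preserved and the
    operation is idempotent.
    """
    cpm = compute_cpm(counts)
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return counts.subset_genes(keep)


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2^f)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        m = np.log2(p_obs / p_ref)                      # expression log-ratio
        a = 0.5 * np.log2(p_obs * p_ref)                # abundance
        # asymptotic (delta-method) variance of M
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    usable = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[usable], a[usable], v[usable]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = np.floor(n * LOG_RATIO_TRIM) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * SUM_TRIM) + 1
    hi_s = n + 1 - lo_s
    rank_m = _rank_average(m)
    rank_a = _rank_average(a)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not np.any(keep):
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def _rank_average(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with midrank ties, as R's rank()."""
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def tmm_factors(counts: CountMatrix) -> np.ndarray:
    """Per-sample TMM scaling factors, geometric-mean normalized to 1.

    The reference sample is the one whose 75th-percentile count proportion
    is closest to the mean across samples.  Genes with zero counts in either
    of the compared samples carry no information about the log-ratio and are
    excluded pair-wise.
    """
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    x = counts.counts.astype(float)
    lib = x.sum(axis=0)
    if np.any(lib == 0):
        bad = [counts.sample_ids[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"zero-library samples: {bad}")
    f75 = np.quantile(x / lib, 0.75, axis=0)
    if np.median(f75) < 1e-20:
        ref = int(np.argmax(np.sqrt(x).sum(axis=0)))
    else:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [_tmm_pair(x[:, s], x[:, ref], lib[s], lib[ref]) for s in range(counts.n_samples)]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm_and_weights(
    counts: CountMatrix,
    tmm: np.ndarray,
    design: np.ndarray | None = None,
    span: float = 0.5,
) -> NormalizedMatrix:
    """log2-cpm transform plus mean-variance precision weights.

    ``log_cpm[g,s] = log2((count + 0.5) / (lib_size * factor + 1) * 1e6)``.
    Residual standard deviations of an (unweighted) gene-wise fit under
    ``design`` are smoothed on the sqrt scale against average log2 count by
    lowess with span ``span``; each observation's weight is the predicted
    standard deviation to the power -4.  ``design`` defaults to an
    intercept-only model.
    """
    y_counts = counts.counts.astype(float)
    n_genes, n_samples = y_counts.shape
    lib = y_counts.sum(axis=0) * np.asarray(tmm, dtype=float)
    log_cpm = np.log2((y_counts + 0.5) / (lib + 1.0) * 1e6)

    if design is None:
        design = np.ones((n_samples, 1))
    design = np.asarray(design, dtype=float)
    rank = np.linalg.matrix_rank(design)
    if n_samples - rank < 1:
        raise ValueError("design leaves zero residual degrees of freedom")

    q, _ = np.linalg.qr(design)
    fitted = log_cpm @ q @ q.T
    resid = log_cpm - fitted
    sigma = np.sqrt((resid ** 2).sum(axis=1) / (n_samples - rank))

    # mean-variance trend: sqrt-sd vs average log2 count
    sx = log_cpm.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    trend = _lowess(sy, sx, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]

    fitted_logcount = fitted + np.log2(lib + 1.0) - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)  # clamped at the ends
    pred_sqrt_sd = np.maximum(pred_sqrt_sd, 1e-6)
    weights = pred_sqrt_sd ** -4

    return NormalizedMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        log_cpm=log_cpm,
        weights=weights,
        tmm_factors=np.asarray(tmm, dtype=float),
        lib_sizes=y_counts.sum(axis=0).astype(np.int64),
    )
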