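"""Gene-wise weighted linear models with empirical-Bayes moderated t contrasts.

Each gene's log2-cpm profile is fitted by weighted least squares under a
group-means design (one indicator column per cell subset, or per lineage for
the total-ILC-vs-total-Th comparison).  Residual variances are shrunk toward
a common prior by empirical Bayes: the ensemble of gene-wise variances is
matched in moments to a scaled F distribution, yielding prior degrees of
freedom ``d0`` and prior variance ``s0^2``; the posterior variance of gene g
is ``(d0*s0^2 + d_g*s_g^2) / (d0 + d_g)``.  Contrast t statistics use the
posterior variance and gain ``d0`` degrees of freedom; p-values are
two-sided and Benjamini-Hochberg adjusted across all tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from subsetseq.io import SampleTable
from subsetseq.normalize import NormalizedMatrix

#: cap representing an effectively infinite prior df
D0_CAP = 1e7

LINEAGE_OF = {
    "ILC1": "ILC", "ILC2": "ILC", "ILCP": "ILC",
    "Th1": "Th", "Th2": "Th", "Th17": "Th",
}
_SUBSET_ORDER = ("ILC1", "ILC2", "ILCP", "Th1", "Th2", "Th17")
_LINEAGE_ORDER = ("ILC", "Th")


@dataclass
class DesignMatrix:
    """Samples x coefficients group-means design, full column rank."""

    matrix: np.ndarray
    coef_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sample_ids), len(self.coef_names)):
            raise ValueError("design shape mismatch")
        if np.linalg.matrix_rank(self.matrix) < len(self.coef_names):
            raise ValueError("design matrix is rank deficient")

    def contrast(self, weights: dict[str, float]) -> np.ndarray:
        """Coefficient-weight vector from a {name: weight} mapping."""
        unknown = set(weights) - set(self.coef_names)
        if unknown:
            raise KeyError(f"unknown coefficients: {sorted(unknown)}")
        return np.array([weights.get(name, 0.0) for name in self.coef_names])


def build_design(samples: SampleTable, grouping: str = "subset") -> DesignMatrix:
    """Group-means design over subsets or over the ILC/Th lineage split."""
    sample_ids = samples.sample_ids
    subsets = samples.aligned_subsets(sample_ids)
    if grouping == "subset":
        labels, order = subsets, _SUBSET_ORDER
    elif grouping == "lineage":
        labels, order = [LINEAGE_OF[s] for s in subsets], _LINEAGE_ORDER
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    empty = [g for g in order if g not in labels]
    if empty:
        raise ValueError(f"groups with zero samples: {empty}")
    matrix = np.array([[1.0 if lab == g else 0.0 for g in order] for lab in labels])
    return DesignMatrix(matrix, list(order), sample_ids)


@dataclass
class FitResult:
    """Per-gene WLS coefficients plus shared empirical-Bayes hyperparameters."""

    gene_ids: list[str]
    coef: np.ndarray            # genes x p
    coef_names: list[str]
    cov_unscaled: np.ndarray    # genes x p x p, (X' W X)^-1
    s2: np.ndarray              # gene-wise residual variances
    df_resid: float
    d0: float = field(default=np.nan)      # prior df (may be inf, capped)
    s02: float = field(default=np.nan)     # prior variance
    s2_post: np.ndarray = field(default=None)

    def with_prior(self, d0: float, s02: float) -> "FitResult":
        """Recompute posterior variances under explicit hyperparameters."""
        d0 = min(d0, D0_CAP) if np.isfinite(d0) else D0_CAP
        if d0 == 0:
            s2_post = self.s2.copy()
        else:
            s2_post = (d0 * s02 + self.df_resid * self.s2) / (d0 + self.df_resid)
        return FitResult(
            self.gene_ids, self.coef, self.coef_names, self.cov_unscaled,
            self.s2, self.df_resid, d0, s02, s2_post,
        )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match gene-wise variances to a scaled F distribution.

    Works on log variances: ``log s^2`` has known mean/variance offsets given
    by di/trigamma functions of the residual df; the excess spread identifies
    the prior df d0, the location identifies s0^2.  Returns (d0, s02), with
    d0 capped at ``D0_CAP`` when the spread is at or below the no-moderation
    limit (all information in the prior).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive variances to estimate the prior")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        if d0 >= D0_CAP:
            d0 = D0_CAP
            s02 = float(np.exp(emean))
        else:
            s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = D0_CAP
        s02 = float(np.exp(emean))
    return float(d0), s02


def fit_models(norm: NormalizedMatrix, design: DesignMatrix) -> FitResult:
    """Weighted least squares per gene, then empirical-Bayes shrinkage."""
    x = design.matrix
    n, p = x.shape
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    y = norm.log_cpm
    w = norm.weights
    # batched X' W X and X' W y across genes
    xtwx = np.einsum("sp,gs,sq->gpq", x, w, x)
    xtwy = np.einsum("sp,gs,gs->gp", x, w, y)
    cov_unscaled = np.linalg.inv(xtwx)
    coef = np.einsum("gpq,gq->gp", cov_unscaled, xtwy)
    resid = y - coef @ x.T
    rss = np.sum(w * resid ** 2, axis=1)
    df_resid = float(n - p)
    s2 = rss / df_resid
    d0, s02 = estimate_prior(s2, df_resid)
    fit = FitResult(
        list(norm.gene_ids), coef, list(design.coef_names), cov_unscaled, s2, df_resid
    )
    return fit.with_prior(d0, s02)


@dataclass
class ContrastTable:
    """Per-gene estimate, moderated t, p and BH-adjusted p for one contrast."""

    name: str
    frame: pd.DataFrame  # columns: gene_id, log2_fc, t, p, adj_p

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame["gene_id"])

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.frame[self.frame["adj_p"] < alpha]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj_p(i) = min over j with p(j) >= p(i) of min(1, m * p(j) / rank(j))``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def test_contrast(
    fit: FitResult, contrast: np.ndarray, name: str = "contrast"
) -> ContrastTable:
    """Moderated t-test of a coefficient contrast across all genes."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(fit.coef_names),):
        raise ValueError(
            f"contrast length {c.size} != {len(fit.coef_names)} coefficients"
        )
    if np.all(c == 0):
        raise ValueError("contrast is identically zero")
    if fit.s2_post is None:
        raise ValueError("fit has no posterior variances; run empirical Bayes first")
    est = fit.coef @ c
    v_unscaled = np.einsum("gpq,p,q->g", fit.cov_unscaled, c, c)
    se = np.sqrt(fit.s2_post * v_unscaled)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / se, 0.0)
    df_total = fit.d0 + fit.df_resid
    p = 2.0 * t_dist.sf(np.abs(t), df_total)
    frame = pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "log2_fc": est,
            "t": t,
            "p": p,
            "adj_p": bh_adjust(p),
        }
    )
    return ContrastTable(name, frame)


def de_summary(
    tables: dict[str, ContrastTable], alpha: float = 0.05
) -> pd.DataFrame:
    """Up/down counts of significant genes per comparison.

    All tables must share one gene universe.  ``n_up`` counts genes with
    ``adj_p < alpha`` and positive estimate, ``n_down`` the negative ones.
    """
    universe = None
    rows = []
    for name, table in tables.items():
        genes = frozenset(table.gene_ids)
        if universe is None:
            universe = genes
        elif genes != universe:
            raise ValueError(f"contrast {name!r} has a different gene universe")
        sig = table.significant(alpha)
        rows.append(
            {
                "comparison": name,
                "n_up": int((sig["log2_fc"] > 0).sum()),
                "n_down": int((sig["log2_fc"] < 0).sum()),
                "n_total": int(len(sig)),
            }
        )
    return pd.DataFrame(rows)


def de_pair_matrix(
    pairwise: dict[tuple[str, str], ContrastTable],
    groups: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Square layout of pairwise DE counts (the two-triangle table).

    Entry [row S, column T] is the number of genes up-regulated in S
    relative to T at ``adj_p < alpha``; the transposed entry holds the
    down-regulated count, so the two triangles summarize every comparison.
    """
    mat = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for (a, b), table in pairwise.items():
        sig = table.significant(alpha)
        mat.loc[a, b] = int((sig["log2_fc"] > 0).sum())
        mat.loc[b, a] = int((sig["log2_fc"] < 0).sum())
    return mat
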