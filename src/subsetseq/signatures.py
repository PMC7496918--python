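"""Subset gene signatures, spider summaries, heatmap z-scores, PCA, lncRNA tables.

A subset's signature is the set of genes significantly over-expressed in
that subset against *every* other subset (BH-adjusted p < alpha and positive
estimate in all five pairwise comparisons).  By this conjunction the six
signatures are disjoint.  Spider-chart coordinates summarize each signature
as its mean log2 normalized cpm within each subset's samples.  Heatmap
matrices are row z-scores ordered by complete-linkage clustering on
Euclidean distances, and sample-level structure is summarized by PCA on the
top variable genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from subsetseq.io import AnnotationTable, SampleTable
from subsetseq.linmod import ContrastTable
from subsetseq.normalize import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class SignatureSet:
    """Member genes per subset plus the 6x6 spider matrix."""

    members: dict[str, list[str]]
    spider: pd.DataFrame  # rows: signature subset, columns: subset, mean log2 cpm

    def sizes(self) -> dict[str, int]:
        return {s: len(g) for s, g in self.members.items()}


def _pair_effect(
    pairwise: dict[tuple[str, str], ContrastTable], a: str, b: str
) -> pd.DataFrame:
    """Per-gene (estimate, adj_p) oriented as a - b, from either key order."""
    if (a, b) in pairwise:
        frame = pairwise[(a, b)].frame
        return frame.set_index("gene_id")[["log2_fc", "adj_p"]]
    if (b, a) in pairwise:
        frame = pairwise[(b, a)].frame.set_index("gene_id")[["log2_fc", "adj_p"]].copy()
        frame["log2_fc"] = -frame["log2_fc"]
        return frame
    raise ValueError(f"missing pairwise contrast for ({a}, {b})")


def subset_signatures(
    pairwise: dict[tuple[str, str], ContrastTable],
    subsets: Sequence[str],
    norm: NormalizedMatrix,
    samples: SampleTable,
    alpha: float = 0.05,
) -> SignatureSet:
    """Signature per subset: genes up vs all other subsets at adj_p < alpha."""
    members: dict[str, list[str]] = {}
    claimed: dict[str, str] = {}
    for s in subsets:
        keep = None
        for t in subsets:
            if t == s:
                continue
            eff = _pair_effect(pairwise, s, t)
            ok = (eff["adj_p"] < alpha) & (eff["log2_fc"] > 0)
            keep = ok if keep is None else (keep & ok)
        genes = list(keep.index[keep])
        for g in genes:
            if g in claimed:  # impossible under the conjunction rule
                raise AssertionError(
                    f"gene {g} claimed by both {claimed[g]} and {s}"
                )
            claimed[g] = s
        members[s] = genes
    spider = spider_values(members, norm, samples, list(subsets))
    return SignatureSet(members, spider)


def spider_values(
    members: dict[str, list[str]] | SignatureSet,
    norm: NormalizedMatrix,
    samples: SampleTable,
    subsets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean log2 normalized cpm of each signature within each subset's samples.

    Entry (signature, subset) averages over the signature's genes and the
    subset's samples; empty signatures yield NaN rows (missing marker).
    """
    if isinstance(members, SignatureSet):
        members = members.members
    if subsets is None:
        subsets = list(members)
    expr = pd.DataFrame(norm.log_cpm, index=norm.gene_ids, columns=norm.sample_ids)
    subset_of = dict(zip(samples.frame["sample_id"], samples.frame["subset"]))
    cols_by_subset = {
        s: [c for c in norm.sample_ids if subset_of.get(c) == s] for s in subsets
    }
    out = pd.DataFrame(np.nan, index=list(members), columns=list(subsets), dtype=float)
    for sig, genes in members.items():
        if not genes:
            continue
        block = expr.loc[genes]
        for s in subsets:
            cols = cols_by_subset[s]
            if cols:
                out.loc[sig, s] = float(block[cols].to_numpy().mean())
    return out


def row_zscores(matrix: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Center and scale each row to mean 0, sd 1 (sample sd); constant rows -> 0."""
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (values - mean) / sd, 0.0)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return z


def cluster_order(zmatrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Row permutation from complete-linkage clustering on Euclidean distances.

    Deterministic for a fixed input: scipy's agglomeration breaks distance
    ties by cluster index, which follows row order.
    """
    values = zmatrix.to_numpy() if isinstance(zmatrix, pd.DataFrame) else np.asarray(zmatrix)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    z = linkage(values, method="complete", metric="euclidean")
    return np.asarray(leaves_list(z), dtype=np.intp)


@dataclass
class PcaSummary:
    """Sample scores, variance fractions and gene contributions of a PCA."""

    scores: pd.DataFrame             # samples x components
    variance_fraction: np.ndarray    # per component, sums to 1
    cumulative_variance: np.ndarray
    loadings: pd.DataFrame           # genes x components
    top_genes: dict[int, list[str]]  # component -> genes by |loading|


def pca_top_variable(
    norm: NormalizedMatrix,
    n_top: int = 500,
    scale: bool = False,
    n_top_genes_report: int = 50,
) -> PcaSummary:
    """PCA of samples on the ``n_top`` most variable genes (by log2-cpm variance).

    Genes are centered (and optionally unit-scaled) across samples; the SVD
    of the samples x genes matrix gives component scores and per-component
    variance fractions over all components.
    """
    if n_top < 2:
        raise ValueError("n_top must be >= 2")
    n_genes = len(norm.gene_ids)
    n_top = min(n_top, n_genes)
    variances = norm.log_cpm.var(axis=1, ddof=1)
    # stable selection: sort by (-variance, gene id) so gene order is irrelevant
    order = sorted(range(n_genes), key=lambda i: (-variances[i], norm.gene_ids[i]))
    top = np.array(order[:n_top], dtype=np.intp)
    genes = [norm.gene_ids[i] for i in top]

    x = norm.log_cpm[top].T.astype(float)  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1, keepdims=True)
        x = np.divide(x, sd, out=np.zeros_like(x), where=sd > 0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| gene positive per component
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    explained = s ** 2
    total = explained.sum()
    frac = explained / total if total > 0 else np.zeros_like(explained)
    scores = pd.DataFrame(
        u * s,
        index=norm.sample_ids,
        columns=[f"PC{i + 1}" for i in range(s.size)],
    )
    loadings = pd.DataFrame(
        vt.T, index=genes, columns=[f"PC{i + 1}" for i in range(s.size)]
    )
    top_genes = {
        k + 1: list(loadings[f"PC{k + 1}"].abs().sort_values(ascending=False).index[:n_top_genes_report])
        for k in range(min(3, s.size))
    }
    return PcaSummary(scores, frac, np.cumsum(frac), loadings, top_genes)


def biotype_subset(
    table: ContrastTable, annotation: AnnotationTable, biotype: str = "lncRNA"
) -> ContrastTable:
    """Restrict a contrast table to genes of one annotation biotype.

    Adjusted p-values are NOT recomputed: the rows are read out of the
    genome-wide BH family, so a biotype's significant genes are exactly its
    significant rows in the full table.
    """
    bmap = annotation.biotype_map()
    available = sorted(set(bmap.values()))
    # "lncRNA" is always a recognized class: an annotation without any simply
    # yields an empty table rather than an error
    if biotype not in available and biotype != "lncRNA":
        raise ValueError(f"unknown biotype {biotype!r}; available: {available}")
    covered = table.frame["gene_id"].map(bmap)
    n_uncovered = int(covered.isna().sum())
    if n_uncovered:
        logger.warning("%d genes missing from the annotation were dropped", n_uncovered)
    keep = covered == biotype
    frame = table.frame[keep].reset_index(drop=True)
    return ContrastTable(f"{table.name}[{biotype}]", frame)


def qpcr_delta_ct(
    ct_target: Sequence[float], ct_reference: Sequence[float]
) -> float:
    """Relative expression by the 2^-dCt rule against a housekeeping gene.

    ``2 ** -(mean(ct_target) - mean(ct_reference))`` over complete
    measurement replicates; Ct values must lie in (0, 45) cycles.
    """
    target = np.asarray(ct_target, dtype=float)
    reference = np.asarray(ct_reference, dtype=float)
    for name, arr in (("target", target), ("reference", reference)):
        if arr.size == 0 or np.any(~np.isfinite(arr)):
            raise ValueError(f"incomplete {name} Ct replicates")
        if np.any((arr <= 0) | (arr >= 45)):
            raise ValueError(f"{name} Ct values outside (0, 45)")
    return float(2.0 ** -(target.mean() - reference.mean()))
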