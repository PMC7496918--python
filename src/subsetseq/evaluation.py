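"""Property measurements over the pipeline: oracles, calibration, recovery.

Each function here re-runs a stage of the pipeline under controlled
synthetic conditions and returns a number: the maximum deviation from an
independently coded reference, a rejection rate under a null, or a recovery
rate on planted structure.  The test suite asserts on these numbers and the
acceptance script reports them; the reference implementations are written
directly from the defining formulas (exhaustive running sums, step-up BH,
step-by-step TMM) so they share no code with the production paths they
check.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from subsetseq.gsea import GseaConfig, RankedList, enrichment_score, gsea_run
from subsetseq.io import CountMatrix, GeneSetCollection
from subsetseq.linmod import bh_adjust, build_design, estimate_prior, fit_models, test_contrast
from subsetseq.normalize import compute_cpm, filter_low_expression, log_cpm_and_weights, tmm_factors
from subsetseq.signatures import spider_values, subset_signatures
from subsetseq.simulate import SimulationConfig, simulate_counts, simulate_genesets

SUBSETS = ("ILC1", "ILC2", "ILCP", "Th1", "Th2", "Th17")


# ---------------------------------------------------------------------------
# independent references


def es_exhaustive(t_values: np.ndarray, member_mask: np.ndarray, p_exp: float) -> tuple[float, float]:
    """Literal step-by-step running sum; O(N) walk, no vectorization tricks."""
    t_values = np.asarray(t_values, dtype=float)
    weights = np.abs(t_values[member_mask]) ** p_exp
    total = weights.sum()
    n = t_values.size
    n_s = int(member_mask.sum())
    running = 0.0
    best_up, best_down = 0.0, 0.0
    w_iter = iter(weights)
    for i in range(n):
        if member_mask[i]:
            running += (next(w_iter) / total) if total > 0 else 1.0 / n_s
        else:
            running -= 1.0 / (n - n_s)
        best_up = max(best_up, running)
        best_down = min(best_down, running)
    return best_up, best_down


def bh_stepup_reference(p: np.ndarray) -> np.ndarray:
    """Closed-form step-up: adj(i) = min over p(j) >= p(i) of min(1, m p(j)/rank(j))."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    out = np.empty(m)
    for i in range(m):
        candidates = [min(1.0, m * p[j] / ranks[j]) for j in range(m) if p[j] >= p[i]]
        out[i] = min(candidates)
    return out


def tmm_stepwise_reference(counts: np.ndarray, sample: int, ref: int) -> float:
    """TMM factor of one column vs a reference, written out step by step.

    Follows the definition: gene-wise M (log2 ratio of library-scaled
    proportions) and A values, genes with a zero in either sample dropped,
    double trim (30% of M, 5% of A, rank-based, both tails), weighted mean
    of the surviving M with inverse delta-method variance weights, 2^mean.
    """
    lib = counts.sum(axis=0).astype(float)
    obs, rf = counts[:, sample].astype(float), counts[:, ref].astype(float)
    rows = [g for g in range(counts.shape[0]) if obs[g] > 0 and rf[g] > 0]
    m_vals, a_vals, w_vals = [], [], []
    for g in rows:
        po, pr = obs[g] / lib[sample], rf[g] / lib[ref]
        m_vals.append(np.log2(po / pr))
        a_vals.append(0.5 * np.log2(po * pr))
        w_vals.append(
            (lib[sample] - obs[g]) / (lib[sample] * obs[g])
            + (lib[ref] - rf[g]) / (lib[ref] * rf[g])
        )
    n = len(m_vals)
    if n == 0 or max(abs(v) for v in m_vals) < 1e-6:
        return 1.0
    from scipy.stats import rankdata

    rank_m = rankdata(m_vals)
    rank_a = rankdata(a_vals)
    lo_l = np.floor(n * 0.3) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * 0.05) + 1
    hi_s = n + 1 - lo_s
    num = den = 0.0
    for i in range(n):
        if lo_l <= rank_m[i] <= hi_l and lo_s <= rank_a[i] <= hi_s:
            num += m_vals[i] / w_vals[i]
            den += 1.0 / w_vals[i]
    return float(2.0 ** (num / den)) if den > 0 else 1.0


# ---------------------------------------------------------------------------
# measurements


def es_oracle_max_error(max_len: int = 10, n_t_vectors: int = 3, seed: int = 0) -> float:
    """Max |vectorized ES - exhaustive ES| over every non-trivial subset of
    ranked lists up to ``max_len`` genes, for several random t profiles."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for n in range(2, max_len + 1):
        for _ in range(n_t_vectors):
            t = np.sort(rng.normal(0, 2, n))[::-1]
            genes = [f"g{i:02d}" for i in range(n)]
            ranked = RankedList(genes, t)
            for bits in itertools.product([0, 1], repeat=n):
                mask = np.array(bits, dtype=bool)
                if not 0 < mask.sum() < n:
                    continue
                member_genes = [ranked.gene_ids[i] for i in range(n) if mask[i]]
                for p_exp in (0.0, 1.0):
                    got = enrichment_score(ranked, member_genes, p_exp)
                    want = es_exhaustive(ranked.t_values, mask, p_exp)
                    worst = max(worst, abs(got[0] - want[0]), abs(got[1] - want[1]))
    return worst


def null_contrast_pvalues(seed: int, n_genes: int = 2000):
    """Moderated-t p-values for ILC2 - Th2 on a no-signal simulation."""
    cfg = SimulationConfig(n_genes=n_genes, de_fraction=0.0, seed=seed)
    counts, samples, _, _ = simulate_counts(cfg)
    filt = filter_low_expression(counts)
    design = build_design(samples, "subset")
    norm = log_cpm_and_weights(filt, tmm_factors(filt), design.matrix)
    fit = fit_models(norm, design)
    table = test_contrast(fit, design.contrast({"ILC2": 1, "Th2": -1}))
    return table


def gsea_null_calibration(
    seed: int = 0,
    n_genes: int = 2000,
    n_sets: int = 1000,
    size_range: tuple[int, int] = (20, 200),
    n_permutations: int = 1000,
    alpha: float = 0.05,
) -> float:
    """Fraction of permutation p < alpha for random sets on null data."""
    table = null_contrast_pvalues(seed, n_genes)
    ranked = RankedList.from_contrast(table)
    rng = np.random.default_rng(seed + 1)
    universe = np.array(ranked.gene_ids, dtype=object)
    sets = {
        f"R{i:04d}": list(rng.choice(universe, size=int(rng.integers(*size_range)), replace=False))
        for i in range(n_sets)
    }
    results = gsea_run(
        ranked,
        GeneSetCollection(sets),
        GseaConfig(n_permutations=n_permutations, seed=seed + 2),
    )
    p = np.array([r.p for r in results])
    return float(np.mean(p < alpha))


def gsea_power(
    n_seeds: int = 20,
    n_genes: int = 2000,
    n_enriched: int = 50,
    n_null: int = 150,
    size_range: tuple[int, int] = (10, 40),
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Recovery rate of planted enriched sets: NES > 0 and adj_p < alpha.

    Per seed: default-condition simulation (|log2FC| = 2, 3 donors per
    subset), moderated-t ranking for ILC2 vs Th2, gene sets planted from
    genes truly up in ILC2 or in the whole ILC lineage among random nulls.
    Returns the fraction of (seed, planted set) pairs recovered.
    """
    hits = trials = 0
    for s in range(n_seeds):
        cfg = SimulationConfig(n_genes=n_genes, seed=seed + 101 + s)
        counts, samples, _, truth = simulate_counts(cfg)
        filt = filter_low_expression(counts)
        design = build_design(samples, "subset")
        norm = log_cpm_and_weights(filt, tmm_factors(filt), design.matrix)
        fit = fit_models(norm, design)
        table = test_contrast(fit, design.contrast({"ILC2": 1, "Th2": -1}))
        collection = simulate_genesets(
            list(filt.gene_ids),
            truth,
            n_null_sets=n_null,
            n_enriched_sets=n_enriched,
            size_range=size_range,
            seed=seed + 201 + s,
            target_subsets=("ILC2", "ILC"),
        )
        ranked = RankedList.from_contrast(table)
        results = gsea_run(
            ranked, collection, GseaConfig(n_permutations=n_permutations, seed=seed + 301 + s)
        )
        for r in results:
            if r.direction != "up" or collection.truth.get(r.set_name) == "null":
                continue
            trials += 1
            if r.nes > 0 and r.adj_p < alpha:
                hits += 1
    return hits / trials


def bh_reference_max_error(n_vectors: int = 1000, max_len: int = 30, seed: int = 0) -> float:
    """Max |bh_adjust - closed-form step-up| over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, max_len + 1))
        p = rng.random(n)
        worst = max(worst, float(np.max(np.abs(bh_adjust(p) - bh_stepup_reference(p)))))
    return worst


def empirical_fdr(
    n_seeds: int = 10, n_genes: int = 2000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Mean false-discovery proportion at BH alpha on planted simulations."""
    fdps = []
    for s in range(n_seeds):
        cfg = SimulationConfig(n_genes=n_genes, seed=seed + 11 + s)
        counts, samples, _, truth = simulate_counts(cfg)
        filt = filter_low_expression(counts)
        design = build_design(samples, "subset")
        norm = log_cpm_and_weights(filt, tmm_factors(filt), design.matrix)
        fit = fit_models(norm, design)
        table = test_contrast(fit, design.contrast({"ILC2": 1, "Th2": -1}))
        eff = truth.effects.loc[table.frame["gene_id"]]
        truly_de = (eff["ILC2"] != eff["Th2"]).to_numpy()
        discovered = (table.frame["adj_p"] < alpha).to_numpy()
        n_disc = int(discovered.sum())
        fp = int((discovered & ~truly_de).sum())
        fdps.append(fp / max(n_disc, 1))
    return float(np.mean(fdps))


def eb_recovery_errors(
    n_genes: int = 2000, d0: float = 4.0, s02: float = 0.25, df: float = 12.0, seed: int = 0
) -> tuple[float, float]:
    """Relative errors of (d0, s02) estimated from scaled-inv-chi2 variances."""
    rng = np.random.default_rng(seed)
    sigma2 = d0 * s02 / rng.chisquare(d0, size=n_genes)
    s2 = sigma2 * rng.chisquare(df, size=n_genes) / df
    d0_hat, s02_hat = estimate_prior(s2, df)
    return abs(d0_hat - d0) / d0, abs(s02_hat - s02) / s02


def tmm_depth_scaling_max_deviation() -> float:
    """TMM factors on a pure depth difference (column2 = 2 x column1)."""
    rng = np.random.default_rng(5)
    base = rng.integers(10, 2000, size=300)
    counts = CountMatrix(
        [f"g{i}" for i in range(300)], ["a", "b"], np.column_stack([base, 2 * base])
    )
    return float(np.max(np.abs(tmm_factors(counts) - 1.0)))


def tmm_composition_max_error(seed: int = 0) -> float:
    """Composition-biased toy vs the step-by-step reference, all samples."""
    rng = np.random.default_rng(seed)
    base = rng.integers(50, 5000, size=200)
    inflated = base.copy()
    inflated[:20] = inflated[:20] * 8  # 20 genes 8-fold up in sample B
    third = rng.integers(50, 5000, size=200)
    mat = np.column_stack([base, inflated, third])
    counts = CountMatrix([f"g{i}" for i in range(200)], ["a", "b", "c"], mat)
    got = tmm_factors(counts)
    lib = mat.sum(axis=0)
    f75 = np.quantile(mat / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    raw = np.array([tmm_stepwise_reference(mat, s, ref) for s in range(3)])
    want = raw / np.exp(np.mean(np.log(raw)))
    return float(np.max(np.abs(got - want)))


def filter_rule_mismatches(n_matrices: int = 50, seed: int = 0) -> int:
    """Retained-gene disagreements between the filter and brute-force cpm rule."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_matrices):
        n_g, n_s = int(rng.integers(2, 30)), int(rng.integers(2, 8))
        mat = rng.integers(0, 50, size=(n_g, n_s))
        mat[:, mat.sum(axis=0) == 0] += 1
        counts = CountMatrix([f"g{i}" for i in range(n_g)], [f"s{j}" for j in range(n_s)], mat)
        kept = set(filter_low_expression(counts, 1.0, 1).gene_ids)
        want = set()
        colsums = mat.sum(axis=0)
        for g in range(n_g):
            if any(mat[g, s] / colsums[s] * 1e6 >= 1.0 for s in range(n_s)):
                want.add(f"g{g}")
        if kept != want:
            mismatches += 1
    return mismatches


def signature_recovery(n_seeds: int = 20, n_genes: int = 1000, seed: int = 0) -> dict:
    """Planted-signature recovery and spider diagonal dominance across seeds.

    Per seed: subset-specific planted genes only (no lineage effects, so
    the truth maps one gene to one subset's signature).  Reports the
    fraction of recovered signature genes owned by the correct subset, the
    fraction of truly-up planted genes recovered, and the fraction of
    non-empty spider rows whose maximum sits on the owning subset.
    """
    correct = recovered_total = planted_total = 0
    diag_hits = diag_total = 0
    for s in range(n_seeds):
        cfg = SimulationConfig(
            n_genes=n_genes, lineage_de_fraction=0.0, de_fraction=0.15, seed=seed + 401 + s
        )
        counts, samples, _, truth = simulate_counts(cfg)
        filt = filter_low_expression(counts)
        design = build_design(samples, "subset")
        norm = log_cpm_and_weights(filt, tmm_factors(filt), design.matrix)
        fit = fit_models(norm, design)
        pairwise = {}
        for i, a in enumerate(SUBSETS):
            for b in SUBSETS[i + 1 :]:
                pairwise[(a, b)] = test_contrast(
                    fit, design.contrast({a: 1, b: -1}), f"{a}_vs_{b}"
                )
        sig = subset_signatures(pairwise, list(SUBSETS), norm, samples)
        owner = dict(zip(truth.frame["gene_id"], truth.frame["de_subset"]))
        for subset, genes in sig.members.items():
            for g in genes:
                recovered_total += 1
                if owner.get(g, "") == subset:
                    correct += 1
        planted_total += sum(len(truth.de_genes(subset=u, sign=1)) for u in SUBSETS)
        spider = sig.spider
        for subset in SUBSETS:
            row = spider.loc[subset]
            if row.notna().all() and sig.members[subset]:
                diag_total += 1
                if row.idxmax() == subset:
                    diag_hits += 1
    return {
        "precision": correct / max(recovered_total, 1),
        "recall": correct / max(planted_total, 1),
        "spider_diagonal_rate": diag_hits / max(diag_total, 1),
    }
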