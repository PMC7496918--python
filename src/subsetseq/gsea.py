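"""Gene-set enrichment by weighted running sum with a gene-label permutation null.

Genes are ranked by decreasing moderated t.  Walking down the list, the
running sum rises by ``|t|^P / sum(|t|^P over members)`` at each member gene
and falls by ``1/(N - N_S)`` at each non-member; the maximum of the walk is
the up-enrichment score, the minimum the down-score (both signed, in
[-1, 1]).  The null redraws the member labels uniformly from the ranked
universe (gene-label randomization, not sample permutation).  NES divides
the observed ES by the magnitude of the mean same-direction null ES, and the
permutation p-value is the proportion of null scores at least as extreme in
the score's own direction.  BH adjustment spans all (set, direction) tests
of one run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from subsetseq.io import GeneSetCollection
from subsetseq.linmod import ContrastTable, bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Gene ids ordered by decreasing t; ties broken by gene id."""

    gene_ids: list[str]
    t_values: np.ndarray

    def __post_init__(self) -> None:
        self.t_values = np.asarray(self.t_values, dtype=float)
        if len(self.gene_ids) != self.t_values.size:
            raise ValueError("ranked list length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranked list")
        order = sorted(
            range(len(self.gene_ids)), key=lambda i: (-self.t_values[i], self.gene_ids[i])
        )
        self.gene_ids = [self.gene_ids[i] for i in order]
        self.t_values = self.t_values[order]
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @classmethod
    def from_contrast(cls, table: ContrastTable) -> "RankedList":
        return cls(list(table.frame["gene_id"]), table.frame["t"].to_numpy())

    def __len__(self) -> int:
        return len(self.gene_ids)

    def positions(self, genes) -> np.ndarray:
        """Sorted 0-based rank positions of the given genes (must be present)."""
        return np.sort(np.array([self._index[g] for g in genes], dtype=np.intp))


@dataclass
class GseaConfig:
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    alpha: float = 0.05
    #: permutation-inclusive p = (1 + extreme) / (1 + n); False gives the raw proportion
    add_one: bool = True
    #: share one null per set size within a ranked list (identical by exchangeability)
    shared_null: bool = True

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight exponent must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class GseaResult:
    set_name: str
    direction: str  # "up" | "down"
    es: float
    nes: float
    p: float
    adj_p: float = field(default=np.nan)
    size: int = 0


def _es_from_positions(
    positions: np.ndarray, abs_t: np.ndarray, n_total: int, p_exp: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (ES_up, ES_down) for one or many sorted position rows.

    ``positions``: (n_draws, k) sorted ascending along axis 1.  The running
    sum only changes value at member positions, so the extrema are attained
    immediately after (max) or immediately before (min) a member hit.
    """
    positions = np.atleast_2d(positions)
    n_draws, k = positions.shape
    if not 0 < k < n_total:
        raise ValueError("set size must be in (0, N)")
    w = np.abs(abs_t[positions]) ** p_exp
    totals = w.sum(axis=1, keepdims=True)
    # all-zero weights (e.g. every member t == 0): fall back to equal steps
    flat = totals[:, 0] == 0
    if np.any(flat):
        w[flat] = 1.0
        totals[flat] = k
    w = w / totals
    cumw = np.cumsum(w, axis=1)
    miss = (positions - np.arange(k)) / (n_total - k)  # miss penalty accrued so far
    after = cumw - miss
    before = cumw - w - miss
    # guard against cumsum rounding a hair past the mathematical bounds
    es_up = np.clip(after.max(axis=1), 0.0, 1.0)
    es_down = np.clip(before.min(axis=1), -1.0, 0.0)
    return es_up, es_down


def enrichment_score(
    ranked: RankedList, geneset, p_exp: float = 1.0
) -> tuple[float, float]:
    """Running-sum enrichment scores (ES_up, ES_down) of one gene set."""
    members = set(geneset) & set(ranked.gene_ids)
    if not members:
        raise ValueError("gene set has empty intersection with the ranked universe")
    if len(members) == len(ranked):
        raise ValueError("gene set equals the ranked universe; miss penalty undefined")
    pos = ranked.positions(members)
    es_up, es_down = _es_from_positions(pos, np.abs(ranked.t_values), len(ranked), p_exp)
    return float(es_up[0]), float(es_down[0])


def permutation_null(
    ranked: RankedList,
    set_size: int,
    p_exp: float = 1.0,
    n: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Null (ES_up, ES_down) pairs from n uniform redraws of the member labels."""
    n_total = len(ranked)
    if not 1 <= set_size < n_total:
        raise ValueError(f"set size {set_size} outside [1, {n_total - 1}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = np.empty((n, set_size), dtype=np.intp)
    # top-k of random keys = uniform sample without replacement, vectorized
    keys = rng.random((n, n_total))
    part = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    draws = np.sort(part, axis=1)
    return _es_from_positions(draws, np.abs(ranked.t_values), n_total, p_exp)


def nes_and_pvalue(
    observed: float,
    null_es: np.ndarray,
    direction: str,
    add_one: bool = True,
) -> tuple[float, float]:
    """Normalize an ES by the mean same-direction null and compute its p-value.

    NES = ES / |mean(null ES)| (the sign of the observed ES is preserved);
    p is the proportion of null scores >= ES for "up", <= ES for "down",
    with the permutation-inclusive add-one guard by default.
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size == 0:
        raise ValueError("empty null sample")
    mean_null = null_es.mean()
    if mean_null == 0:
        raise ValueError("degenerate null: mean ES is zero")
    nes = observed / abs(mean_null)
    if direction == "up":
        extreme = int(np.sum(null_es >= observed))
    elif direction == "down":
        extreme = int(np.sum(null_es <= observed))
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    n = null_es.size
    p = (1 + extreme) / (1 + n) if add_one else extreme / n
    return float(nes), float(p)


def gsea_run(
    ranked: RankedList, sets: GeneSetCollection, config: GseaConfig
) -> list[GseaResult]:
    """Score every usable gene set in both directions; BH across all tests."""
    universe = set(ranked.gene_ids)
    usable: dict[str, set] = {}
    skipped = 0
    for name, members in sets.items():
        inter = set(members) & universe
        if inter and len(inter) < len(ranked):
            usable[name] = inter
        else:
            skipped += 1
    if skipped:
        logger.warning("skipped %d gene sets with unusable universe intersection", skipped)
    if not usable:
        raise ValueError("no usable gene sets after universe intersection")

    # one null per distinct set size; seeded per size for order-independence
    sizes = sorted({len(m) for m in usable.values()})
    nulls: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for size in sizes:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, size]))
        nulls[size] = permutation_null(
            ranked, size, config.weight_exponent, config.n_permutations, rng
        )

    results: list[GseaResult] = []
    for name in sorted(usable):
        members = usable[name]
        if config.shared_null:
            null_up, null_down = nulls[len(members)]
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, len(members), hash(name) % (2**31)])
            )
            null_up, null_down = permutation_null(
                ranked, len(members), config.weight_exponent, config.n_permutations, rng
            )
        es_up, es_down = enrichment_score(ranked, members, config.weight_exponent)
        nes_up, p_up = nes_and_pvalue(es_up, null_up, "up", config.add_one)
        nes_down, p_down = nes_and_pvalue(es_down, null_down, "down", config.add_one)
        results.append(GseaResult(name, "up", es_up, nes_up, p_up, size=len(members)))
        results.append(GseaResult(name, "down", es_down, nes_down, p_down, size=len(members)))

    adj = bh_adjust(np.array([r.p for r in results]))
    for r, a in zip(results, adj):
        r.adj_p = float(a)
    return results


def results_frame(results: list[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name, "direction": r.direction, "size": r.size,
                "es": r.es, "nes": r.nes, "p": r.p, "adj_p": r.adj_p,
            }
            for r in results
        ]
    )


def shared_enriched_sets(
    results: dict[str, list[GseaResult]], alpha: float = 0.05
) -> dict[tuple[str, ...], list[str]]:
    """Venn partition of significantly up-enriched sets across comparisons.

    Returns, per non-empty region (exact combination of comparison names),
    the sorted set names significant (adj_p < alpha, NES > 0, direction up)
    in precisely those comparisons.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 result lists to intersect")
    hits: dict[str, set[str]] = {}
    for comparison, res in results.items():
        hits[comparison] = {
            r.set_name
            for r in res
            if r.direction == "up" and r.adj_p < alpha and r.nes > 0
        }
    regions: dict[tuple[str, ...], list[str]] = {}
    every = set().union(*hits.values())
    for set_name in sorted(every):
        region = tuple(sorted(c for c, names in hits.items() if set_name in names))
        regions.setdefault(region, []).append(set_name)
    return regions
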