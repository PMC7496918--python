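"""Ground-truth synthetic data emulating the 6-subset x 3-donor study design.

Counts are negative binomial with ``Var = mu + phi * mu^2``: per-gene
baseline means are log2-uniform, per-gene dispersions gamma-distributed,
library sizes log-normal, and donor effects small per-(gene, donor)
log-normal multipliers.  A configurable fraction of genes carries a planted
subset-specific log2 effect; a fraction of genes is labelled "lncRNA".
Everything downstream can therefore be checked against a recorded truth
table: which genes are differentially expressed where, and which generated
gene sets were built from concordant true effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from subsetseq.io import AnnotationTable, CountMatrix, GeneSetCollection, SampleTable

SUBSET_NAMES = ("ILC1", "ILC2", "ILCP", "Th1", "Th2", "Th17")


@dataclass
class SimulationConfig:
    """Generator parameters; defaults emulate the study conditions at desk scale."""

    n_genes: int = 2000
    n_subsets: int = 6
    n_donors: int = 3
    #: log2 range of baseline mean counts per gene
    baseline_mean_log_range: tuple[float, float] = (1.0, 9.0)
    #: mean NB dispersion phi (gene-wise phi ~ Gamma with this mean); 0 -> Poisson
    dispersion: float = 0.1
    #: fraction of genes with a planted effect
    de_fraction: float = 0.1
    #: fraction of planted genes whose effect spans a whole lineage (all ILC
    #: or all Th subsets) rather than a single subset; emulates the common
    #: innate-vs-adaptive signature on top of subset-specific programs
    lineage_de_fraction: float = 0.5
    #: magnitude of planted log2 fold changes
    effect_size_log2: float = 2.0
    #: sd of the natural log of the per-sample library-size factor
    libsize_log_sd: float = 0.3
    #: sd (log2) of per-(gene, donor) multipliers
    donor_sd_log2: float = 0.1
    #: fraction of genes labelled with the lncRNA biotype
    lncrna_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fraction", "lineage_de_fraction", "lncrna_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_donors < 2:
            raise ValueError("need at least 2 donors")
        if not 1 <= self.n_subsets <= len(SUBSET_NAMES):
            raise ValueError(f"n_subsets must be in [1, {len(SUBSET_NAMES)}]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.libsize_log_sd < 0 or self.donor_sd_log2 < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")

    @property
    def subsets(self) -> tuple[str, ...]:
        return SUBSET_NAMES[: self.n_subsets]


@dataclass
class TruthTable:
    """Planted ground truth: per-gene subset effects, biotypes, set flags."""

    frame: pd.DataFrame       # gene_id, biotype, is_de, de_subset, de_sign
    effects: pd.DataFrame     # genes x subsets, true log2 effects
    #: set name -> "null" or "enriched:<subset>:<up|down>"
    geneset_truth: dict[str, str] = field(default_factory=dict)
    #: per-sample library-size factors actually applied
    lib_factors: pd.Series | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame["gene_id"])

    def de_genes(self, subset: str | None = None, sign: int | None = None) -> list[str]:
        """Planted genes, optionally filtered by target (a subset or a
        lineage name, ``"ILC"``/``"Th"``) and effect sign."""
        mask = self.frame["is_de"]
        if subset is not None:
            mask = mask & (self.frame["de_subset"] == subset)
        if sign is not None:
            mask = mask & (self.frame["de_sign"] == sign)
        return list(self.frame.loc[mask, "gene_id"])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean=mu, Var=mu+phi*mu^2) via gamma-Poisson; phi=0 rows are Poisson."""
    out = np.empty(mu.shape, dtype=np.int64)
    poisson_rows = phi <= 0
    if np.any(poisson_rows):
        out[poisson_rows] = rng.poisson(mu[poisson_rows])
    nb_rows = ~poisson_rows
    if np.any(nb_rows):
        shape = 1.0 / phi[nb_rows, None]
        lam = rng.gamma(shape, mu[nb_rows] / shape)
        out[nb_rows] = rng.poisson(lam)
    return out


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleTable, AnnotationTable, TruthTable]:
    """Generate a count matrix, metadata, annotation and truth table.

    Sample layout: one column per (subset, donor); mean model
    ``mu[g,s] = baseline_g * 2^effect[g, subset(s)] * 2^donor[g, donor(s)]
    * libfactor_s``; counts NB with gene-wise dispersion.  Deterministic
    under a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    subsets = config.subsets
    n_samples = config.n_subsets * config.n_donors
    width = max(6, len(str(config.n_genes)))
    gene_ids = [f"G{str(i + 1).zfill(width)}" for i in range(config.n_genes)]

    sample_rows = [
        {"sample_id": f"{s}_d{d + 1}", "subset": s, "donor": f"d{d + 1}"}
        for s in subsets
        for d in range(config.n_donors)
    ]
    samples = SampleTable(pd.DataFrame(sample_rows))

    lo, hi = config.baseline_mean_log_range
    baseline = 2.0 ** rng.uniform(lo, hi, size=config.n_genes)
    if config.dispersion > 0:
        # shape 2 keeps gene-wise phi positive with mild spread around the mean
        phi = rng.gamma(2.0, config.dispersion / 2.0, size=config.n_genes)
    else:
        phi = np.zeros(config.n_genes)

    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    n_lineage = int(round(config.lineage_de_fraction * n_de))
    is_lineage = np.zeros(n_de, dtype=bool)
    is_lineage[:n_lineage] = True  # de_idx is already a random draw
    de_sign = rng.choice([-1, 1], size=n_de) if n_de else np.array([], int)
    lineages = {"ILC": [s for s in subsets if s.startswith("ILC")],
                "Th": [s for s in subsets if s.startswith("Th")]}
    lineages = {k: v for k, v in lineages.items() if v}
    de_target = np.empty(n_de, dtype=object)
    effects = np.zeros((config.n_genes, len(subsets)))
    lineage_names = list(lineages)
    for j in range(n_de):
        g = de_idx[j]
        if is_lineage[j] and lineage_names:
            lin = lineage_names[rng.integers(len(lineage_names))]
            de_target[j] = lin
            for s in lineages[lin]:
                effects[g, subsets.index(s)] = de_sign[j] * config.effect_size_log2
        else:
            k = int(rng.integers(len(subsets)))
            de_target[j] = subsets[k]
            effects[g, k] = de_sign[j] * config.effect_size_log2

    donor_eff = (
        rng.normal(0.0, config.donor_sd_log2, size=(config.n_genes, config.n_donors))
        if config.donor_sd_log2 > 0
        else np.zeros((config.n_genes, config.n_donors))
    )
    lib_factor = (
        np.exp(rng.normal(0.0, config.libsize_log_sd, size=n_samples))
        if config.libsize_log_sd > 0
        else np.ones(n_samples)
    )

    subset_idx = np.array([subsets.index(r["subset"]) for r in sample_rows])
    donor_idx = np.array([int(r["donor"][1:]) - 1 for r in sample_rows])
    mu = (
        baseline[:, None]
        * 2.0 ** effects[:, subset_idx]
        * 2.0 ** donor_eff[:, donor_idx]
        * lib_factor[None, :]
    )
    counts = _nb_draw(rng, mu, phi)

    biotype = np.where(
        rng.random(config.n_genes) < config.lncrna_fraction, "lncRNA", "protein_coding"
    )
    annotation = AnnotationTable(
        pd.DataFrame(
            {"gene_id": gene_ids, "symbol": [f"SYM{g[1:]}" for g in gene_ids], "biotype": biotype}
        )
    )

    is_de = np.zeros(config.n_genes, dtype=bool)
    is_de[de_idx] = True
    de_subset_col = np.array([""] * config.n_genes, dtype=object)
    de_subset_col[de_idx] = de_target
    de_sign_col = np.zeros(config.n_genes, dtype=int)
    de_sign_col[de_idx] = de_sign
    truth = TruthTable(
        frame=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "biotype": biotype,
                "is_de": is_de,
                "de_subset": de_subset_col,
                "de_sign": de_sign_col,
            }
        ),
        effects=pd.DataFrame(effects, index=gene_ids, columns=list(subsets)),
        lib_factors=pd.Series(lib_factor, index=[r["sample_id"] for r in sample_rows]),
    )

    matrix = CountMatrix(gene_ids, [r["sample_id"] for r in sample_rows], counts)
    return matrix, samples, annotation, truth


def simulate_genesets(
    genes: list[str],
    truth: TruthTable,
    n_null_sets: int = 450,
    n_enriched_sets: int = 50,
    size_range: tuple[int, int] = (20, 200),
    seed: int = 0,
    enriched_purity: float = 0.9,
    target_subsets: tuple[str, ...] | None = None,
) -> GeneSetCollection:
    """Gene-set collection with known enrichment truth.

    Null sets sample the universe uniformly without replacement; enriched
    sets draw a ``enriched_purity`` fraction of their members from genes
    with a positive planted effect in one target subset (cycled over
    ``target_subsets``) and the rest at random.  Each set's truth flag is
    recorded on the returned collection.
    """
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    if lo < 2 or hi > len(genes):
        raise ValueError(f"size_range {size_range} outside [2, {len(genes)}]")
    if not 0.0 <= enriched_purity <= 1.0:
        raise ValueError("enriched_purity must be in [0, 1]")
    genes = list(genes)
    universe = np.array(genes, dtype=object)
    if target_subsets is None:
        target_subsets = tuple(truth.effects.columns)

    sets: dict[str, list[str]] = {}
    flags: dict[str, str] = {}
    for i in range(n_null_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"NULL_{i + 1:04d}"
        sets[name] = list(rng.choice(universe, size=size, replace=False))
        flags[name] = "null"
    gene_set = set(genes)
    pools = {
        t: [g for g in truth.de_genes(subset=t, sign=1) if g in gene_set]
        for t in target_subsets
    }
    available = [t for t in target_subsets if len(pools[t]) >= 2]
    if n_enriched_sets and not available:
        raise ValueError(
            f"no target in {target_subsets} has planted positive-effect genes"
        )
    for i in range(n_enriched_sets):
        subset = available[i % len(available)]
        pool = pools[subset]
        size = int(rng.integers(lo, hi + 1))
        n_signal = min(len(pool), max(2, int(round(enriched_purity * size))))
        # never dilute below the purity target: shrink the set if the pool is small
        size = min(size, max(2, int(np.floor(n_signal / max(enriched_purity, 1e-9)))))
        n_signal = min(n_signal, size)
        signal = list(rng.choice(np.array(pool, dtype=object), size=n_signal, replace=False))
        rest_pool = np.array([g for g in genes if g not in set(signal)], dtype=object)
        filler = list(rng.choice(rest_pool, size=size - n_signal, replace=False))
        name = f"ENRICHED_{subset}_{i + 1:04d}"
        sets[name] = signal + filler
        flags[name] = f"enriched:{subset}:up"
    collection = GeneSetCollection(
        sets, {name: flags[name] for name in sets}, truth=flags
    )
    truth.geneset_truth = dict(flags)
    return collection
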