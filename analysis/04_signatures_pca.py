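"""Subset signatures with spider summaries, heatmap matrices, and PCA.

Builds the per-subset gene signatures (genes up vs all five other subsets at
adj_p < 0.05), their spider-chart coordinates (mean log2 normalized cpm per
subset), the row z-score matrix with complete-linkage row order for the top
DE genes, and the PCA on the 500 most variable genes.
"""

import itertools

from _common import OUT_DIR, SUBSETS, load_inputs, normalize_and_fit

import numpy as np
import pandas as pd

from subsetseq import io as sio
from subsetseq.linmod import test_contrast
from subsetseq.signatures import cluster_order, pca_top_variable, row_zscores, subset_signatures


def main() -> None:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    counts, samples, _, _ = load_inputs()
    _, norm, design, fit = normalize_and_fit(counts, samples)

    pairwise = {
        (a, b): test_contrast(fit, design.contrast({a: 1, b: -1}), f"{a}_vs_{b}")
        for a, b in itertools.combinations(SUBSETS, 2)
    }
    sig = subset_signatures(pairwise, list(SUBSETS), norm, samples)
    sio.write_table(
        pd.DataFrame(
            [{"subset": s, "n_genes": len(g), "genes": ";".join(g)} for s, g in sig.members.items()]
        ),
        OUT_DIR / "signatures.tsv",
    )
    sio.write_table(
        sig.spider.rename_axis("signature").reset_index(), OUT_DIR / "spider_matrix.tsv"
    )
    print("signature sizes:", sig.sizes())
    diag_ok = [
        s for s in SUBSETS if sig.members[s] and sig.spider.loc[s].idxmax() == s
    ]
    print(f"spider maxima on owning subset: {len(diag_ok)}/{sum(1 for s in SUBSETS if sig.members[s])}")

    # z-score heatmap matrix of the 100 most significant pairwise genes
    top = (
        pd.concat([t.frame.assign(pair=n) for (a, b), t in pairwise.items() for n in [f"{a}_vs_{b}"]])
        .sort_values("adj_p")
        .drop_duplicates("gene_id")
        .head(100)["gene_id"]
        .tolist()
    )
    idx = [norm.gene_ids.index(g) for g in top]
    z = row_zscores(pd.DataFrame(norm.log_cpm[idx], index=top, columns=norm.sample_ids))
    order = cluster_order(z)
    sio.write_table(
        z.iloc[order].rename_axis("gene_id").reset_index(), OUT_DIR / "heatmap_zscores.tsv"
    )

    pca = pca_top_variable(norm, n_top=500)
    sio.write_table(
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(pca.variance_fraction.size)],
                "variance_fraction": pca.variance_fraction,
                "cumulative": pca.cumulative_variance,
            }
        ),
        OUT_DIR / "pca_variance.tsv",
    )
    sio.write_table(pca.scores.rename_axis("sample_id").reset_index(), OUT_DIR / "pca_scores.tsv")
    print(
        f"PCA: PC1 explains {100 * pca.variance_fraction[0]:.1f}% of variance, "
        f"first 3 PCs {100 * pca.cumulative_variance[2]:.1f}%"
    )


if __name__ == "__main__":
    main()
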