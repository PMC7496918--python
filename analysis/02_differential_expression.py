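"""Differential expression: total lineages, mirror pairs, and all 15 subset pairs.

Filters to genes with >= 1 cpm in >= 1 sample, computes TMM factors and voom
precision weights, fits the lineage (total ILC vs total Th) and 6-subset
group-means models, and tests the headline contrasts plus every subset pair.
Writes per-contrast tables, the up/down summary and the two-triangle
pairwise count matrix under results/analysis/.
"""

import itertools

from _common import MIRROR_PAIRS, OUT_DIR, SUBSETS, load_inputs, normalize_and_fit

from subsetseq import io as sio
from subsetseq.linmod import (
    DesignMatrix,
    build_design,
    de_pair_matrix,
    de_summary,
    fit_models,
    test_contrast,
)


def main() -> None:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    counts, samples, _, _ = load_inputs()
    filtered, norm, design, fit = normalize_and_fit(counts, samples)
    print(f"retained {filtered.n_genes}/{counts.n_genes} genes at >=1 cpm in >=1 sample")
    print(f"EB prior df d0 = {fit.d0:.2f}, prior variance s0^2 = {fit.s02:.4f}")

    lineage = build_design(samples, "lineage")
    lineage = DesignMatrix(
        lineage.matrix[[lineage.sample_ids.index(s) for s in filtered.sample_ids]],
        lineage.coef_names, list(filtered.sample_ids),
    )
    fit_lin = fit_models(norm, lineage)
    headline = {
        "ILC_vs_Th": test_contrast(fit_lin, lineage.contrast({"ILC": 1, "Th": -1}), "ILC_vs_Th")
    }
    for a, b in MIRROR_PAIRS:
        name = f"{a}_vs_{b}"
        headline[name] = test_contrast(fit, design.contrast({a: 1, b: -1}), name)
    for name, table in headline.items():
        sio.write_contrast_table(table, OUT_DIR / f"de_{name}.tsv")

    summary = de_summary(headline)
    sio.write_table(summary, OUT_DIR / "de_summary.tsv")
    print("\nsignificant genes (adj_p < 0.05):")
    for _, row in summary.iterrows():
        print(f"  {row['comparison']}: {row['n_total']} ({row['n_up']} up, {row['n_down']} down)")

    pairwise = {}
    for a, b in itertools.combinations(SUBSETS, 2):
        name = f"{a}_vs_{b}"
        pairwise[(a, b)] = test_contrast(fit, design.contrast({a: 1, b: -1}), name)
        sio.write_contrast_table(pairwise[(a, b)], OUT_DIR / f"pairwise_{name}.tsv")
    mat = de_pair_matrix(pairwise, list(SUBSETS))
    sio.write_table(mat.rename_axis("subset").reset_index(), OUT_DIR / "de_pair_matrix.tsv")
    print("\npairwise DE counts (row up vs column):")
    print(mat.to_string())


if __name__ == "__main__":
    main()
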