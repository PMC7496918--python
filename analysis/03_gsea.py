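"""Gene-set enrichment per mirror comparison and the shared-set Venn partition.

Ranks all genes by moderated t for each ILC-subset-vs-Th-counterpart
comparison, scores every gene set in both directions against a 1,000-draw
gene-label permutation null, BH-adjusts across all tests, and intersects the
significantly up-enriched sets across the three comparisons.
"""

from _common import MIRROR_PAIRS, OUT_DIR, load_inputs, normalize_and_fit

import pandas as pd

from subsetseq import io as sio
from subsetseq.gsea import GseaConfig, RankedList, gsea_run, shared_enriched_sets
from subsetseq.linmod import test_contrast

SEED = 23


def main() -> None:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    counts, samples, _, genesets = load_inputs()
    _, norm, design, fit = normalize_and_fit(counts, samples)

    cfg = GseaConfig(n_permutations=1000, seed=SEED)
    results = {}
    for a, b in MIRROR_PAIRS:
        name = f"{a}_vs_{b}"
        table = test_contrast(fit, design.contrast({a: 1, b: -1}), name)
        res = gsea_run(RankedList.from_contrast(table), genesets, cfg)
        results[name] = res
        sio.write_gsea_table(res, OUT_DIR / f"gsea_{name}.tsv")
        n_up = sum(1 for r in res if r.direction == "up" and r.adj_p < 0.05)
        print(f"{name}: {n_up} sets up-enriched at adj_p < 0.05 (of {len(res) // 2})")

    venn = shared_enriched_sets(results)
    frame = pd.DataFrame(
        [{"region": "&".join(k), "n_sets": len(v), "sets": ";".join(v)} for k, v in sorted(venn.items())],
        columns=["region", "n_sets", "sets"],
    )
    sio.write_table(frame, OUT_DIR / "gsea_venn.tsv")
    print("\nVenn regions of shared up-enriched sets:")
    for region, names in sorted(venn.items()):
        print(f"  {' & '.join(region)}: {len(names)}")


if __name__ == "__main__":
    main()
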