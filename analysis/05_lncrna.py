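"""lncRNA sub-analysis: read lncRNAs out of the mirror-pair DE tables.

Restricts each mirror-comparison contrast table to genes annotated with the
lncRNA biotype (adjusted p-values kept from the genome-wide family) and
summarizes how many are differentially expressed per comparison, plus the
overlap of significant lncRNAs across the ILC subsets.
"""

from _common import MIRROR_PAIRS, OUT_DIR, load_inputs, normalize_and_fit

from subsetseq import io as sio
from subsetseq.linmod import test_contrast
from subsetseq.signatures import biotype_subset


def main() -> None:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    counts, samples, annotation, _ = load_inputs()
    _, norm, design, fit = normalize_and_fit(counts, samples)

    significant = {}
    for a, b in MIRROR_PAIRS:
        name = f"{a}_vs_{b}"
        table = test_contrast(fit, design.contrast({a: 1, b: -1}), name)
        lnc = biotype_subset(table, annotation, "lncRNA")
        sio.write_contrast_table(lnc, OUT_DIR / f"lncrna_{name}.tsv")
        sig = set(lnc.frame.loc[lnc.frame["adj_p"] < 0.05, "gene_id"])
        significant[name] = sig
        print(f"{name}: {len(sig)} lncRNAs differentially expressed (adj_p < 0.05)")

    names = list(significant)
    shared_all = set.intersection(*significant.values())
    print(f"\nshared across all three comparisons: {len(shared_all)}")
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            both = significant[a] & significant[b]
            print(f"  {a} & {b}: {len(both)}")


if __name__ == "__main__":
    main()
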