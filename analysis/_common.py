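"""Shared paths and loading helpers for the numbered analysis drivers."""

from pathlib import Path

from subsetseq import io as sio
from subsetseq.linmod import build_design, fit_models
from subsetseq.normalize import filter_low_expression, log_cpm_and_weights, tmm_factors

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "results" / "data"
OUT_DIR = ROOT / "results" / "analysis"

SUBSETS = ("ILC1", "ILC2", "ILCP", "Th1", "Th2", "Th17")
MIRROR_PAIRS = (("ILC1", "Th1"), ("ILC2", "Th2"), ("ILCP", "Th17"))


def load_inputs():
    counts = sio.read_counts(DATA_DIR / "counts.tsv")
    samples = sio.read_metadata(DATA_DIR / "metadata.tsv")
    samples.validate_against(counts)
    annotation = sio.read_annotation(DATA_DIR / "annotation.tsv")
    genesets = sio.read_gmt(DATA_DIR / "genesets.gmt")
    return counts, samples, annotation, genesets


def normalize_and_fit(counts, samples):
    """Filter -> TMM -> voom -> 6-group fit, the backbone every step shares."""
    filtered = filter_low_expression(counts)
    factors = tmm_factors(filtered)
    design = build_design(samples, "subset")
    norm = log_cpm_and_weights(filtered, factors, design.matrix)
    fit = fit_models(norm, design)
    return filtered, norm, design, fit
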