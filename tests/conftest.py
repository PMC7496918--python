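import numpy as np
import pytest

from subsetseq.io import CountMatrix, SampleTable
from subsetseq.linmod import build_design, fit_models, test_contrast
from subsetseq.normalize import filter_low_expression, log_cpm_and_weights, tmm_factors
from subsetseq.simulate import SimulationConfig, simulate_counts

SUBSETS = ("ILC1", "ILC2", "ILCP", "Th1", "Th2", "Th17")


@pytest.fixture(scope="session")
def sim_bundle():
    """One moderate simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(n_genes=400, seed=11)
    counts, samples, annotation, truth = simulate_counts(cfg)
    return counts, samples, annotation, truth


@pytest.fixture(scope="session")
def fitted_bundle(sim_bundle):
    """Filter -> TMM -> voom -> subset fit with all 15 pairwise contrasts."""
    counts, samples, annotation, truth = sim_bundle
    filtered = filter_low_expression(counts)
    factors = tmm_factors(filtered)
    design = build_design(samples, "subset")
    norm = log_cpm_and_weights(filtered, factors, design.matrix)
    fit = fit_models(norm, design)
    pairwise = {}
    for i, a in enumerate(SUBSETS):
        for b in SUBSETS[i + 1 :]:
            pairwise[(a, b)] = test_contrast(fit, design.contrast({a: 1, b: -1}), f"{a}_vs_{b}")
    return {
        "samples": samples,
        "annotation": annotation,
        "truth": truth,
        "filtered": filtered,
        "design": design,
        "norm": norm,
        "fit": fit,
        "pairwise": pairwise,
    }


@pytest.fixture
def toy_counts():
    rng = np.random.default_rng(3)
    mat = rng.integers(0, 500, size=(40, 4))
    return CountMatrix([f"g{i:02d}" for i in range(40)], ["s1", "s2", "s3", "s4"], mat)
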