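import pytest

from medipdiff.core import ASSAY_INPUT, ASSAY_MC
from medipdiff.differential import (
    build_candidate_regions,
    call_differential_regions,
    density_matrix,
)
from medipdiff.peaks import call_peaks, window_scan
from medipdiff.synthetic import (
    SyntheticConfig,
    generate_gene_models,
    generate_truth_regions,
    simulate_library,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        genome=[("chr1", 300_000)],
        n_genes=10,
        n_enriched_regions=8,
        n_differential_regions=6,
        tags_per_library=30_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genes(small_config):
    return generate_gene_models(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_genes):
    return generate_truth_regions(small_config, small_genes)


def run_one_assay_analysis(config, truth, window_size=200, step=50,
                           p_max=1e-5, fdr_max=0.01, merge_gap=100,
                           fold_min=2.0, alpha=0.05):
    """Simulate one 5mC experiment and run peaks -> candidates -> DMR calls."""
    sizes = config.chrom_sizes()
    samples = [("case", i) for i in range(config.n_case)] + [
        ("control", i) for i in range(config.n_control)
    ]
    ip_libs, peak_sets = [], {}
    for j, (group, i) in enumerate(samples):
        inp = simulate_library(config, [], ASSAY_INPUT, group, replicate_seed=j)
        ip = simulate_library(config, truth, ASSAY_MC, group, replicate_seed=100 + j,
                              library_id=f"{group}{i}_ip")
        ip_libs.append(ip)
        stats = window_scan(ip, inp, sizes, window_size, step)
        peak_sets[ip.library_id] = call_peaks(stats, p_max, fdr_max, merge_gap,
                                              ip.library_id)
    if not any(peak_sets.values()):
        return ip_libs, [], None, []
    candidates = build_candidate_regions(peak_sets, ASSAY_MC)
    matrix = density_matrix(candidates, ip_libs)
    groups = {lib.library_id: lib.group for lib in ip_libs}
    calls, _ = call_differential_regions(candidates, matrix, groups, fold_min, alpha)
    return ip_libs, candidates, matrix, calls
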