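import pytest

from cherrygt import panel, simulate


@pytest.fixture(scope="session")
def loci():
    return panel.default_loci()


@pytest.fixture(scope="session")
def scenario_barcodes():
    return panel.scenario_barcode_panel()


@pytest.fixture(scope="session")
def small_sheet(scenario_barcodes):
    """Four strains x 4 individuals in the two-pool layout."""
    return panel.default_sample_sheet(scenario_barcodes, n_per_strain=4)


@pytest.fixture(scope="session")
def small_truth(loci):
    specs = simulate.default_strain_specs(loci, p_het_yellow=0.5)
    return simulate.draw_truth_genotypes(specs, n_per_strain=4, seed=11)


@pytest.fixture()
def small_library(tmp_path, loci, scenario_barcodes, small_sheet, small_truth):
    """Error-free library at depth 40: {pool_id: (r1, r2)} plus context."""
    paths = simulate.simulate_library(
        loci, scenario_barcodes, small_sheet, small_truth,
        depth_per_locus=40, error_rate=0.0, seed=12, out_dir=tmp_path)
    return {
        "paths": paths, "loci": loci, "barcodes": scenario_barcodes,
        "sheet": small_sheet, "truth": small_truth, "depth": 40,
    }
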