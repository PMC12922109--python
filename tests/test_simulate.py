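"""Synthetic-data generator: truth draws, read layout, images, Ct tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cherrygt import panel, simulate
from cherrygt._seq import revcomp


def spec_for(loci, strain="red", probs=(1.0, 0.0, 0.0)):
    return simulate.StrainGenotypeSpec(
        strain=strain, locus_probs={loc.locus_id: probs for loc in loci})


class TestDrawTruthGenotypes:
    def test_degenerate_hom_ref(self, loci):
        truth = simulate.draw_truth_genotypes([spec_for(loci)], 20, seed=1)
        assert (truth["genotype"] == "hom_ref").all()

    def test_degenerate_het(self, loci):
        truth = simulate.draw_truth_genotypes(
            [spec_for(loci, probs=(0.0, 1.0, 0.0))], 20, seed=1)
        assert (truth["genotype"] == "het").all()

    def test_het_fraction_matches_binomial_sampling(self, loci):
        # oracle: het count ~ Binomial(n, 0.3); check within 3 standard errors
        n = 10000
        truth = simulate.draw_truth_genotypes(
            [spec_for(loci, strain="yellow", probs=(0.7, 0.3, 0.0))], n, seed=2)
        for _, sub in truth.groupby("locus_id"):
            frac = (sub["genotype"] == "het").mean()
            se = np.sqrt(0.3 * 0.7 / n)
            assert abs(frac - 0.3) < 3 * se

    def test_invalid_probabilities_raise(self, loci):
        with pytest.raises(ValueError, match="sum"):
            simulate.draw_truth_genotypes(
                [spec_for(loci, probs=(0.5, 0.2, 0.1))], 5, seed=1)
        with pytest.raises(ValueError):
            simulate.draw_truth_genotypes([spec_for(loci)], 0, seed=1)

    def test_reproducible_under_fixed_seed(self, loci):
        specs = [spec_for(loci, strain="yellow", probs=(0.5, 0.5, 0.0))]
        a = simulate.draw_truth_genotypes(specs, 50, seed=9)
        b = simulate.draw_truth_genotypes(specs, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_truth_csv_roundtrip(self, tmp_path, small_truth):
        path = tmp_path / "truth.csv"
        simulate.write_truth_csv(small_truth, path)
        pd.testing.assert_frame_equal(simulate.read_truth_csv(path), small_truth)


class TestSimulateLibrary:
    def test_total_read_pairs(self, small_library):
        n_records = sum(1 for _ in open(list(small_library["paths"].values())[0][0])) // 4
        total = sum(sum(1 for _ in open(p1)) // 4
                    for p1, _ in small_library["paths"].values())
        n_ind = len(small_library["sheet"])
        assert total == n_ind * len(small_library["loci"]) * small_library["depth"]
        assert n_records > 0

    def test_error_free_reads_have_exact_layout(self, small_library):
        loci = {loc.locus_id: loc for loc in small_library["loci"]}
        bar = small_library["barcodes"]
        sheet = {r.individual_id: r for r in small_library["sheet"].records}
        for pool_id, (p1, p2) in small_library["paths"].items():
            with open(p1) as f1, open(p2) as f2:
                lines1 = f1.read().splitlines()
                lines2 = f2.read().splitlines()
            for i in range(0, len(lines1), 4 * 17):  # sample sparsely
                name = lines1[i][1:]
                _, ind, locus_id, _ = name.split("|")
                rec, loc = sheet[ind], loci[locus_id]
                s1, s2 = lines1[i + 1], lines2[i + 1]
                assert s1.startswith(rec.i5_tag + bar.oh1 + loc.forward_primer)
                assert s2.startswith(rec.i7_tag + bar.oh2 + loc.reverse_primer)
                assert len(s1) <= 150 and len(s2) <= 150

    def test_hom_ref_individual_all_ref_at_snp(self, small_library):
        loc = small_library["loci"][0]
        bar = small_library["barcodes"]
        truth = small_library["truth"]
        hom = truth[(truth["genotype"] == "hom_ref") &
                    (truth["locus_id"] == loc.locus_id)]["individual_id"].iloc[0]
        snp_col = 6 + len(bar.oh1) + len(loc.forward_primer) + loc.snp_offset - 1
        found = 0
        for p1, _ in small_library["paths"].values():
            with open(p1) as fh:
                lines = fh.read().splitlines()
            for i in range(0, len(lines), 4):
                _, ind, locus_id, _ = lines[i][1:].split("|")
                if ind == hom and locus_id == loc.locus_id:
                    assert lines[i + 1][snp_col] == loc.ref_allele
                    found += 1
        assert found == small_library["depth"]

    def test_het_individual_emits_both_alleles(self, tmp_path, loci, scenario_barcodes):
        sheet = panel.default_sample_sheet(scenario_barcodes, n_per_strain=1)
        specs = [spec_for(loci, s, (0.0, 1.0, 0.0)) for s in
                 ("red", "yellow", "blue", "wild")]
        truth = simulate.draw_truth_genotypes(specs, 1, seed=3)
        paths = simulate.simulate_library(loci, scenario_barcodes, sheet, truth,
                                          depth_per_locus=200, error_rate=0.0,
                                          seed=4, out_dir=tmp_path)
        loc = loci[0]
        snp_col = 6 + len(scenario_barcodes.oh1) + len(loc.forward_primer) + loc.snp_offset - 1
        counts = {loc.ref_allele: 0, loc.alt_allele: 0}
        p1, _ = paths["RY"]
        with open(p1) as fh:
            lines = fh.read().splitlines()
        for i in range(0, len(lines), 4):
            if lines[i].split("|")[2] == loc.locus_id:
                counts[lines[i + 1][snp_col]] += 1
        n_ref, n_alt = counts[loc.ref_allele], counts[loc.alt_allele]
        # two het individuals in this pool at depth 200 each
        assert n_ref + n_alt == 400
        assert n_ref > 0 and n_alt > 0
        # Binomial(400, 0.5): ratio far inside the heterozygous AFI zone
        assert 0.2 < n_ref / n_alt < 5

    def test_fixed_seed_gives_byte_identical_fastq(self, tmp_path, loci,
                                                   scenario_barcodes, small_sheet,
                                                   small_truth):
        outs = []
        for sub in ("a", "b"):
            paths = simulate.simulate_library(
                loci, scenario_barcodes, small_sheet, small_truth,
                depth_per_locus=10, error_rate=0.01, seed=99,
                out_dir=tmp_path / sub)
            outs.append(b"".join(p.read_bytes() for pair in paths.values() for p in pair))
        assert outs[0] == outs[1]

    def test_precondition_errors(self, loci, scenario_barcodes, small_sheet,
                                 small_truth, tmp_path):
        with pytest.raises(ValueError, match="depth"):
            simulate.simulate_library(loci, scenario_barcodes, small_sheet,
                                      small_truth, 0, 0.0, 1, tmp_path)
        with pytest.raises(ValueError, match="error_rate"):
            simulate.simulate_library(loci, scenario_barcodes, small_sheet,
                                      small_truth, 5, 1.5, 1, tmp_path)
        with pytest.raises(ValueError, match="missing"):
            simulate.simulate_library(loci, scenario_barcodes, small_sheet,
                                      small_truth.iloc[:3], 5, 0.0, 1, tmp_path)


class TestSimulateImages:
    def test_zero_clusters_gives_empty_truth(self):
        img, truth = simulate.simulate_images(
            0, simulate.ClusterGeometry(10, 4), 0.8, background=30, seed=1)
        assert truth.empty
        assert (img == 30).all()

    def test_cluster_truth_records_geometry(self):
        geom = simulate.ClusterGeometry(15, 6, rotate=True)
        img, truth = simulate.simulate_images(3, geom, 0.7, background=30, seed=2)
        assert len(truth) == 3
        assert (truth["length"] == 30).all() and (truth["width"] == 12).all()
        assert np.allclose(truth["rpb"], 0.7, atol=0.01)

    def test_cluster_larger_than_image_raises(self):
        with pytest.raises(ValueError, match="larger"):
            simulate.simulate_images(1, simulate.ClusterGeometry(200, 50), 0.8,
                                     background=30, seed=1, image_size=(64, 64))

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            simulate.ClusterGeometry(0, 0).validate()
        with pytest.raises(ValueError):
            simulate.ClusterGeometry(4, 10).validate()


class TestSimulateCtTable:
    def test_noiseless_one_cycle_effect_gives_fold_change_two(self):
        from cherrygt import expression
        ct = simulate.simulate_ct_table({"cg": 0.0, "tg": -1.0}, sd=0.0,
                                        n_per_group=4, seed=1)
        expr = expression.delta_delta_ct(ct, "cg")
        assert np.allclose(expr.loc[expr["group"] == "tg", "rel_expr"], 2.0)
        assert np.allclose(expr.loc[expr["group"] == "cg", "rel_expr"], 1.0)

    def test_identical_group_means_give_near_zero_f(self):
        ct = simulate.simulate_ct_table({"a": 1.0, "b": 1.0, "c": 1.0}, sd=0.3,
                                        n_per_group=200, seed=2)
        dct = ct.assign(dct=ct["target_ct"] - ct["reference_ct"])
        f = stats.f_oneway(*[g["dct"].to_numpy() for _, g in dct.groupby("group")])
        assert f.pvalue > 0.01

    def test_two_fold_effect_recovered_within_20_percent(self):
        # Monte-Carlo over seeds: mean recovered fold change near 2
        from cherrygt import expression
        folds = []
        for seed in range(5):
            ct = simulate.simulate_ct_table({"cg": 0.0, "tg": -1.0}, sd=0.2,
                                            n_per_group=7, seed=seed)
            expr = expression.delta_delta_ct(ct, "cg")
            folds.append(expr.loc[expr["group"] == "tg", "rel_expr"].mean())
        assert abs(np.mean(folds) - 2.0) < 0.4

    def test_preconditions(self):
        with pytest.raises(ValueError):
            simulate.simulate_ct_table({"a": 0.0}, sd=-1, n_per_group=4, seed=1)
        with pytest.raises(ValueError):
            simulate.simulate_ct_table({"a": 0.0}, sd=0.1, n_per_group=1, seed=1)


class TestAmpliconConstruction:
    def test_amplicon_carries_allele_and_primers(self, loci):
        loc = loci[0]
        for allele in (loc.ref_allele, loc.alt_allele):
            amp = simulate.build_amplicon(loc, allele)
            assert len(amp) == loc.amplicon_length
            assert amp.startswith(loc.forward_primer)
            assert amp.endswith(revcomp(loc.reverse_primer))
            assert amp[loc.snp_position - 1] == allele

    def test_filler_is_locus_stable(self, loci):
        a = simulate.build_amplicon(loci[0], loci[0].ref_allele)
        b = simulate.build_amplicon(loci[0], loci[0].ref_allele)
        assert a == b
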