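"""End-to-end orchestration of the default four-strain scenario.

Chains simulate -> demultiplex -> genotype -> associate -> annotate on
the default panel (two coding SNPs, four colour strains in two pools)
and writes every stage artifact plus a machine-readable run manifest.
Used by the ``all`` CLI subcommand and importable directly.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path

import pandas as pd

from . import association, coding, demux, genotype, panel, simulate


@dataclass
class ScenarioConfig:
    """Parameters of the default simulation-and-analysis scenario."""

    seed: int = 1
    n_per_strain: int = simulate.DEFAULT_N_PER_STRAIN
    depth_per_locus: int = simulate.DEFAULT_DEPTH
    error_rate: float = simulate.DEFAULT_ERROR_RATE
    p_het_yellow: float = simulate.DEFAULT_P_HET_YELLOW
    max_mismatch: int = 0
    min_depth: int = genotype.DEFAULT_MIN_DEPTH
    thresholds: genotype.AfiThresholds = field(default_factory=genotype.AfiThresholds)
    focal_strain: str = "yellow"


def write_manifest(out_dir: Path, stage: str, params: dict) -> Path:
    """Record stage, parameters, package version, and platform for a run."""
    try:
        ver = pkg_version("cherrygt")
    except Exception:
        ver = "unknown"
    manifest = {
        "stage": stage,
        "package": "cherrygt",
        "version": ver,
        "python": platform.python_version(),
        "parameters": params,
    }
    path = Path(out_dir) / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


def run_end_to_end(out_dir: str | Path, config: ScenarioConfig | None = None) -> dict:
    """Run the whole pipeline on simulated data; returns stage results.

    Returns a dict with the loci, sample sheet, truth table, demux
    summaries, long-format calls, and per-locus association reports.
    All tabular artifacts are also written under ``out_dir``.
    """
    cfg = config or ScenarioConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    loci = panel.default_loci()
    barcodes = panel.scenario_barcode_panel()
    sheet = panel.default_sample_sheet(barcodes, n_per_strain=cfg.n_per_strain)
    report = panel.validate_panel(loci, barcodes, sheet)
    if report.errors:
        raise ValueError("panel validation failed: " + "; ".join(report.errors))

    specs = simulate.default_strain_specs(loci, p_het_yellow=cfg.p_het_yellow)
    truth = simulate.draw_truth_genotypes(specs, cfg.n_per_strain, seed=cfg.seed)
    fastqs = simulate.simulate_library(
        loci, barcodes, sheet, truth, cfg.depth_per_locus, cfg.error_rate,
        seed=cfg.seed + 1, out_dir=out_dir / "fastq")

    results = demux.demultiplex_pools(fastqs, barcodes, sheet,
                                      max_mismatch=cfg.max_mismatch)
    demux.write_summary_csv([r.summary for r in results.values()],
                            out_dir / "demux_summary.csv")

    calls = genotype.call_genotypes(results, loci, barcodes,
                                    thresholds=cfg.thresholds,
                                    min_depth=cfg.min_depth)
    genotype.write_calls_csv(calls, out_dir / "genotype_calls.csv")
    genotype.genotype_matrix(calls).to_csv(out_dir / "genotype_matrix.csv")

    reports = {}
    tables = {}
    for loc in loci:
        tab, _ = association.genotype_frequency_table(calls, sheet, loc.locus_id)
        tables[loc.locus_id] = tab
        rep = association.association_report(calls, sheet, loc.locus_id,
                                             focal_strain=cfg.focal_strain)
        reports[loc.locus_id] = rep
        (out_dir / f"association_{loc.locus_id}.txt").write_text(rep + "\n")

    cds = coding.synthetic_cds()
    changes = coding.annotate_panel(loci, cds)
    ann = pd.DataFrame([{
        "locus_id": loc.locus_id,
        "cdna_label": ch.nucleotide_label,
        "protein_label": ch.protein_label,
        "codon_index": ch.codon_idx,
        "codon_position": ch.codon_pos,
        "ref_codon": ch.ref_codon,
        "alt_codon": ch.alt_codon,
        "synonymous": ch.synonymous,
    } for loc, ch in zip([l for l in loci if l.cdna_position], changes)])
    ann.to_csv(out_dir / "coding_effects.csv", index=False)

    write_manifest(out_dir, "all", asdict(cfg))
    return {
        "loci": loci, "barcodes": barcodes, "sheet": sheet, "truth": truth,
        "fastqs": fastqs, "demux": results, "calls": calls,
        "tables": tables, "association_reports": reports,
        "coding_effects": ann,
    }


def concordance_with_truth(calls: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of individual x locus calls matching the simulated truth."""
    merged = calls.merge(truth, on=["individual_id", "locus_id"], how="inner")
    if merged.empty:
        raise ValueError("no overlapping individual x locus pairs")
    return float((merged["call"] == merged["genotype"]).mean())
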