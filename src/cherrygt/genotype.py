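"""Allele counting and AFI-threshold genotype calling.

For each demultiplexed read, the forward primer is located at its fixed
construct offset (barcode + OH1 adapter), and the base ``snp_offset``
positions past the primer's 3' end is tallied as ref, alt, or other.
The allele frequency index (AFI) is the ratio of ref-allele to
alt-allele read counts; genotype classes follow the published threshold
scheme: AFI > 10 -> homozygous ref, AFI < 0.1 -> homozygous alt,
0.2 < AFI < 5 -> heterozygous, with the buffer zones [0.1, 0.2] and
[5, 10] (boundaries inclusive) and any call below the depth floor left
unclassifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .demux import DemuxResult
from .panel import BARCODE_LENGTH, BarcodePanel, SnpLocus

CALLS = ("hom_ref", "hom_alt", "het", "unclassifiable")
DEFAULT_MIN_DEPTH = 10
DEFAULT_MAX_PRIMER_MISMATCH = 2


@dataclass(frozen=True)
class AfiThresholds:
    """Genotype-zone boundaries on the ref/alt count ratio."""

    hom_low: float = 0.1
    het_low: float = 0.2
    het_high: float = 5.0
    hom_high: float = 10.0

    def validate(self) -> None:
        if not (0 < self.hom_low < self.het_low < self.het_high < self.hom_high):
            raise ValueError(
                "thresholds must satisfy 0 < hom_low < het_low < het_high < hom_high, "
                f"got {self}")


DEFAULT_THRESHOLDS = AfiThresholds()


@dataclass(frozen=True)
class AlleleCounts:
    individual_id: str
    locus_id: str
    n_ref: int
    n_alt: int
    n_other: int

    @property
    def depth(self) -> int:
        return self.n_ref + self.n_alt + self.n_other


def _mismatches_capped(a: str, b: str, cap: int) -> int:
    """Substitution count between equal-length strings, early exit past cap."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > cap:
                return n
    return n


def extract_snp_base(read: str, locus: SnpLocus,
                     max_primer_mismatch: int = DEFAULT_MAX_PRIMER_MISMATCH,
                     primer_start: int | None = None,
                     adapter_length: int | None = None) -> str | None:
    """SNP base from one read 1, or None when the primer is not found.

    The primer is expected at ``primer_start`` (default: barcode length
    plus OH1 adapter length) and is accepted with up to
    ``max_primer_mismatch`` substitutions; the returned base sits
    ``snp_offset`` positions after the primer's 3' end.
    """
    if primer_start is None:
        if adapter_length is None:
            from .panel import OH1_DEFAULT
            adapter_length = len(OH1_DEFAULT)
        primer_start = BARCODE_LENGTH + adapter_length
    fp = locus.forward_primer
    snp_pos = primer_start + len(fp) + locus.snp_offset - 1
    if snp_pos >= len(read) or primer_start + len(fp) > len(read):
        return None
    window = read[primer_start:primer_start + len(fp)]
    if _mismatches_capped(window, fp, max_primer_mismatch) > max_primer_mismatch:
        return None
    return read[snp_pos]


def count_alleles(reads: list[str] | list[tuple[str, str, str]], locus: SnpLocus,
                  individual_id: str = "", barcodes: BarcodePanel | None = None,
                  max_primer_mismatch: int = DEFAULT_MAX_PRIMER_MISMATCH) -> AlleleCounts:
    """Tally ref/alt/other SNP bases over one individual's read bin.

    Accepts raw read-1 strings or demultiplexer ``(read_id, seq1, seq2)``
    triples.  Reads whose primer cannot be located contribute nothing.
    """
    adapter_length = len(barcodes.oh1) if barcodes is not None else None
    n_ref = n_alt = n_other = 0
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        base = extract_snp_base(seq, locus, max_primer_mismatch,
                                adapter_length=adapter_length)
        if base is None:
            continue
        if base == locus.ref_allele:
            n_ref += 1
        elif base == locus.alt_allele:
            n_alt += 1
        else:
            n_other += 1
    return AlleleCounts(individual_id=individual_id, locus_id=locus.locus_id,
                        n_ref=n_ref, n_alt=n_alt, n_other=n_other)


def compute_afi(counts: AlleleCounts) -> float:
    """Ref-to-alt read-count ratio; +inf when alt is absent, NaN when both are."""
    if counts.n_alt == 0:
        return math.inf if counts.n_ref > 0 else math.nan
    return counts.n_ref / counts.n_alt


def classify_genotype(afi: float, depth: int,
                      thresholds: AfiThresholds = DEFAULT_THRESHOLDS,
                      min_depth: int = DEFAULT_MIN_DEPTH) -> str:
    """Genotype class from AFI and depth under the threshold scheme."""
    thresholds.validate()
    if depth < min_depth or math.isnan(afi):
        return "unclassifiable"
    if afi > thresholds.hom_high:
        return "hom_ref"
    if afi < thresholds.hom_low:
        return "hom_alt"
    if thresholds.het_low < afi < thresholds.het_high:
        return "het"
    return "unclassifiable"


def call_genotypes(demux_results: dict[str, DemuxResult] | DemuxResult,
                   loci: list[SnpLocus], barcodes: BarcodePanel,
                   thresholds: AfiThresholds = DEFAULT_THRESHOLDS,
                   min_depth: int = DEFAULT_MIN_DEPTH,
                   max_primer_mismatch: int = DEFAULT_MAX_PRIMER_MISMATCH
                   ) -> pd.DataFrame:
    """Full calling stage: long-format table of counts, AFI, and calls.

    One row per individual x locus with columns ``individual_id,
    locus_id, n_ref, n_alt, n_other, depth, afi, call``.
    """
    if isinstance(demux_results, DemuxResult):
        demux_results = {"_": demux_results}
    rows = []
    for result in demux_results.values():
        for individual_id, reads in result.bins.items():
            for locus in loci:
                counts = count_alleles(reads, locus, individual_id, barcodes,
                                       max_primer_mismatch)
                afi = compute_afi(counts)
                call = classify_genotype(afi, counts.depth, thresholds, min_depth)
                rows.append((individual_id, locus.locus_id, counts.n_ref,
                             counts.n_alt, counts.n_other, counts.depth, afi, call))
    return pd.DataFrame(rows, columns=[
        "individual_id", "locus_id", "n_ref", "n_alt", "n_other",
        "depth", "afi", "call"])


def genotype_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Wide individuals x loci matrix; unclassifiable shown as NA."""
    wide = calls.pivot(index="individual_id", columns="locus_id", values="call")
    return wide.where(wide != "unclassifiable")


def write_calls_csv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, index=False)
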