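"""Amplicon panel, barcode set, and sample-sheet domain model.

A GT-seq panel targets a handful of SNPs with locus-specific primer pairs.
The two-round PCR design appends overhang adapters (OH1/OH2) to the
first-round primers; second-round primers add 6-bp inline i5/i7 barcodes
whose pair identifies one individual.  This module holds the plain data
types plus design-rule validation; nothing here touches reads.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._seq import generate_barcodes, hamming, is_dna

# Overhang adapter sequences of the two-round GT-seq construct.
OH1_DEFAULT = "CGACAGGTTCAGAGTTCTACAGTCCGACGATC"
OH2_DEFAULT = "GCTCGTCGTGACGCCATGACGG"

BARCODE_LENGTH = 6
MAX_AMPLICON_LENGTH = 300
SNP_DISTANCE_RANGE = (50, 100)  # preferred SNP distance from a primer, bp
STRAINS = ("red", "yellow", "blue", "wild")


@dataclass(frozen=True)
class SnpLocus:
    """One amplicon target with a single diagnostic SNP.

    ``snp_offset`` counts bases from the 3' end of the forward-primer
    binding site to the SNP, 1-based; ``cdna_position`` (optional) places
    the SNP on the coding sequence for downstream effect annotation.
    """

    locus_id: str
    forward_primer: str
    reverse_primer: str
    snp_offset: int
    ref_allele: str
    alt_allele: str
    amplicon_length: int
    cdna_position: int | None = None

    @property
    def snp_position(self) -> int:
        """1-based SNP position within the amplicon."""
        return len(self.forward_primer) + self.snp_offset


@dataclass(frozen=True)
class BarcodePanel:
    """Inline 6-bp barcode sets and the overhang adapters they follow."""

    i5_tags: tuple[str, ...]
    i7_tags: tuple[str, ...]
    oh1: str = OH1_DEFAULT
    oh2: str = OH2_DEFAULT


@dataclass(frozen=True)
class SampleRecord:
    pool_id: str
    i5_tag: str
    i7_tag: str
    individual_id: str
    strain: str


@dataclass(frozen=True)
class SampleSheet:
    """Mapping of (pool, i5, i7) triples to individuals.

    Identity is the full triple: one pooled sequencing submission reuses
    barcode pairs only across pools, never within one.
    """

    records: tuple[SampleRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def by_pool(self) -> dict[str, list[SampleRecord]]:
        pools: dict[str, list[SampleRecord]] = {}
        for rec in self.records:
            pools.setdefault(rec.pool_id, []).append(rec)
        return pools

    def lookup(self) -> dict[tuple[str, str, str], SampleRecord]:
        return {(r.pool_id, r.i5_tag, r.i7_tag): r for r in self.records}

    def strain_of(self) -> dict[str, str]:
        return {r.individual_id: r.strain for r in self.records}


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors and not self.warnings


def validate_panel(loci: list[SnpLocus], barcodes: BarcodePanel,
                   sheet: SampleSheet | None = None) -> ValidationReport:
    """Check a panel against the GT-seq design rules.

    Violations are collected, not raised: hard design errors (amplicon
    over 300 bp, malformed primers, duplicate barcodes or sheet triples)
    versus soft warnings (SNP outside the preferred 50-100 bp window from
    either primer, barcode pairs at Hamming distance 1).
    """
    rep = ValidationReport()

    for loc in loci:
        tag = f"locus {loc.locus_id}"
        if loc.ref_allele == loc.alt_allele:
            rep.errors.append(f"{tag}: ref and alt alleles identical ({loc.ref_allele})")
        for name, allele in (("ref", loc.ref_allele), ("alt", loc.alt_allele)):
            if allele not in "ACGT" or len(allele) != 1:
                rep.errors.append(f"{tag}: {name} allele {allele!r} is not a single ACGT base")
        for name, primer in (("forward", loc.forward_primer), ("reverse", loc.reverse_primer)):
            if not is_dna(primer):
                rep.errors.append(f"{tag}: {name} primer empty or non-ACGT")
        if loc.amplicon_length > MAX_AMPLICON_LENGTH:
            rep.errors.append(
                f"{tag}: amplicon length {loc.amplicon_length} exceeds "
                f"{MAX_AMPLICON_LENGTH} bp")
        if loc.snp_offset < 1:
            rep.errors.append(f"{tag}: snp_offset {loc.snp_offset} < 1")
        elif loc.snp_position > loc.amplicon_length:
            rep.errors.append(
                f"{tag}: SNP at amplicon position {loc.snp_position} beyond "
                f"amplicon length {loc.amplicon_length}")
        else:
            lo, hi = SNP_DISTANCE_RANGE
            dist_fwd = loc.snp_offset
            dist_rev = loc.amplicon_length - len(loc.reverse_primer) - loc.snp_position + 1
            if not (lo <= dist_fwd <= hi or lo <= dist_rev <= hi):
                rep.warnings.append(
                    f"{tag}: SNP is {dist_fwd} bp from the forward and {dist_rev} bp "
                    f"from the reverse primer; prefer {lo}-{hi} bp from one of them")

    for name, tags in (("i5", barcodes.i5_tags), ("i7", barcodes.i7_tags)):
        for t in tags:
            if len(t) != BARCODE_LENGTH or not is_dna(t):
                rep.errors.append(f"{name} barcode {t!r} is not a {BARCODE_LENGTH}-bp DNA word")
        if len(set(tags)) != len(tags):
            dupes = sorted({t for t in tags if tags.count(t) > 1})
            rep.errors.append(f"duplicate {name} barcodes: {', '.join(dupes)}")
        close = [
            (a, b) for a, b in itertools.combinations(sorted(set(tags)), 2)
            if len(a) == len(b) == BARCODE_LENGTH and hamming(a, b) < 2
        ]
        for a, b in close:
            rep.warnings.append(
                f"{name} barcodes {a}/{b} differ at a single base; "
                f"1-mismatch rescue would be ambiguous")

    if sheet is not None:
        seen: set[tuple[str, str, str]] = set()
        for rec in sheet.records:
            key = (rec.pool_id, rec.i5_tag, rec.i7_tag)
            if key in seen:
                rep.errors.append(f"duplicate sample-sheet triple {key}")
            seen.add(key)
            if rec.i5_tag not in barcodes.i5_tags:
                rep.errors.append(
                    f"sample {rec.individual_id}: i5 tag {rec.i5_tag} not in panel")
            if rec.i7_tag not in barcodes.i7_tags:
                rep.errors.append(
                    f"sample {rec.individual_id}: i7 tag {rec.i7_tag} not in panel")
            if rec.strain not in STRAINS:
                rep.errors.append(
                    f"sample {rec.individual_id}: unknown strain {rec.strain!r}")
    return rep


def enumerate_tag_pairs(barcodes: BarcodePanel) -> list[tuple[str, str]]:
    """All ordered (i5, i7) combinations the panel can tag.

    8 i5 x 24 i7 tagging primers give the study design's 192 distinct
    combinations; one pair marks one individual within a pool.
    """
    return list(itertools.product(barcodes.i5_tags, barcodes.i7_tags))


# ---------------------------------------------------------------------------
# defaults

def default_loci() -> list[SnpLocus]:
    """The two coding SNPs of the carotenoid-oxygenase target gene.

    Each SNP is modelled as its own amplicon target with its own primer
    pair (the panel's first-round primers), offsets placing the variant
    base inside the preferred central read region.
    """
    return [
        SnpLocus(
            locus_id="ninab_c927",
            forward_primer="AACGAATATAAAAACGTAATCTCCAG",
            reverse_primer="AGCCCCTAAGATCGGTGT",
            snp_offset=75,
            ref_allele="C",
            alt_allele="A",
            amplicon_length=220,
            cdna_position=927,
        ),
        SnpLocus(
            locus_id="ninab_c935",
            forward_primer="CATCCTGAAGCACAGAACGA",
            reverse_primer="CGTATCTCCCTCCTTCCCTC",
            snp_offset=83,
            ref_allele="A",
            alt_allele="C",
            amplicon_length=240,
            cdna_position=935,
        ),
    ]


def default_barcode_panel() -> BarcodePanel:
    """The study-design panel: 8 i5 and 24 i7 tags (192 combinations)."""
    codes = generate_barcodes(8 + 24)
    return BarcodePanel(i5_tags=tuple(codes[:8]), i7_tags=tuple(codes[8:32]))


def scenario_barcode_panel() -> BarcodePanel:
    """Extended panel (16 i5 x 24 i7) for the two-pool, four-strain scenario.

    One pooled submission carries two 192-individual strain plates; each
    plate gets its own block of 8 i5 tags so every individual in the pool
    has a unique (i5, i7) pair.
    """
    codes = generate_barcodes(16 + 24)
    return BarcodePanel(i5_tags=tuple(codes[:16]), i7_tags=tuple(codes[16:40]))


def default_sample_sheet(barcodes: BarcodePanel | None = None,
                         n_per_strain: int = 192) -> SampleSheet:
    """Two-pool layout: {red, yellow} and {blue, wild}, 192 individuals each.

    Within a pool the first strain uses the first 8 i5 tags and the second
    strain the next 8, each crossed with all 24 i7 tags.
    """
    if barcodes is None:
        barcodes = scenario_barcode_panel()
    n_i7 = len(barcodes.i7_tags)
    block = 8
    if n_per_strain > block * n_i7:
        raise ValueError(
            f"n_per_strain {n_per_strain} exceeds the {block}x{n_i7} tag "
            f"combinations available per strain plate")
    pools = {"RY": ("red", "yellow"), "BW": ("blue", "wild")}
    records = []
    for pool_id, strains in pools.items():
        for slot, strain in enumerate(strains):
            i5_block = barcodes.i5_tags[slot * block:(slot + 1) * block]
            for k in range(n_per_strain):
                records.append(SampleRecord(
                    pool_id=pool_id,
                    i5_tag=i5_block[k // n_i7],
                    i7_tag=barcodes.i7_tags[k % n_i7],
                    individual_id=f"{strain}_{k + 1:03d}",
                    strain=strain,
                ))
    return SampleSheet(records=tuple(records))


# ---------------------------------------------------------------------------
# file I/O

def read_loci_csv(path: str | Path) -> list[SnpLocus]:
    loci = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            loci.append(SnpLocus(
                locus_id=row["locus_id"],
                forward_primer=row["forward_primer"],
                reverse_primer=row["reverse_primer"],
                snp_offset=int(row["snp_offset"]),
                ref_allele=row["ref_allele"],
                alt_allele=row["alt_allele"],
                amplicon_length=int(row["amplicon_length"]),
                cdna_position=int(row["cdna_position"]) if row.get("cdna_position") else None,
            ))
    return loci


def write_loci_csv(loci: list[SnpLocus], path: str | Path) -> None:
    cols = ["locus_id", "forward_primer", "reverse_primer", "snp_offset",
            "ref_allele", "alt_allele", "amplicon_length", "cdna_position"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for loc in loci:
            w.writerow([getattr(loc, c) if getattr(loc, c) is not None else ""
                        for c in cols])


def read_barcodes_yaml(path: str | Path) -> BarcodePanel:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return BarcodePanel(
        i5_tags=tuple(data["i5_tags"]),
        i7_tags=tuple(data["i7_tags"]),
        oh1=data.get("oh1", OH1_DEFAULT),
        oh2=data.get("oh2", OH2_DEFAULT),
    )


def write_barcodes_yaml(barcodes: BarcodePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({
            "i5_tags": list(barcodes.i5_tags),
            "i7_tags": list(barcodes.i7_tags),
            "oh1": barcodes.oh1,
            "oh2": barcodes.oh2,
        }, fh, sort_keys=False)


def read_sample_sheet_csv(path: str | Path) -> SampleSheet:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(SampleRecord(
                pool_id=row["pool_id"], i5_tag=row["i5_tag"], i7_tag=row["i7_tag"],
                individual_id=row["individual_id"], strain=row["strain"]))
    return SampleSheet(records=tuple(records))


def write_sample_sheet_csv(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pool_id", "i5_tag", "i7_tag", "individual_id", "strain"])
        for r in sheet.records:
            w.writerow([r.pool_id, r.i5_tag, r.i7_tag, r.individual_id, r.strain])
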