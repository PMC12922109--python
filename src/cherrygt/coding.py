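"""Coding-effect annotation of SNPs on a 1-based CDS coordinate system.

Position 1 is the first base of the start codon, so nucleotide position
``p`` falls in codon ``ceil(p/3)`` at within-codon position
``((p-1) mod 3) + 1``.  Substitutions are translated under the standard
genetic code and labelled in the cDNA ("C.927C > A") and protein
("309S > R") styles used for these shrimp variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from ._seq import DNA_BASES, is_dna


def codon_index(cdna_position: int) -> tuple[int, int]:
    """Map a 1-based CDS nucleotide position to (codon index, codon position).

    Both outputs are 1-based; codon position is 1..3.  E.g. position 927
    is the third base of codon 309, position 935 the second base of
    codon 312.
    """
    if cdna_position < 1:
        raise ValueError(f"cDNA position must be >= 1, got {cdna_position}")
    return (cdna_position + 2) // 3, (cdna_position - 1) % 3 + 1


def cds_position(codon_idx: int, codon_pos: int) -> int:
    """Inverse of :func:`codon_index`."""
    if codon_idx < 1 or codon_pos not in (1, 2, 3):
        raise ValueError("codon index must be >= 1 and codon position in 1..3")
    return 3 * (codon_idx - 1) + codon_pos


@dataclass(frozen=True)
class CodingChange:
    cdna_position: int
    ref_nt: str
    alt_nt: str
    codon_idx: int
    codon_pos: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa

    @property
    def nucleotide_label(self) -> str:
        return f"C.{self.cdna_position}{self.ref_nt} > {self.alt_nt}"

    @property
    def protein_label(self) -> str:
        return f"{self.codon_idx}{self.ref_aa} > {self.alt_aa}"


def validate_cds(cds: str) -> None:
    if len(cds) < 3:
        raise ValueError("CDS must be at least one codon long")
    if not is_dna(cds):
        raise ValueError("CDS must be non-empty ACGT")
    if len(cds) % 3:
        warnings.warn(
            f"CDS length {len(cds)} is not a multiple of 3; the trailing "
            f"partial codon is ignored", stacklevel=2)


def translate_codon(codon: str) -> str:
    """Single-letter amino acid (stop as '*') under the standard code."""
    return str(Seq(codon).translate())


def annotate_substitution(cds: str, position: int, ref_nt: str, alt_nt: str) -> CodingChange:
    """Annotate a single-base substitution at a CDS position.

    The CDS base at ``position`` must equal ``ref_nt``; a mismatch is an
    error (wrong reference, wrong coordinates, or both).
    """
    validate_cds(cds)
    if ref_nt == alt_nt:
        raise ValueError("ref and alt nucleotides are identical")
    c_idx, c_pos = codon_index(position)
    if position > len(cds) - (len(cds) % 3):
        raise ValueError(
            f"position {position} beyond the last complete codon of a "
            f"{len(cds)}-nt CDS")
    observed = cds[position - 1]
    if observed != ref_nt:
        raise ValueError(
            f"reference mismatch at position {position}: CDS has {observed}, "
            f"expected {ref_nt}")
    start = 3 * (c_idx - 1)
    ref_codon = cds[start:start + 3]
    alt_codon = ref_codon[:c_pos - 1] + alt_nt + ref_codon[c_pos:]
    return CodingChange(
        cdna_position=position, ref_nt=ref_nt, alt_nt=alt_nt,
        codon_idx=c_idx, codon_pos=c_pos,
        ref_codon=ref_codon, alt_codon=alt_codon,
        ref_aa=translate_codon(ref_codon), alt_aa=translate_codon(alt_codon))


_STOPS = {"TAA", "TAG", "TGA"}


def synthetic_cds(n_codons: int = 400, seed: int = 20230914) -> str:
    """Synthetic stand-in CDS reproducing the panel's codon contexts.

    The real transcript sequence is not shipped; this generated CDS
    carries the codon contexts the two coding SNPs require — AGC
    (serine) at codon 309 so the third-position C>A at nucleotide 927
    yields arginine, and AAA (lysine) at codon 312 so the second-position
    A>C at nucleotide 935 yields threonine — plus an A at nucleotide 920
    (codon 307) for the monomorphic third variant.  Elsewhere: ATG start,
    seeded random non-stop codons, TAA stop.
    """
    if n_codons < 313:
        raise ValueError("need at least 313 codons to place the panel SNP contexts")
    rng = np.random.default_rng(seed)
    non_stop = [a + b + c
                for a in DNA_BASES for b in DNA_BASES for c in DNA_BASES
                if a + b + c not in _STOPS]
    codons = ["ATG"] + [non_stop[i] for i in rng.integers(0, len(non_stop),
                                                          size=n_codons - 2)] + ["TAA"]
    codons[306] = "CAT"  # codon 307: A at position 2 (CDS nucleotide 920)
    codons[308] = "AGC"  # codon 309: serine, C at position 3 (nucleotide 927)
    codons[311] = "AAA"  # codon 312: lysine, A at position 2 (nucleotide 935)
    return "".join(codons)


def annotate_panel(loci, cds: str) -> list[CodingChange]:
    """Annotate every panel locus that carries a cDNA position."""
    return [annotate_substitution(cds, loc.cdna_position, loc.ref_allele, loc.alt_allele)
            for loc in loci if loc.cdna_position is not None]
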