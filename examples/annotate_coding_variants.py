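"""Map the panel's cDNA SNP positions to codons and amino-acid changes.

Uses the synthetic stand-in CDS that reproduces the panel's codon
contexts (AGC at codon 309, AAA at codon 312).
"""

from cherrygt import coding, panel

cds = coding.synthetic_cds()
for change in coding.annotate_panel(panel.default_loci(), cds):
    kind = "synonymous" if change.synonymous else "nonsynonymous"
    print(f"{change.nucleotide_label}: codon {change.codon_idx} "
          f"position {change.codon_pos}, {change.ref_codon} -> {change.alt_codon}, "
          f"{change.protein_label} ({kind})")
# C.927C > A gives 309S > R and C.935A > C gives 312K > T — both
# nonsynonymous substitutions in the carotenoid-oxygenase coding sequence.
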