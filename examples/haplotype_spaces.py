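"""Enumerate the haplotype and genotype spaces of a multiplexed drive locus.

With m gRNA target sites, each site is wild type (W), functional resistant
(R) or nonfunctional resistant (N), and the drive construct (D) occupies the
whole chromosome. With no positional effects there are C(m+2,2)+1 haplotypes.
"""

from multidrive import enumerate_genotypes, enumerate_haplotypes

for m in (1, 2, 3):
    haps = enumerate_haplotypes(m)
    genos = enumerate_genotypes(m)
    fully = [h.label for h in haps if not h.is_drive and h.is_fully_resistant()]
    print(f"m={m}: {len(haps):2d} haplotypes, {len(genos):2d} diploid genotypes")
    print(f"   haplotypes: {', '.join(h.label for h in haps)}")
    print(f"   fully resistant (count toward the 0.95 criterion): {', '.join(fully)}")

# The counts 4 / 7 / 11 are what make multiplexing tractable: resistance
# requires an R or N allele at *all* m sites of one chromosome.
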