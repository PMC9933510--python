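"""Per-locus diversity statistics of a germplasm collection.

Simulates a 160-accession x 40-locus codominant genotype matrix (2-5
alleles per locus) and prints the seven per-locus statistics with their
column means — the layout of a standard SSR diversity table.
"""

from ssrcore import GenotypeSimConfig, collection_summary, generate_genotypes
from ssrcore.diversity import rounded_summary, total_alleles

matrix, truth = generate_genotypes(
    GenotypeSimConfig(
        n_accessions=160, n_loci=40, alleles_per_locus=None,
        missing_rate=0.02, seed=11,
    )
)
table = collection_summary(matrix)
print(rounded_summary(table).head(8).to_string())
print("...")
print(rounded_summary(table).tail(1).to_string(header=False))
print(f"total alleles: {total_alleles(table)}")
# Na counts observed alleles; Ne = 1/sum(p^2) weights them by evenness;
# I is the Shannon index; Ho the observed and He/Nei the expected
# heterozygosity; PIC summarizes how informative the marker is for
# distinguishing accessions.
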