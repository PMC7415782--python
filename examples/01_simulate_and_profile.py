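"""Simulate a genome, sequence it, and estimate its size from k-mers.

Builds a 500 kb single-chromosome genome, draws error-free 50x reads, and
runs the k-mer profiler.  The genome-size estimate divides the number of
counted 19-mers by the depth of the histogram's main peak; the repeat
threshold is twice the peak plus one.
"""
from wgacompare import (build_histogram, estimate_profile, generate_ancestor,
                        simulate_reads)

genomes, genes = generate_ancestor(n_chroms=1, chrom_length=500_000,
                                   gene_count=30, gc=0.39, seed=1)
reads = simulate_reads(genomes, coverage=50, read_length=1000,
                       error_rate=0.0, seed=2)
profile = estimate_profile(build_histogram(reads, k=19))

print(f"true genome size      : {sum(g.length for g in genomes):,} bp")
print(f"main k-mer peak depth : {profile.peak_depth}")
print(f"estimated genome size : {profile.genome_size_estimate:,} bp")
print(f"repeat depth threshold: {profile.repeat_depth_threshold}")
print(f"heterozygosity est.   : {profile.heterozygosity_estimate:.2e}")
# The estimate should land within a few percent of 500,000; the peak sits
# near the 50x coverage; heterozygosity is ~0 for this homozygous genome.
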