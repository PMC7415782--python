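"""Recover implanted inversions, translocations and relocations.

Inversions appear as reverse-strand blocks between well-aligned forward
flanks; moved segments appear as well-aligned blocks off the collinear
backbone (inter-chromosomal = translocation, intra = relocation).
"""
from collections import Counter

from wgacompare import (MutationConfig, align_genomes, call_svs, evolve_pair,
                        generate_ancestor, sv_recovery)

anc, genes = generate_ancestor(2, 600_000, 40, seed=11)
cfg = MutationConfig(snp_rate=0.002, n_inversions=3, n_translocations=2,
                     n_relocations=2, inversion_size_range=(2000, 20000),
                     translocation_size_range=(5000, 20000),
                     relocation_size_range=(5000, 20000))
ga, _, gb, _, truth = evolve_pair(anc, genes, MutationConfig(), cfg, seed=11)

svs = call_svs(align_genomes(ga, gb))
print("called:", dict(Counter(s.sv_type for s in svs)))
for types in (("inversion",), ("translocation", "relocation")):
    r = sv_recovery(truth, svs, types)
    print(f"{'+'.join(types):26s} recall {r.recall:.2f} "
          f"precision {r.precision:.2f}")
# Recall/precision are measured at 50% reciprocal overlap with the truth
# intervals on the reference genome.
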