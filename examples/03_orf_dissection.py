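"""Design the protein-vs-RNA dissection mutants for a random gene.

Finds all ORFs (including TTG/GTG alternative starts) in a random-gene
insert, then builds the three diagnostic constructs: start-codon
knockout (kills the protein, barely touches the RNA), maximal synonymous
recoding (keeps the protein, scrambles RNA-level features), and a
3'-third truncation. The printed substitution counts are the number of
nucleotide changes each design introduces.
"""

import numpy as np

from randgene import (
    DegenerateScheme,
    design_start_mutation,
    find_orfs,
    synonymous_recode,
    truncate_3prime,
)

rng = np.random.default_rng(7)
codons = DegenerateScheme("NNB", "NNB").codons
stopfree = [c for c in codons if c not in {"TAA", "TAG", "TGA"}]
insert = "ATG" + "".join(
    stopfree[i] for i in rng.integers(0, len(stopfree), 50)
) + "TAA"

orfs = find_orfs(insert, min_aa=10)
print(f"ORFs with >= 10 residues: {len(orfs)}")
for orf in orfs:
    print(f"  [{orf.start:3d},{orf.end:3d}) start={orf.start_codon} "
          f"protein={len(orf.protein)} aa")

main_orf = orfs[0]
knockout = design_start_mutation(insert, main_orf)
print(f"\nstart knockout : {main_orf.start_codon} -> {knockout[main_orf.start:main_orf.start+3]}"
      f" (no ORF remains at position {main_orf.start}:"
      f" {all(o.start != main_orf.start for o in find_orfs(knockout))})")

recoded, n_subs = synonymous_recode(insert, main_orf)
same_protein = find_orfs(recoded, min_aa=10)[0].protein == main_orf.protein
print(f"synonymous recode: {n_subs} substitutions across "
      f"{len(main_orf.protein)} codons, protein unchanged: {same_protein}")

truncated = truncate_3prime(insert, 1 / 3)
print(f"3' truncation  : {len(insert)} -> {len(truncated)} nt")
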